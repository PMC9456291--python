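import numpy as np
import pytest

from kcnq1ca import gating as G
from kcnq1ca.protocols import Segment, VoltageProtocol

from conftest import random_scheme, two_state_scheme


def short_protocol(v_step=-20.0, settle=20.0, dur=30.0, holding=-80.0):
    return VoltageProtocol(
        holding_mV=holding,
        sweeps=((Segment(settle, holding, holding), Segment(dur, v_step, v_step)),),
    )


def euler_occupancy(scheme, protocol, ca, dt=5e-5, dt_out=1.0):
    """Independent explicit-Euler reference integrator.

    Mathematically identical to step-by-step Euler at step ``dt``: for a
    constant generator the n-step Euler map is (I + Q dt)^n, evaluated here
    by exact matrix powers.
    """
    p = G.steady_state(scheme, protocol.holding_mV, ca)
    t_grid = np.arange(0.0, protocol.sweep_duration_ms, dt_out)
    out = np.empty((t_grid.size, scheme.n_states))
    onsets = protocol.segment_onsets_ms()
    k = 0
    for seg, onset in zip(protocol.sweeps[0], onsets):
        Q = G.rate_matrix(scheme, seg.v0_mV, ca)
        n_pts = int(round(seg.dur_ms / dt_out))
        n_sub = int(round(dt_out / dt))
        E = np.linalg.matrix_power(np.eye(scheme.n_states) + dt * Q, n_sub)
        for j in range(n_pts):
            out[k + j] = p
            p = E @ p
        k += n_pts
    return t_grid, out


class TestSchemeConstruction:
    def test_wt_eight_states_two_conducting(self, wt_scheme):
        assert wt_scheme.n_states == 8
        conducting = [s.name for s in wt_scheme.states if s.conducting_weight > 0]
        assert sorted(conducting) == ["AO", "IO"]

    def test_layer_removal_identity(self, wt_scheme, wt5_scheme):
        assert wt5_scheme.n_states == 5
        kept = [s.name for s in wt5_scheme.states]
        assert kept == [s.name for s in wt_scheme.states if s.layer == "normal"]
        # shared transitions carry identical rate laws
        tr8 = {(t.source, t.target): t.rate_law for t in wt_scheme.transitions}
        tr5 = {(t.source, t.target): t.rate_law for t in wt5_scheme.transitions}
        assert set(tr5) == {k for k in tr8 if "*" not in k[0] + k[1]}
        assert all(tr8[k] == tr5[k] for k in tr5)

    @pytest.mark.parametrize("variant", ["P369L", "R116L"])
    def test_mutant_starved_layer_is_unreachable_padding(self, variant):
        """A mutant's 8-state generator equals its 5-state generator padded
        with unreachable starred states, at any voltage and Ca2+."""
        s8 = G.scheme_from_parameters(G.default_parameters(), variant, True)
        s5 = G.scheme_from_parameters(G.default_parameters(), variant, False)
        for v, ca in [(-80, 20e-9), (0, 100e-9), (40, 5e-6)]:
            q8 = G.rate_matrix(s8, v, ca)
            q5 = G.rate_matrix(s5, v, ca)
            np.testing.assert_allclose(q8[:5, :5], q5, atol=1e-15)
            assert np.all(q8[5:, :5] == 0), "starred states must be unreachable"

    def test_unknown_variant_rejected(self):
        with pytest.raises(G.GatingError):
            G.build_default_scheme("A300T")

    def test_json_round_trip(self, wt_scheme):
        again = G.GatingScheme.from_json(wt_scheme.to_json())
        assert again == wt_scheme

    def test_starved_states_nonconducting_enforced(self):
        with pytest.raises(G.GatingError):
            G.State("X*", conducting_weight=0.5, layer="starved")


class TestRateMatrix:
    @pytest.mark.parametrize("v,ca", [(-120, 20e-9), (-30, 100e-9), (60, 5e-6)])
    def test_generator_columns_sum_to_zero(self, wt_scheme, v, ca):
        Q = G.rate_matrix(wt_scheme, v, ca)
        np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_saturating_ca_empties_starved_layer(self, wt_scheme):
        p = G.steady_state(wt_scheme, -80.0, 1.0)  # 1 M: f -> 1
        starved = [i for i, s in enumerate(wt_scheme.states) if s.layer == "starved"]
        assert p[starved].sum() < 1e-6

    def test_ca_enters_only_via_modulated_transitions(self, wt_scheme):
        idx = {s.name: i for i, s in enumerate(wt_scheme.states)}
        q1 = G.rate_matrix(wt_scheme, -40.0, 20e-9)
        q2 = G.rate_matrix(wt_scheme, -40.0, 5e-6)
        unmodulated = [
            (idx[t.target], idx[t.source])
            for t in wt_scheme.transitions
            if t.rate_law.ca_scaling == "none"
        ]
        for i, j in unmodulated:
            assert q1[i, j] == pytest.approx(q2[i, j])

    def test_nonfinite_inputs_rejected(self, wt_scheme):
        with pytest.raises(G.GatingError):
            G.rate_matrix(wt_scheme, np.nan, 1e-7)
        with pytest.raises(G.GatingError):
            G.rate_matrix(wt_scheme, 0.0, -1e-9)


class TestSteadyState:
    def test_symmetric_two_state_is_half_half(self):
        p = G.steady_state(two_state_scheme(0.01, 0.01), 0.0, 1e-7)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_detailed_balance_two_state(self):
        p = G.steady_state(two_state_scheme(0.02, 0.01), 0.0, 1e-7)
        np.testing.assert_allclose(p, [1 / 3, 2 / 3], atol=1e-12)

    def test_wt_hyperpolarized_low_ca_rests_in_rc_states(self, wt_scheme):
        p = G.steady_state(wt_scheme, -120.0, 20e-9)
        names = wt_scheme.state_names
        assert names[int(np.argmax(p))] in ("RC", "RC*")

    def test_steady_state_solves_nullspace(self, wt_scheme):
        for v, ca in [(-80, 20e-9), (0, 5e-6)]:
            p = G.steady_state(wt_scheme, v, ca)
            Q = G.rate_matrix(wt_scheme, v, ca)
            assert np.max(np.abs(Q @ p)) < 1e-10
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)

    def test_long_simulation_converges_to_steady_state(self, wt_scheme):
        """100 s at constant voltage reaches the algebraic stationary state."""
        v, ca = -50.0, 100e-9
        target = G.steady_state(wt_scheme, v, ca)
        prot = VoltageProtocol(holding_mV=v, sweeps=((Segment(100_000.0, v, v),),))
        tr = G.simulate(wt_scheme, prot, ca=ca, dt_out=1000.0,
                        p0=G.steady_state(wt_scheme, -80.0, ca))[0]
        np.testing.assert_allclose(tr.occupancy[-1], target, atol=1e-7)


class TestSimulate:
    def test_constant_voltage_from_steady_state_is_fixed_point(self, wt_scheme):
        prot = short_protocol(v_step=-80.0)
        tr = G.simulate(wt_scheme, prot, ca=100e-9)[0]
        drift = np.max(np.abs(tr.occupancy - tr.occupancy[0]))
        assert drift < 1e-8

    def test_occupancy_conserved_everywhere(self, wt_scheme):
        prot = short_protocol(v_step=20.0, dur=200.0)
        tr = G.simulate(wt_scheme, prot, ca=20e-9)[0]
        np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(tr.occupancy >= 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrix_exponential_matches_fine_euler(self, seed):
        """Propagator equivalence on randomized schemes (independent oracle)."""
        rng = np.random.default_rng(seed)
        scheme = random_scheme(rng)
        prot = short_protocol(v_step=float(rng.uniform(-40, 40)), dur=30.0,
                              holding=-40.0)
        tr = G.simulate(scheme, prot, ca=1e-7, dt_out=1.0)[0]
        _, ref = euler_occupancy(scheme, prot, ca=1e-7, dt=5e-5, dt_out=1.0)
        assert np.max(np.abs(tr.occupancy - ref)) < 1e-6

    def test_ramp_substepping_converges(self, wt_scheme):
        prot = VoltageProtocol(
            holding_mV=-80.0,
            sweeps=((Segment(20.0, -80.0, -80.0), Segment(100.0, -120.0, -40.0)),),
        )
        tr1 = G.simulate(wt_scheme, prot, ca=1e-7, dt_out=1.0)[0]
        tr2 = G.simulate(wt_scheme, prot, ca=1e-7, dt_out=0.5)[0]
        shared = np.isin(tr2.time_ms, tr1.time_ms)
        assert np.max(np.abs(tr2.occupancy[shared] - tr1.occupancy)) < 1e-5

    def test_invalid_dt_rejected(self, wt_scheme):
        with pytest.raises(G.GatingError):
            G.simulate(wt_scheme, short_protocol(), dt_out=-1.0)


class TestCurrent:
    def test_zero_driving_force_zero_current(self, wt_scheme):
        e_k = -86.0
        prot = short_protocol(v_step=e_k)
        tr = G.simulate(wt_scheme, prot, ca=5e-6)[0]
        cur = G.current_from_occupancy(tr, 20.0, e_k, weights=wt_scheme.conducting_weights)
        seg2 = tr.voltage_mV == e_k
        np.testing.assert_allclose(cur[seg2], 0.0, atol=1e-12)

    def test_current_linear_in_gmax(self, wt_scheme):
        prot = short_protocol(v_step=0.0, dur=100.0)
        tr = G.simulate(wt_scheme, prot, ca=5e-6)[0]
        w = wt_scheme.conducting_weights
        c1 = G.current_from_occupancy(tr, 10.0, -86.0, weights=w)
        c2 = G.current_from_occupancy(tr, 20.0, -86.0, weights=w)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_outward_current_at_depolarized_potentials(self, wt_scheme):
        prot = short_protocol(v_step=40.0, dur=400.0)
        tr = G.simulate(wt_scheme, prot, ca=5e-6)[0]
        cur = G.current_from_occupancy(tr, 20.0, -85.0, weights=wt_scheme.conducting_weights)
        assert cur[-1] > 0


class TestCaLimits:
    def test_high_ca_limit_matches_five_state_model(self, wt_scheme, wt5_scheme):
        p8 = G.steady_state(wt_scheme, -40.0, 1.0)
        p5 = G.steady_state(wt5_scheme, -40.0, 1.0)
        np.testing.assert_allclose(p8[:5], p5, atol=1e-5)
        assert p8[5:].sum() < 1e-5

    def test_conducting_occupancy_decreases_as_ca_falls(self, wt_scheme):
        w = wt_scheme.conducting_weights
        cas = [5e-6, 1e-6, 3e-7, 1e-7, 3e-8, 1e-8]
        cond = [float(G.steady_state(wt_scheme, -50.0, ca) @ w) for ca in cas]
        assert all(a > b for a, b in zip(cond, cond[1:]))

    def test_sensor_hill_function_monotone_bounded(self):
        sensor = G.CaSensor(kd=2.5e-7, hill_n=1.3)
        cas = np.geomspace(1e-10, 1e-3, 50)
        f = sensor.f(cas)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(np.diff(f) > 0)
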