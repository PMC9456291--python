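import numpy as np
import pytest

from kcnq1ca import analysis as A
from kcnq1ca import gating as G
from kcnq1ca import pipelines as P
from kcnq1ca.protocols import get_preset
from kcnq1ca.recording import Recording


def boltz(v, c, comps):
    y = np.full_like(np.asarray(v, float), c)
    for vh, k, d in comps:
        y = y + d / (1.0 + np.exp(-(v - vh) / k))
    return y


def synthetic_recording(protocol, fill=100.0):
    """Recording with a constant current everywhere (protocol-shaped)."""
    t = np.arange(0.0, protocol.sweep_duration_ms, 1.0)
    volts = np.vstack([protocol.sample_voltage(i, 1.0)[1] for i in range(protocol.n_sweeps)])
    cur = np.full((protocol.n_sweeps, t.size), fill)
    return Recording(cur, t, volts, protocol, 1.0)


class TestAmplitudes:
    def test_constant_trace_amplitude(self):
        rec = synthetic_recording(get_preset("iv2s"), fill=100.0)
        amps = A.measure_amplitude(rec, 2, 2.0, 5.0)
        np.testing.assert_allclose(amps, 100.0)

    def test_full_segment_window_equals_segment_mean(self):
        prot = get_preset("iv2s")
        rec = synthetic_recording(prot)
        rec.sweeps[:] = np.arange(rec.time_ms.size)[None, :]
        seg = prot.sweeps[0][1]
        amps = A.measure_amplitude(rec, 1, 0.0, seg.dur_ms)
        mask = rec.segment_window_mask(1, 0.0, seg.dur_ms)
        np.testing.assert_allclose(amps, rec.sweeps[:, mask].mean(axis=1))

    def test_window_outside_segment_rejected(self):
        rec = synthetic_recording(get_preset("iv2s"))
        with pytest.raises(Exception):
            A.measure_amplitude(rec, 1, 1990.0, 50.0)

    def test_instantaneous_amplitude_tracks_open_fraction(self, wt_scheme):
        """On noiseless model output the early-P2 amplitude is proportional
        to the conducting occupancy at the end of P1."""
        rec = P.model_recording(wt_scheme, "iv2s", ca=5e-6)
        traces = G.simulate(wt_scheme, get_preset("iv2s"), ca=5e-6)
        w = wt_scheme.conducting_weights
        p1_end = np.array([tr.occupancy[2049] @ w for tr in traces])  # last P1 sample
        amps = A.measure_amplitude(rec, 2, *A.INSTANT_WINDOW_MS)
        r = np.corrcoef(p1_end, amps)[0, 1]
        assert r > 0.999


class TestGV:
    def test_identical_sweeps_flat_gv(self):
        rec = synthetic_recording(get_preset("iv2s"), fill=50.0)
        gv = A.extract_gv(rec)
        np.testing.assert_allclose(gv.normalized_conductance, 1.0)
        assert gv.isochrone_ms == 2000.0

    def test_normalization_idempotent(self, early_iv_recording):
        gv = A.extract_gv(early_iv_recording)
        assert np.max(gv.normalized_conductance) == pytest.approx(1.0)
        assert np.all(np.diff(gv.p1_potentials) > 0)

    def test_saturated_gv_monotone(self, wt_scheme):
        gv = P.model_gv(wt_scheme, ca=5e-6)
        assert np.all(np.diff(gv.normalized_conductance) > -1e-6)

    def test_low_ca_gv_lacks_saturation(self, low_ca_iv_recording):
        """The low-Ca GV keeps rising at the most positive potentials
        (the HVA component) instead of saturating."""
        gv = A.extract_gv(low_ca_iv_recording)
        top = gv.normalized_conductance[-4:]
        assert np.all(np.diff(top) > 0.01)

    def test_non_double_pulse_rejected(self):
        rec = synthetic_recording(get_preset("rundown"))
        with pytest.raises(A.AnalysisError):
            A.extract_gv(rec)


class TestBoltzmannFit:
    def test_single_component_recovery_exact(self):
        v = np.arange(-100.0, 61.0, 10.0)
        gv = A.GVCurve(v, boltz(v, 0.0, [(-33.2, 9.2, 1.0)]), 2000.0)
        fit = A.fit_boltzmann(gv, 1)
        c = fit.components[0]
        assert c.v_half == pytest.approx(-33.2, abs=1e-6)
        assert c.k == pytest.approx(9.2, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_midpoint_identity(self):
        v = np.arange(-100.0, 61.0, 10.0)
        gv = A.GVCurve(v, boltz(v, 0.1, [(-30.0, 8.0, 0.8)]), 2000.0)
        fit = A.fit_boltzmann(gv, 1)
        c = fit.components[0]
        assert fit([c.v_half])[0] == pytest.approx(fit.offset + c.d / 2)

    def test_two_component_recovery_vs_grid_oracle(self):
        """Multi-start double fit against a coarse grid search."""
        v = np.arange(-100.0, 61.0, 10.0)
        truth = [(-40.0, 7.0, 0.7), (0.0, 25.0, 0.3)]
        y = boltz(v, 0.0, truth)
        fit = A.fit_boltzmann(A.GVCurve(v, y, 2000.0), 2)
        for comp, (vh, k, d) in zip(fit.components, truth):
            assert comp.v_half == pytest.approx(vh, abs=1e-4)
            assert comp.k == pytest.approx(k, abs=1e-4)
            assert comp.d == pytest.approx(d, abs=1e-4)
        # grid-search oracle: best grid node must not beat the fit
        best = np.inf
        for v1 in (-50, -40, -30):
            for v2 in (-10, 0, 10):
                for k1 in (5.0, 7.0, 9.0):
                    for k2 in (20.0, 25.0, 30.0):
                        r = y - boltz(v, 0.0, [(v1, k1, 0.7), (v2, k2, 0.3)])
                        best = min(best, float(r @ r))
        assert fit.residual_sse <= best + 1e-9

    def test_components_ordered_by_v_half(self, low_ca_iv_recording):
        fit = A.fit_boltzmann(A.extract_gv(low_ca_iv_recording), 2)
        assert fit.components[0].v_half < fit.components[1].v_half
        assert 5.0 <= fit.hva.k <= 60.0

    def test_too_few_points_rejected(self):
        v = np.arange(-40.0, 1.0, 10.0)
        gv = A.GVCurve(v, boltz(v, 0, [(-20, 9, 1)]), 2000.0)
        with pytest.raises(A.AnalysisError):
            A.fit_boltzmann(gv, 2)

    def test_unbiased_at_recording_noise(self):
        """Fits on GVs with the generator's default noise level are
        unbiased within Monte-Carlo error (100 replicates)."""
        rng = np.random.default_rng(7)
        v = np.arange(-100.0, 61.0, 10.0)
        truth = (-33.2, 9.2)
        est = []
        for _ in range(100):
            # 5 pA noise on ~600 pA tail amplitudes ~ 0.8% of range
            y = boltz(v, 0.0, [(truth[0], truth[1], 1.0)]) + rng.normal(0, 0.008, v.size)
            fit = A.fit_boltzmann(A.GVCurve(v, y, 2000.0), 1)
            est.append((fit.components[0].v_half, fit.components[0].k))
        est = np.array(est)
        se = est.std(axis=0) / 10.0
        assert abs(est[:, 0].mean() - truth[0]) < 3 * se[0] + 0.02
        assert abs(est[:, 1].mean() - truth[1]) < 3 * se[1] + 0.02


class TestOrderSelection:
    def test_single_component_data_selects_one(self):
        rng = np.random.default_rng(0)
        v = np.arange(-100.0, 61.0, 10.0)
        y = boltz(v, 0.0, [(-33.0, 9.0, 1.0)]) + rng.normal(0, 0.002, v.size)
        assert A.select_boltzmann_order(A.GVCurve(v, y, 2000.0)).order == 1

    def test_low_ca_model_gv_needs_double(self, low_ca_iv_recording):
        sel = A.select_boltzmann_order(A.extract_gv(low_ca_iv_recording))
        assert sel.order == 2
        assert sel.hva_amplitude >= 0.05

    def test_saturated_model_gv_single_adequate(self, wt_scheme):
        sel = A.select_boltzmann_order(P.model_gv(wt_scheme, ca=5e-6))
        assert sel.order == 1

    def test_false_double_rate_at_default_noise(self):
        """Operating characteristics: <= 10% double-Boltzmann selections on
        single-component data at the generator's noise level."""
        rng = np.random.default_rng(42)
        v = np.arange(-100.0, 61.0, 10.0)
        false_pos = 0
        n_rep = 40
        for _ in range(n_rep):
            y = boltz(v, 0.0, [(-33.0, 9.0, 1.0)]) + rng.normal(0, 0.008, v.size)
            if A.select_boltzmann_order(A.GVCurve(v, y, 2000.0)).order == 2:
                false_pos += 1
        assert false_pos / n_rep <= 0.10


class TestBiexponential:
    def test_pure_single_exponential_degenerates(self):
        t = np.arange(0.0, 500.0, 1.0)
        y = 10.0 + 200.0 * np.exp(-t / 80.0)
        fit = A.fit_biexponential(t, y)
        fast_first = abs(fit.amp_fast) > abs(fit.amp_slow)
        tau = fit.tau_fast if fast_first else fit.tau_slow
        amp_other = fit.amp_slow if fast_first else fit.amp_fast
        assert tau == pytest.approx(80.0, rel=1e-6)
        assert abs(amp_other) < 1e-3 * 200.0

    def test_two_time_constants_recovered(self):
        t = np.arange(0.0, 2000.0, 1.0)
        y = 5.0 + 300.0 * np.exp(-t / 50.0) + 150.0 * np.exp(-t / 400.0)
        fit = A.fit_biexponential(t, y)
        assert fit.tau_fast == pytest.approx(50.0, rel=1e-4)
        assert fit.tau_slow == pytest.approx(400.0, rel=1e-4)
        assert fit.tau_fast <= fit.tau_slow

    def test_v185m_activation_slower_than_wt(self):
        """The V185M variant activates more slowly at +40 mV (larger
        amplitude-weighted time constant)."""
        taus = {}
        for variant in ("WT", "V185M"):
            scheme = G.build_default_scheme(variant)
            rec = P.model_recording(scheme, "rundown", ca=P.EARLY_CA_M)
            mask = rec.segment_window_mask(1, 0.0, 500.0)
            t = rec.time_ms[mask]
            y = rec.sweeps[0][mask]
            taus[variant] = A.fit_biexponential(t, y, "activation").weighted_tau
        assert taus["V185M"] > taus["WT"]

    def test_short_segment_rejected(self):
        with pytest.raises(A.AnalysisError):
            A.fit_biexponential(np.arange(5.0), np.ones(5))


class TestRunDown:
    def test_constant_recording_no_rundown(self):
        rec = synthetic_recording(get_preset("rundown"), fill=500.0)
        rd = A.rundown_metric(rec)
        assert rd.relative_amplitude_at_window == pytest.approx(1.0)
        assert rd.sweep_amplitudes[0] == 1.0

    def test_linear_decay_closed_form(self):
        """10%/min linear decay -> window mean ~ 0.625 by construction."""
        prot = get_preset("rundown")
        rec = synthetic_recording(prot, fill=1.0)
        starts = prot.sweep_start_times_s()
        rec.sweeps[:] = (1.0 - 0.10 * starts / 60.0)[:, None]
        rd = A.rundown_metric(rec, window_s=(210.0, 240.0))
        expected = np.mean(1.0 - 0.10 * starts[(starts >= 210) & (starts <= 240)] / 60.0)
        assert rd.relative_amplitude_at_window == pytest.approx(expected)
        assert expected == pytest.approx(0.625, abs=0.005)

    def test_empty_window_rejected(self):
        rec = synthetic_recording(get_preset("rundown"))
        with pytest.raises(A.AnalysisError):
            A.rundown_metric(rec, window_s=(240.0, 210.0))


class TestCrossover:
    def test_monotone_profile_has_no_minimum(self):
        prot = get_preset("iv2s")
        rec = synthetic_recording(prot)
        rec.sweeps[:] = np.linspace(10, 100, prot.n_sweeps)[:, None]
        assert A.crossover_profile(rec).minimum_mV is None

    def test_low_ca_minimum_at_minus_30(self, low_ca_iv_recording):
        assert A.crossover_profile(low_ca_iv_recording).minimum_mV == -30.0

    def test_minimum_needs_at_least_three_sweeps(self):
        prot = get_preset("iv2s")
        rec = synthetic_recording(prot)
        two = Recording(rec.sweeps[:2], rec.time_ms, rec.voltage_mV[:2],
                        _truncate(prot, 2), 1.0)
        with pytest.raises(A.AnalysisError):
            A.crossover_profile(two)


def _truncate(prot, n):
    from kcnq1ca.protocols import VoltageProtocol
    return VoltageProtocol(prot.holding_mV, prot.sweeps[:n],
                           prot.inter_sweep_interval_ms)


class TestCurrentDensity:
    def test_simple_quotient(self):
        assert A.current_density(1200.0, 12.0) == 100.0

    def test_scale_invariance(self):
        assert A.current_density(2400.0, 24.0) == A.current_density(1200.0, 12.0)

    def test_zero_capacitance_rejected(self):
        with pytest.raises(A.AnalysisError):
            A.current_density(100.0, 0.0)
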