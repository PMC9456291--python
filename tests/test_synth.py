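import numpy as np
import pytest

from kcnq1ca import synth as SY
from kcnq1ca.analysis import (
    measure_amplitude,
    restoration_halftime_s,
    rundown_metric,
)
from kcnq1ca.synth import ConditionSpec, HIGH_CA_ICS, LOW_CA_ICS


def cond(**kw):
    return ConditionSpec(**{"variant": "WT", "ics_free_ca": LOW_CA_ICS, **kw})


class TestCaTimecourse:
    @pytest.mark.parametrize(
        "pre,ca0_nM", [("none", 100.0), ("egta_ringer", 30.0), ("bapta_am", 5.0)]
    )
    def test_initial_level_per_preincubation(self, pre, ca0_nM):
        c = cond(pre_incubation=pre)
        assert SY.intracellular_ca_timecourse(c, 0.0) == pytest.approx(ca0_nM * 1e-9)

    def test_long_time_limit_reaches_pipette_ca(self):
        c = cond(ics_free_ca=HIGH_CA_ICS)
        tau = SY.condition_table()["tau_wash_s"]["none"]
        ca = SY.intracellular_ca_timecourse(c, 10.0 * tau)
        assert ca == pytest.approx(HIGH_CA_ICS, rel=1e-4)

    def test_monotone_between_endpoints(self):
        c = cond()  # 100 nM -> 20 nM: monotone decreasing
        t = np.linspace(0.0, 400.0, 100)
        ca = SY.intracellular_ca_timecourse(c, t)
        assert np.all(np.diff(ca) < 0)
        assert np.all((ca >= LOW_CA_ICS) & (ca <= 100e-9))

    def test_negative_time_rejected(self):
        with pytest.raises(SY.SynthError):
            SY.intracellular_ca_timecourse(cond(), -1.0)

    def test_cam_overexpression_raises_effective_ca(self):
        c0, c1 = cond(), cond(cam_overexpressed=True)
        assert SY.effective_ca(c1, 0.0) > SY.effective_ca(c0, 0.0)


class TestAvailability:
    def test_starts_at_one(self):
        for c in (cond(), cond(cam_overexpressed=True), cond(ics_free_ca=HIGH_CA_ICS)):
            assert SY.availability_timecourse(c, 0.0) == pytest.approx(1.0)

    def test_standard_condition_runs_down(self):
        a = SY.availability_timecourse(cond(), np.array([0.0, 120.0, 240.0]))
        assert a[0] > a[1] > a[2]

    def test_high_ca_condition_runs_up(self):
        a = SY.availability_timecourse(
            cond(ics_free_ca=HIGH_CA_ICS), np.array([0.0, 225.0])
        )
        assert a[1] > 1.0


class TestGenerateRecording:
    def test_noiseless_generation_deterministic(self):
        r1 = SY.generate_recording(cond(), "rundown", noise_sd=0.0)
        r2 = SY.generate_recording(cond(), "rundown", noise_sd=0.0)
        np.testing.assert_array_equal(r1.sweeps, r2.sweeps)

    def test_same_seed_bit_identical(self):
        r1 = SY.generate_recording(cond(), "rundown", noise_sd=5.0, seed=11)
        r2 = SY.generate_recording(cond(), "rundown", noise_sd=5.0, seed=11)
        np.testing.assert_array_equal(r1.sweeps, r2.sweeps)

    def test_noise_requires_seed(self):
        with pytest.raises(SY.SynthError):
            SY.generate_recording(cond(), "rundown", noise_sd=5.0, seed=None)

    def test_unknown_condition_labels_rejected(self):
        with pytest.raises(SY.SynthError):
            ConditionSpec(variant="WT", pre_incubation="ionomycin")
        with pytest.raises(SY.SynthError):
            ConditionSpec(variant="G189R")

    def test_mutant_q1e2_exceeds_wt_q1e2_at_rest(self):
        """Disease variants raise the constitutive Q1E2 conductance."""
        amps = {}
        for variant in ("WT", "R116L", "V185M", "P369L"):
            rec = SY.generate_recording(
                cond(variant=variant, kcne2=True), "rundown", noise_sd=0.0
            )
            amps[variant] = measure_amplitude(rec, 1, 450.0, 50.0)[0]
        assert all(amps[m] > amps["WT"] for m in ("R116L", "V185M", "P369L"))

    def test_wt_q1e2_cam_high_ca_dramatic_runup(self):
        rec = SY.generate_recording(
            cond(kcne2=True, cam_overexpressed=True, ics_free_ca=HIGH_CA_ICS),
            "rundown", noise_sd=0.0,
        )
        amps = measure_amplitude(rec, 1, 450.0, 50.0)
        assert amps.max() / amps[0] > 3.0

    def test_bapta_wt_restores_slower_than_v185m(self):
        halftimes = {}
        for variant in ("WT", "V185M"):
            rec = SY.generate_recording(
                cond(variant=variant, ics_free_ca=HIGH_CA_ICS,
                     pre_incubation="bapta_am"),
                "rundown", noise_sd=0.0,
            )
            rd = rundown_metric(rec)
            halftimes[variant] = restoration_halftime_s(
                rd.sweep_amplitudes, rd.sweep_times_s
            )
        assert halftimes["WT"] > halftimes["V185M"]

    def test_e2_leak_near_linear_iv_with_sag(self):
        """The Q1E2 leak component has a near-linear IV with a slight
        time-dependent attenuation at positive potentials only."""
        from kcnq1ca.protocols import get_preset

        prot = get_preset("iv2s")
        c = cond(variant="P369L", kcne2=True)
        t = np.arange(0.0, prot.sweep_duration_ms, 1.0)
        inst, late = [], []
        for i in range(prot.n_sweeps):
            _, v = prot.sample_voltage(i, 1.0)
            leak = SY._e2_leak_sweep(c, prot, i, t, v, LOW_CA_ICS, g_e2=8.0)
            p1 = (t >= 50.0) & (t < 2050.0)
            inst.append(leak[p1][2:7].mean())
            late.append(leak[p1][-50:].mean())
        inst, late = np.array(inst), np.array(late)
        vs = np.array([sw[1].v0_mV for sw in prot.sweeps])
        assert np.all(late[vs >= 20] < inst[vs >= 20])  # sag when depolarized
        np.testing.assert_allclose(late[vs <= 0], inst[vs <= 0])  # none below 0
        r = np.corrcoef(vs - (-86.0), inst)[0, 1]  # near-linear leak IV
        assert r > 0.999


class TestCohort:
    def test_single_cell_cohort_matches_direct_generation(self):
        recs = SY.generate_cohort([cond()], 1, "rundown", base_seed=3, noise_sd=5.0)
        assert len(recs) == 1
        assert recs[0].seed is not None

    def test_disjoint_base_seeds_disjoint_recordings(self):
        r1 = SY.generate_cohort([cond()], 2, "rundown", base_seed=1, noise_sd=5.0)
        r2 = SY.generate_cohort([cond()], 2, "rundown", base_seed=2, noise_sd=5.0)
        for a in r1:
            for b in r2:
                assert not np.array_equal(a.sweeps, b.sweeps)

    def test_capacitance_and_expression_vary_across_cells(self):
        recs = SY.generate_cohort([cond()], 5, "rundown", base_seed=0, noise_sd=5.0)
        caps = {r.capacitance_pF for r in recs}
        assert len(caps) == 5

    def test_empty_condition_list_rejected(self):
        with pytest.raises(SY.SynthError):
            SY.generate_cohort([], 3, "rundown", base_seed=0)
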