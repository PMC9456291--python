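"""Tail-current analysis: isochronal GV extraction, Boltzmann and
biexponential fitting, run-down metrics and cross-over detection.

The conductance-voltage (GV) relation of isochronal activation is measured
from the instantaneous current at the start of the constant P2 pulse of a
double-pulse protocol: since the P2 potential is fixed, the instantaneous
tail amplitude is proportional to the open-channel fraction reached at the
end of the variable P1 pulse.  Normalized GV points are fitted with

    y(V) = c + sum_i d_i / (1 + exp(-(V - V0.5_i) / k_i))

with one component, or two for recordings exhibiting an additional
high-voltage-activated (HVA) component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .recording import Recording, RecordingError

#: default "instantaneous" tail window after P2 onset (skips the residual
#: capacitive settle; the figure insets do not resolve the first ms)
INSTANT_WINDOW_MS = (2.0, 5.0)  # offset, length
#: late-P2 amplitude window: final 50 ms of the P2 pulse
LATE_WINDOW_MS = 50.0
#: run-down tracer amplitude window: final 50 ms of the test pulse
RUNDOWN_WINDOW_MS = 50.0


class AnalysisError(ValueError):
    """Raised for inputs an analysis operation cannot interpret."""


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear fit fails; carries the best residual seen."""

    def __init__(self, msg: str, residual: float = np.nan):
        super().__init__(msg)
        self.residual = residual


# ---------------------------------------------------------------------------
# amplitudes


def measure_amplitude(
    recording: Recording,
    segment_index: int,
    window_offset_ms: float,
    window_len_ms: float,
) -> np.ndarray:
    """Mean current (pA) over a window of one segment, per sweep."""
    mask = recording.segment_window_mask(segment_index, window_offset_ms, window_len_ms)
    return recording.sweeps[:, mask].mean(axis=1)


def _double_pulse_indices(recording: Recording) -> tuple[int, int]:
    """(P1 segment index, P2 segment index) of a double-pulse recording."""
    segs = recording.protocol.sweeps
    if len(segs[0]) < 3:
        raise AnalysisError("not a double-pulse protocol (fewer than 3 segments)")
    p1, p2 = 1, 2
    p1_levels = [sw[p1].v0_mV for sw in segs]
    p2_levels = {(sw[p2].v0_mV, sw[p2].v1_mV) for sw in segs}
    if len(set(p1_levels)) < 2 or len(p2_levels) != 1:
        raise AnalysisError(
            "not a double-pulse family (variable P1 followed by constant P2 expected)"
        )
    return p1, p2


@dataclass
class GVCurve:
    """Normalized isochronal activation vs pre-pulse potential."""

    p1_potentials: np.ndarray
    normalized_conductance: np.ndarray
    isochrone_ms: float

    def __post_init__(self) -> None:
        self.p1_potentials = np.asarray(self.p1_potentials, dtype=float)
        self.normalized_conductance = np.asarray(
            self.normalized_conductance, dtype=float
        )
        if np.any(np.diff(self.p1_potentials) <= 0):
            raise AnalysisError("P1 potentials must be strictly increasing")


def extract_gv(recording: Recording) -> GVCurve:
    """Instantaneous P2 amplitudes, normalized to their maximum."""
    p1, p2 = _double_pulse_indices(recording)
    amps = measure_amplitude(recording, p2, *INSTANT_WINDOW_MS)
    vs = np.array([sw[p1].v0_mV for sw in recording.protocol.sweeps])
    order = np.argsort(vs)
    amps = amps[order]
    peak = np.max(np.abs(amps))
    if peak == 0:
        raise AnalysisError("flat zero recording; GV undefined")
    g = amps / amps[np.argmax(np.abs(amps))]
    return GVCurve(vs[order], g, recording.protocol.sweeps[0][p1].dur_ms)


# ---------------------------------------------------------------------------
# Boltzmann fits


@dataclass
class BoltzmannComponent:
    v_half: float
    k: float
    d: float


@dataclass
class BoltzmannFit:
    components: list[BoltzmannComponent]
    offset: float
    residual_sse: float
    aicc: float
    n_points: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def hva(self) -> BoltzmannComponent:
        """The higher-V0.5 (HVA) component; components are sorted ascending."""
        return self.components[-1]

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        y = np.full_like(v, self.offset)
        for comp in self.components:
            y = y + comp.d / (1.0 + np.exp(-(v - comp.v_half) / comp.k))
        return y


def _boltz_model(v, c, comps):
    y = np.full_like(v, c, dtype=float)
    for (vh, k, d) in comps:
        y = y + d / (1.0 + np.exp(-(v - vh) / k))
    return y


# deterministic multi-start grids (documented; no randomness in fitting)
_V_STARTS = (-60.0, -40.0, -20.0, 0.0, 20.0)
_K_STARTS = (5.0, 10.0, 25.0)


def _fit_once(v, y, n_components, starts):
    params = lmfit.Parameters()
    params.add("c", value=0.0, min=-0.5, max=0.5)
    span = v.max() - v.min()
    for i, (vh0, k0) in enumerate(starts):
        params.add(f"vh{i}", value=vh0, min=v.min() - span, max=v.max() + span)
        # HVA slope bounded to (5, 60) mV to prevent component collapse
        kmin, kmax = (5.0, 60.0) if (n_components == 2 and i == 1) else (1.0, 60.0)
        params.add(f"k{i}", value=float(np.clip(k0, kmin, kmax)), min=kmin, max=kmax)
        params.add(f"d{i}", value=1.0 / n_components, min=0.0, max=2.0)

    def resid(p):
        comps = [
            (p[f"vh{i}"].value, p[f"k{i}"].value, p[f"d{i}"].value)
            for i in range(n_components)
        ]
        return _boltz_model(v, p["c"].value, comps) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    return out


def fit_boltzmann(gv: GVCurve, n_components: int = 1) -> BoltzmannFit:
    """Least-squares Boltzmann fit from a documented multi-start grid."""
    if n_components not in (1, 2):
        raise AnalysisError("n_components must be 1 or 2")
    v = gv.p1_potentials
    y = gv.normalized_conductance
    if v.size < 2 * (2 * n_components) + 1:
        raise AnalysisError(
            f"need at least {2 * (2 * n_components) + 1} points for "
            f"{n_components} component(s), got {v.size}"
        )
    if n_components == 1:
        start_sets = [[(vh, k)] for vh in _V_STARTS for k in _K_STARTS]
    else:
        start_sets = [
            [(v1, k1), (v2, k2)]
            for v1 in _V_STARTS
            for v2 in _V_STARTS
            if v1 < v2
            for k1 in (5.0, 10.0)
            for k2 in (10.0, 25.0)
        ]
    best = None
    for starts in start_sets:
        try:
            out = _fit_once(v, y, n_components, starts)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise FitConvergenceError(
            "Boltzmann fit did not converge",
            residual=np.nan if best is None else best.chisqr,
        )
    p = best.params
    comps = sorted(
        (
            BoltzmannComponent(p[f"vh{i}"].value, p[f"k{i}"].value, p[f"d{i}"].value)
            for i in range(n_components)
        ),
        key=lambda cpn: cpn.v_half,
    )
    n = v.size
    n_par = 1 + 3 * n_components
    sse = float(best.chisqr)
    with np.errstate(divide="ignore"):
        aic = n * np.log(max(sse, 1e-300) / n) + 2 * n_par
    aicc = aic + (2 * n_par * (n_par + 1)) / max(n - n_par - 1, 1)
    return BoltzmannFit(comps, float(p["c"].value), sse, float(aicc), n)


@dataclass
class OrderSelection:
    order: int
    f_stat: float
    p_value: float
    hva_amplitude: float
    fits: dict


def select_boltzmann_order(gv: GVCurve, alpha: float = 0.05) -> OrderSelection:
    """Single vs double Boltzmann by the extra-sum-of-squares F-test.

    Returns order 2 only when the F-test favors the double fit at ``alpha``
    AND the HVA component carries at least 5% of the total amplitude.
    """
    from scipy.stats import f as f_dist

    fit1 = fit_boltzmann(gv, 1)
    n = fit1.n_points
    sse1 = fit1.residual_sse
    # adequacy guard: a single Boltzmann whose RMS deviation is below 1.5%
    # of the normalized amplitude "adequately describes" the data
    if np.sqrt(sse1 / n) <= 0.015:
        return OrderSelection(1, 0.0, 1.0, 0.0, {1: fit1})
    fit2 = fit_boltzmann(gv, 2)
    p1n, p2n = 4, 7
    sse2 = fit2.residual_sse
    if sse2 <= 0:
        f_stat, p_val = np.inf, 0.0
    else:
        f_stat = ((sse1 - sse2) / (p2n - p1n)) / (sse2 / (n - p2n))
        p_val = float(f_dist.sf(f_stat, p2n - p1n, n - p2n)) if f_stat > 0 else 1.0
    total_amp = sum(c.d for c in fit2.components)
    hva_frac = fit2.hva.d / total_amp if total_amp > 0 else 0.0
    order = 2 if (p_val < alpha and hva_frac >= 0.05) else 1
    return OrderSelection(order, float(f_stat), p_val, hva_frac, {1: fit1, 2: fit2})


# ---------------------------------------------------------------------------
# biexponential kinetics


@dataclass
class BiexpFit:
    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    offset: float
    residual_sse: float

    @property
    def weighted_tau(self) -> float:
        wsum = abs(self.amp_fast) + abs(self.amp_slow)
        if wsum == 0:
            return self.tau_fast
        return (abs(self.amp_fast) * self.tau_fast + abs(self.amp_slow) * self.tau_slow) / wsum

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.offset
            + self.amp_fast * np.exp(-t / self.tau_fast)
            + self.amp_slow * np.exp(-t / self.tau_slow)
        )


def fit_biexponential(
    time_ms: np.ndarray, current: np.ndarray, direction: str = "activation"
) -> BiexpFit:
    """Double-exponential fit with tau_fast <= tau_slow enforced.

    ``direction`` is metadata ('activation' or 'deactivation'); the second
    amplitude may converge to ~0, i.e. a single exponential is an admissible
    degenerate outcome.
    """
    if direction not in ("activation", "deactivation"):
        raise AnalysisError("direction must be 'activation' or 'deactivation'")
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size < 10:
        raise AnalysisError("segment too short for a biexponential fit (< 10 samples)")
    t = t - t[0]
    span = max(t[-1], 1.0)
    scale = max(np.ptp(y), 1e-12)

    best = None
    for tf0 in (span / 50, span / 10, span / 4):
        for ratio0 in (4.0, 10.0):
            params = lmfit.Parameters()
            params.add("off", value=float(y[-1]))
            params.add("af", value=float(y[0] - y[-1]), min=-10 * scale, max=10 * scale)
            params.add("as_", value=0.1 * float(y[0] - y[-1]), min=-10 * scale, max=10 * scale)
            params.add("tf", value=tf0, min=1e-3, max=10 * span)
            params.add("dts", value=tf0 * (ratio0 - 1), min=0.0, max=100 * span)

            def resid(p):
                ts = p["tf"].value + p["dts"].value
                return (
                    p["off"].value
                    + p["af"].value * np.exp(-t / p["tf"].value)
                    + p["as_"].value * np.exp(-t / ts)
                    - y
                )

            try:
                out = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
    if best is None:
        raise FitConvergenceError("biexponential fit did not converge")
    p = best.params
    tf = float(p["tf"].value)
    ts = tf + float(p["dts"].value)
    return BiexpFit(
        tau_fast=tf,
        tau_slow=ts,
        amp_fast=float(p["af"].value),
        amp_slow=float(p["as_"].value),
        offset=float(p["off"].value),
        residual_sse=float(best.chisqr),
    )


# ---------------------------------------------------------------------------
# run-down and cross-over


@dataclass
class RunDownResult:
    relative_amplitude_at_window: float
    window_s: tuple
    sweep_amplitudes: np.ndarray
    sweep_times_s: np.ndarray

    @property
    def percent_rundown(self) -> float:
        return 100.0 * (1.0 - self.relative_amplitude_at_window)


def rundown_metric(
    recording: Recording, window_s: tuple = (210.0, 240.0), test_segment: int = 1
) -> RunDownResult:
    """Relative current amplitude in a late time window, sweep 1 = 1.0.

    Amplitudes are measured over the final 50 ms of the test pulse; the
    window selects sweeps by their absolute start time (run-down clock).
    """
    lo, hi = window_s
    if hi <= lo:
        raise AnalysisError("empty run-down window")
    seg = recording.protocol.sweeps[0][test_segment]
    amps = measure_amplitude(
        recording, test_segment, seg.dur_ms - RUNDOWN_WINDOW_MS, RUNDOWN_WINDOW_MS
    )
    if amps[0] == 0:
        raise AnalysisError("first-sweep amplitude is zero; cannot normalize")
    rel = amps / amps[0]
    t = recording.sweep_start_s
    in_win = (t >= lo) & (t <= hi)
    if not in_win.any():
        raise AnalysisError("no sweeps start inside the run-down window")
    return RunDownResult(float(rel[in_win].mean()), (lo, hi), rel, t)


@dataclass
class CrossoverProfile:
    p1_potentials: np.ndarray
    late_amplitudes: np.ndarray
    minimum_mV: float | None


def crossover_profile(recording: Recording) -> CrossoverProfile:
    """Late-P2 amplitude vs P1 potential; interior-minimum detection.

    The characteristic cross-over of current traces at low intracellular
    Ca2+ shows up as an interior minimum of the late-P2 amplitude profile;
    a point qualifies when it lies below both neighbors by more than 2% of
    the profile range.
    """
    if recording.n_sweeps < 3:
        raise AnalysisError("need at least 3 sweeps for a cross-over profile")
    p1, p2 = _double_pulse_indices(recording)
    seg = recording.protocol.sweeps[0][p2]
    amps = measure_amplitude(recording, p2, seg.dur_ms - LATE_WINDOW_MS, LATE_WINDOW_MS)
    vs = np.array([sw[p1].v0_mV for sw in recording.protocol.sweeps])
    order = np.argsort(vs)
    vs, amps = vs[order], amps[order]
    rng = np.ptp(amps)
    min_idx = None
    if rng > 0:
        for i in range(1, len(amps) - 1):
            if (
                amps[i] < amps[i - 1] - 0.02 * rng
                and amps[i] < amps[i + 1] - 0.02 * rng
            ):
                if min_idx is None or amps[i] < amps[min_idx]:
                    min_idx = i
    minimum = None if min_idx is None else float(vs[min_idx])
    return CrossoverProfile(vs, amps, minimum)


def current_density(amplitude_pA: float, capacitance_pF: float) -> float:
    """Current density in pA/pF."""
    if capacitance_pF <= 0:
        raise AnalysisError("capacitance must be > 0")
    return amplitude_pA / capacitance_pF


def restoration_halftime_s(
    sweep_amplitudes: np.ndarray, sweep_times_s: np.ndarray
) -> float:
    """First time at which the amplitude reaches halfway from initial to max.

    Used for the Ca2+-loading (run-up) experiments; returns 0 when the
    recording starts at its maximum.
    """
    a = np.asarray(sweep_amplitudes, dtype=float)
    half = a[0] + 0.5 * (a.max() - a[0])
    idx = np.nonzero(a >= half)[0]
    return float(sweep_times_s[idx[0]]) if idx.size else float(sweep_times_s[-1])
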