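"""Synthetic whole-cell recordings under the study's experimental conditions.

The generator emulates CHO-cell (or GH3/B6) recordings of KCNQ1 channel
variants with optional KCNE2 co-expression and calmodulin overexpression,
pipette solutions buffered to ~20 nM or 5 uM free Ca2+, and optional
low-Ca2+ pre-incubation (EGTA-Ringer bath or BAPTA-AM loading).  It composes

* the Markov gating model, simulated sweep-by-sweep at the instantaneous
  intracellular Ca2+ (quasi-static: each sweep starts from the holding
  steady state at its own Ca2+ level; the Ca2+ wash-in time constant is
  orders of magnitude slower than a sweep),
* an exponential wash-in of the pipette Ca2+ into the cytosol,
* a multiplicative wash-out ("run-down") factor with a condition-specific
  plateau, representing loss of cytosolic cofactors distinct from Ca2+,
* a phenomenological KCNE2 leak conductance whose availability tracks
  Ca2+-CaM with a much higher Ca2+ demand than the homomeric channel, and
* additive Gaussian recording noise (NumPy PCG64 generator, seed-stable).

Pre-incubated cells start their first sweep from the model steady state at
a depolarized unpatched resting potential, which places low-Ca2+ cells deep
in the starved/trapped states and reproduces the small initial currents and
subsequent run-up seen with EGTA-Ringer or BAPTA loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from importlib import resources

import numpy as np

from . import gating
from .gating import (
    CaSensor,
    GatingScheme,
    build_default_scheme,
    current_from_occupancy,
    simulate,
    steady_state,
)
from .protocols import VoltageProtocol, get_preset, make_pulse_train
from .recording import Recording

PRE_INCUBATIONS = ("none", "egta_ringer", "bapta_am")
CELL_LINES = ("CHO", "GH3B6")

#: nominal free Ca2+ of the two pipette solutions (molar)
LOW_CA_ICS = 20e-9
HIGH_CA_ICS = 5e-6

DEFAULT_GMAX_NS = 20.0
DEFAULT_EK_MV = -86.0
DEFAULT_NOISE_SD_PA = 5.0
DEFAULT_CAPACITANCE_PF = 12.0

# cohort variability (documented, arbitrary): lognormal capacitance and
# expression level to mimic the considerable cell-to-cell amplitude spread
CAP_LOGNORM = (np.log(12.0), 0.35)
GMAX_LOGNORM = (np.log(DEFAULT_GMAX_NS), 0.5)

# KCNE2 phenomenology: heteromeric channels are modelled as a strongly
# suppressed homomer current plus a near-linear leak conductance gated by
# Ca2+-CaM with a high Ca2+ demand
E2_MARKOV_SCALE = 0.15
E2_GMAX_NS = 8.0
E2_SENSOR = CaSensor(kd=5e-6, hill_n=1.5)
E2_SAG_AMPLITUDE = 0.15
E2_SAG_TAU_MS = 200.0
GH3B6_LEAK_NS = 1.0
GH3B6_LEAK_EREV_MV = -40.0


class SynthError(ValueError):
    """Raised for invalid generator conditions."""


def _load_condition_table() -> dict:
    with resources.files("kcnq1ca.data").joinpath("condition_table.json").open() as fh:
        return json.load(fh)


_TABLE = None


def condition_table() -> dict:
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_condition_table()
    return _TABLE


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the study."""

    variant: str = "WT"
    kcne2: bool = False
    cam_overexpressed: bool = False
    ics_free_ca: float = LOW_CA_ICS  # molar
    pre_incubation: str = "none"
    cell_line: str = "CHO"

    def __post_init__(self) -> None:
        if self.variant not in gating.VARIANTS:
            raise SynthError(f"unknown variant {self.variant!r}")
        if self.pre_incubation not in PRE_INCUBATIONS:
            raise SynthError(f"unknown pre_incubation {self.pre_incubation!r}")
        if self.cell_line not in CELL_LINES:
            raise SynthError(f"unknown cell_line {self.cell_line!r}")
        if not self.ics_free_ca > 0:
            raise SynthError("ics_free_ca must be > 0")

    @property
    def ca_class(self) -> str:
        return "high" if self.ics_free_ca >= 1e-6 else "low"

    def key(self) -> str:
        return (
            f"{self.variant}|e2={int(self.kcne2)}|cam={int(self.cam_overexpressed)}"
            f"|ca={self.ca_class}|pre={self.pre_incubation}"
        )

    def to_dict(self) -> dict:
        return asdict(self)


def wash_plateau(condition: ConditionSpec) -> float:
    tab = condition_table()
    return float(tab["plateaus"].get(condition.key(), tab["default_plateau"]))


def intracellular_ca_timecourse(
    condition: ConditionSpec, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Free cytosolic Ca2+ (molar) during pipette wash-in.

    Exponential relaxation from the pre-incubation-determined initial level
    towards the pipette free Ca2+ with time constant tau_wash.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise SynthError("time must be >= 0")
    tab = condition_table()
    ca0 = tab["initial_ca_nM"][condition.pre_incubation] * 1e-9
    tau = tab["tau_wash_s"][condition.pre_incubation]
    ca = condition.ics_free_ca + (ca0 - condition.ics_free_ca) * np.exp(-t / tau)
    return float(ca) if ca.ndim == 0 else ca


def effective_ca(condition: ConditionSpec, t_s: float | np.ndarray):
    """Ca2+ seen by the channel's CaM sensor; CaM overexpression raises the
    effective calcified-CaM availability, modelled as a Ca2+ gain."""
    ca = intracellular_ca_timecourse(condition, t_s)
    if condition.cam_overexpressed:
        ca = ca * condition_table()["cam_ca_gain"]
    return ca


def scheme_for(condition: ConditionSpec) -> GatingScheme:
    return build_default_scheme(condition.variant, include_starved_layer=True)


def _wash_factor(condition: ConditionSpec, t_s: np.ndarray) -> np.ndarray:
    tab = condition_table()
    p = wash_plateau(condition)
    return p + (1.0 - p) * np.exp(-np.asarray(t_s, float) / tab["tau_rundown_s"])


# -- quasi-static test-pulse amplitude of the gating model ------------------

_AMP_CACHE: dict = {}


def _single_test_sweep() -> VoltageProtocol:
    return make_pulse_train(n_sweeps=1, name="rundown-1")


def model_pulse_amplitude(scheme: GatingScheme, ca: float) -> float:
    """Conducting amplitude at the end of a 500 ms +40 mV test pulse.

    Mean weighted conducting occupancy times driving force over the final
    50 ms of the test pulse, starting from the holding steady state at the
    given fixed Ca2+.  This is the quasi-static amplitude the run-down
    tracer reads out, and the Ca2+-dependent gain entering the availability
    time course.
    """
    key = (hash(scheme.to_json()), round(float(np.log10(ca)), 9))
    if key not in _AMP_CACHE:
        prot = _single_test_sweep()
        tr = simulate(scheme, prot, ca=ca, dt_out=1.0)[0]
        cur = current_from_occupancy(tr, 1.0, DEFAULT_EK_MV, weights=scheme.conducting_weights)
        sel = (tr.time_ms >= 500.0) & (tr.time_ms < 550.0)  # last 50 ms of test pulse
        _AMP_CACHE[key] = float(cur[sel].mean())
    return _AMP_CACHE[key]


def availability_timecourse(
    condition: ConditionSpec, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Relative channel availability (1.0 at t = 0).

    Composes the wash-out run-down factor with the Ca2+-dependent gain of
    the gating model (quasi-static test-pulse amplitude at the current
    effective Ca2+, normalized to its value at break-in).
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    if np.any(t < 0):
        raise SynthError("time must be >= 0")
    scheme = scheme_for(condition)
    a0 = model_pulse_amplitude(scheme, float(np.asarray(effective_ca(condition, 0.0))))
    gains = np.array(
        [model_pulse_amplitude(scheme, float(np.asarray(effective_ca(condition, ti)))) for ti in t]
    )
    out = _wash_factor(condition, t) * gains / a0
    return float(out[0]) if np.isscalar(t_s) or np.asarray(t_s).ndim == 0 else out


# -- recording generation ---------------------------------------------------

def _e2_availability(condition: ConditionSpec, ca_eff: float) -> float:
    """Ca2+-CaM-dependent availability of the phenomenological Q1E2 leak."""
    f = float(E2_SENSOR.f(ca_eff))
    v = condition.variant
    if v == "WT":
        cam_fac = 1.0 if condition.cam_overexpressed else 0.25
        return 0.08 + 0.92 * f * cam_fac
    if v == "V185M":
        return 0.50 + 0.50 * f
    if v == "R116L":
        cam_fac = 1.0 if condition.cam_overexpressed else 0.3
        return 0.50 + 0.50 * f * cam_fac
    return 0.55  # P369L: constitutive, Ca2+-independent


def _e2_leak_sweep(
    condition: ConditionSpec,
    protocol: VoltageProtocol,
    isweep: int,
    time_ms: np.ndarray,
    voltage: np.ndarray,
    ca_eff: float,
    g_e2: float,
) -> np.ndarray:
    """Near-linear leak with a slight time-dependent sag at positive V."""
    avail = _e2_availability(condition, ca_eff)
    cur = g_e2 * avail * (voltage - DEFAULT_EK_MV)
    onsets = protocol.segment_onsets_ms()
    segs = protocol.sweeps[isweep]
    for seg, onset in zip(segs, onsets):
        if seg.v0_mV > 0 or seg.v1_mV > 0:
            m = (time_ms >= onset) & (time_ms < onset + seg.dur_ms)
            t_seg = time_ms[m] - onset
            vmax = max(seg.v0_mV, seg.v1_mV)
            sag = E2_SAG_AMPLITUDE * min(vmax, 60.0) / 60.0
            cur[m] *= 1.0 - sag * (1.0 - np.exp(-t_seg / E2_SAG_TAU_MS))
    return cur


def generate_recording(
    condition: ConditionSpec,
    protocol: VoltageProtocol | str = "rundown",
    noise_sd: float = 0.0,
    seed: int | None = None,
    g_max: float = DEFAULT_GMAX_NS,
    capacitance_pF: float = DEFAULT_CAPACITANCE_PF,
    e_k: float = DEFAULT_EK_MV,
) -> Recording:
    """Synthetic whole-cell recording for one cell under one condition.

    With ``noise_sd`` = 0 the output is fully deterministic; otherwise a
    seed is required and identical seeds give bit-identical recordings.
    """
    if noise_sd > 0 and seed is None:
        raise SynthError("a seed is required when noise_sd > 0")
    if isinstance(protocol, str):
        protocol = get_preset(protocol)
    scheme = scheme_for(condition)
    starts = protocol.sweep_start_times_s()

    def ca_fn(t_s: float) -> float:
        # quasi-static: the Ca2+ level is evaluated once per sweep (at the
        # sweep start), consistent with the per-sweep holding reset
        i = int(np.searchsorted(starts, t_s + 1e-9, side="right")) - 1
        return float(np.asarray(effective_ca(condition, float(starts[max(i, 0)]))))

    p0 = None
    if condition.pre_incubation != "none":
        # pre-incubated cells sat for >=30 min at low Ca2+ and an unpatched,
        # relatively depolarized resting potential
        rest = condition_table()["preincubation_rest_mV"]
        p0 = steady_state(scheme, rest, ca_fn(0.0))

    traces = simulate(scheme, protocol, ca=ca_fn, dt_out=1.0, p0=p0, carryover=False)
    w = scheme.conducting_weights
    starts = protocol.sweep_start_times_s()
    wash = _wash_factor(condition, starts)

    sweeps = []
    volts = []
    for isw, tr in enumerate(traces):
        cur = wash[isw] * current_from_occupancy(tr, g_max, e_k, weights=w)
        if condition.kcne2:
            cur = E2_MARKOV_SCALE * cur + wash[isw] * _e2_leak_sweep(
                condition, protocol, isw, tr.time_ms, tr.voltage_mV,
                ca_fn(starts[isw]), g_e2=g_max / DEFAULT_GMAX_NS * E2_GMAX_NS,
            )
        if condition.cell_line == "GH3B6":
            cur = cur + GH3B6_LEAK_NS * (tr.voltage_mV - GH3B6_LEAK_EREV_MV)
        sweeps.append(cur)
        volts.append(tr.voltage_mV)
    sweeps = np.vstack(sweeps)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sweeps = sweeps + rng.normal(0.0, noise_sd, size=sweeps.shape)

    return Recording(
        sweeps=sweeps,
        time_ms=traces[0].time_ms,
        voltage_mV=np.vstack(volts),
        protocol=protocol,
        sampling_interval_ms=1.0,
        condition={**condition.to_dict(), "g_max_nS": g_max, "noise_sd_pA": noise_sd},
        capacitance_pF=capacitance_pF,
        seed=seed,
    )


def generate_cohort(
    conditions: list[ConditionSpec],
    n_per_condition: int,
    protocol: VoltageProtocol | str = "rundown",
    base_seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
) -> list[Recording]:
    """Cohort of cells with lognormal capacitance and expression spread.

    Per-cell seeds are derived deterministically from ``base_seed`` via
    NumPy's SeedSequence spawning, so disjoint base seeds give disjoint
    cohorts.
    """
    if not conditions:
        raise SynthError("empty condition list")
    if n_per_condition < 1:
        raise SynthError("n_per_condition must be >= 1")
    if isinstance(protocol, str):
        protocol = get_preset(protocol)
    recs = []
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(conditions) * n_per_condition)
    i = 0
    for cond in conditions:
        for _ in range(n_per_condition):
            child = children[i]
            i += 1
            rng = np.random.default_rng(child)
            cap = float(rng.lognormal(*CAP_LOGNORM))
            gmax = float(rng.lognormal(*GMAX_LOGNORM))
            cell_seed = int(child.generate_state(1)[0] % (2**31))
            recs.append(
                generate_recording(
                    cond, protocol, noise_sd=noise_sd, seed=cell_seed,
                    g_max=gmax, capacitance_pF=cap,
                )
            )
    return recs
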