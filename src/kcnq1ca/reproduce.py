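"""End-to-end reproduction of the study's quantitative anchors.

Every target is recomputed from scratch by running the calibrated model
and the analysis pipeline: simulate the voltage protocol, generate the
synthetic recording where the anchor concerns whole-cell time courses,
then measure with the same trace-analysis operations used throughout.
All computations are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import pipelines, synth
from .analysis import fit_boltzmann, crossover_profile, rundown_metric
from .gating import build_default_scheme
from .synth import ConditionSpec, HIGH_CA_ICS, LOW_CA_ICS


def _standard_condition(**kw) -> ConditionSpec:
    return ConditionSpec(**{"variant": "WT", "ics_free_ca": LOW_CA_ICS, **kw})


def early_recording_ca() -> float:
    """Intracellular free Ca2+ right after break-in, no pre-incubation."""
    return float(np.asarray(synth.intracellular_ca_timecourse(_standard_condition(), 0.0)))


def washed_out_ca(minutes: float = 5.0) -> float:
    """Intracellular free Ca2+ after several minutes of pipette wash-out."""
    return float(
        np.asarray(synth.intracellular_ca_timecourse(_standard_condition(), 60.0 * minutes))
    )


# -- target computations ----------------------------------------------------

def gv_v05(variant: str, ca: float) -> tuple[float, int]:
    scheme = build_default_scheme(variant, include_starved_layer=True)
    gv = pipelines.model_gv(scheme, ca=ca)
    fit = fit_boltzmann(gv, 1)
    return float(fit.components[0].v_half), gv.p1_potentials.size


def t1() -> tuple[float, int]:
    return gv_v05("WT", early_recording_ca())


def t2() -> tuple[float, int]:
    return gv_v05("V185M", early_recording_ca())


def t3() -> tuple[float, int]:
    return gv_v05("WT", HIGH_CA_ICS)


def _rundown_percent(condition: ConditionSpec) -> tuple[float, int]:
    rec = synth.generate_recording(condition, "rundown", noise_sd=0.0)
    rd = rundown_metric(rec, window_s=(210.0, 240.0))
    return rd.relative_amplitude_at_window, rec.n_sweeps


def t6() -> tuple[float, int]:
    rel, n = _rundown_percent(_standard_condition())
    return 100.0 * (1.0 - rel), n


def t7() -> tuple[float, int]:
    rel, n = _rundown_percent(_standard_condition(cam_overexpressed=True))
    return 100.0 * (1.0 - rel), n


def t8() -> tuple[float, int]:
    rel, n = _rundown_percent(_standard_condition(ics_free_ca=HIGH_CA_ICS))
    return 100.0 * rel, n


def _low_ca_recording():
    scheme = build_default_scheme("WT", include_starved_layer=True)
    return pipelines.model_recording(scheme, "iv2s", ca=washed_out_ca())


def t9() -> tuple[float, int]:
    rec = _low_ca_recording()
    prof = crossover_profile(rec)
    if prof.minimum_mV is None:
        raise RuntimeError("no cross-over minimum found in the low-Ca profile")
    return float(prof.minimum_mV), rec.n_sweeps


def t10() -> tuple[float, int]:
    from .analysis import extract_gv

    rec = _low_ca_recording()
    fit = fit_boltzmann(extract_gv(rec), 2)
    return float(fit.hva.k), rec.n_sweeps


@dataclass(frozen=True)
class Target:
    tid: str
    description: str
    units: str
    reference: float  # the study's printed value
    tolerance: float  # absolute, for the local pass/fail report
    fn: Callable[[], tuple[float, int]]


TARGETS: dict[str, Target] = {
    t.tid: t
    for t in [
        Target("t1", "WT isochronal GV V0.5, early recording (standard ICS)",
               "mV", -33.2, 0.7, t1),
        Target("t2", "V185M isochronal GV V0.5, early recording",
               "mV", -29.0, 0.6, t2),
        Target("t3", "WT isochronal GV V0.5, CaM + high-Ca2+ ICS (saturated)",
               "mV", -39.6, 0.8, t3),
        Target("t6", "percent run-down at 3.5-4 min, WT standard ICS",
               "%", 37.3, 0.8, t6),
        Target("t7", "percent run-down at 3.5-4 min, WT + CaM, standard ICS",
               "%", 20.4, 0.5, t7),
        Target("t8", "relative 4-min amplitude, WT high-Ca2+ ICS",
               "%", 112.0, 2.3, t8),
        Target("t9", "P1 potential of the late-P2 cross-over minimum, low Ca2+",
               "mV", -30.0, 0.5, t9),
        Target("t10", "slope factor k of the HVA component, low Ca2+",
               "mV", 25.0, 0.6, t10),
    ]
}


def reproduce(target_ids: list[str] | None = None) -> list[dict]:
    """Recompute targets and compare with the printed reference values."""
    ids = list(TARGETS) if target_ids is None else target_ids
    rows = []
    for tid in ids:
        if tid not in TARGETS:
            raise KeyError(f"unknown target id {tid!r}; known: {list(TARGETS)}")
        t = TARGETS[tid]
        value, n = t.fn()
        rows.append(
            {
                "id": tid,
                "description": t.description,
                "units": t.units,
                "value": round(value, 4),
                "reference": t.reference,
                "abs_error": round(abs(value - t.reference), 4),
                "tolerance": t.tolerance,
                "n": n,
                "pass": bool(abs(value - t.reference) <= t.tolerance),
            }
        )
    return rows
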