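"""Model-to-analysis glue: simulate a protocol and package the current as a
noiseless Recording so every trace-analysis operation applies unchanged to
pure model output.  These helpers are the canonical path used by the
calibration, the analysis scripts and the reproduction targets.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .gating import GatingScheme, simulate, current_from_occupancy
from .protocols import VoltageProtocol, get_preset
from .recording import Recording
from .analysis import GVCurve, extract_gv, crossover_profile, CrossoverProfile

#: intracellular free Ca2+ shortly after break-in with no pre-incubation
EARLY_CA_M = 100e-9
#: default conductance scale and K+ reversal used for model recordings
DEFAULT_GMAX_NS = 20.0
DEFAULT_EK_MV = -86.0


def model_recording(
    scheme: GatingScheme,
    protocol: VoltageProtocol | str = "iv2s",
    ca: float | Callable[[float], float] = EARLY_CA_M,
    g_max: float = DEFAULT_GMAX_NS,
    e_k: float = DEFAULT_EK_MV,
    dt_out: float = 1.0,
    carryover: bool = True,
    capacitance_pF: float = 12.0,
) -> Recording:
    """Noiseless Recording of a protocol simulated from the gating model."""
    if isinstance(protocol, str):
        protocol = get_preset(protocol)
    traces = simulate(scheme, protocol, ca=ca, dt_out=dt_out, carryover=carryover)
    w = scheme.conducting_weights
    cur = np.vstack([current_from_occupancy(tr, g_max, e_k, weights=w) for tr in traces])
    volt = np.vstack([tr.voltage_mV for tr in traces])
    return Recording(
        sweeps=cur,
        time_ms=traces[0].time_ms,
        voltage_mV=volt,
        protocol=protocol,
        sampling_interval_ms=dt_out,
        condition={"source": "model", "scheme": scheme.name, "ca_molar": None if callable(ca) else ca},
        capacitance_pF=capacitance_pF,
    )


def model_gv(
    scheme: GatingScheme,
    ca: float = EARLY_CA_M,
    protocol: VoltageProtocol | str = "iv2s",
) -> GVCurve:
    """Isochronal GV of the model under a double-pulse protocol."""
    return extract_gv(model_recording(scheme, protocol, ca=ca))


def model_crossover(
    scheme: GatingScheme,
    ca: float,
    protocol: VoltageProtocol | str = "iv2s",
) -> CrossoverProfile:
    """Late-P2 amplitude profile of the model under a double-pulse protocol."""
    return crossover_profile(model_recording(scheme, protocol, ca=ca))
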