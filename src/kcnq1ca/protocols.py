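"""Sweep-structured command-voltage programs for whole-cell voltage clamp.

A protocol is a list of sweeps, each a list of piecewise-linear segments
(duration, start voltage, end voltage).  All sweeps of a protocol share the
same segment count and durations; only the voltages differ (e.g. the variable
P1 pulse of a double-pulse IV family).  Command voltages are membrane
potentials, i.e. they are assumed to be already corrected for the liquid
junction potential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: settle time spent at the holding potential at the start of every sweep so
#: that simulations begin from the holding steady state (ms)
HOLD_SETTLE_MS = 50.0

V_LIMIT_MV = 200.0


class ProtocolError(ValueError):
    """Raised for invalid protocol definitions."""


@dataclass(frozen=True)
class Segment:
    """One piecewise-linear command segment."""

    dur_ms: float
    v0_mV: float
    v1_mV: float

    def __post_init__(self) -> None:
        if not self.dur_ms > 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.dur_ms}")
        for v in (self.v0_mV, self.v1_mV):
            if not np.isfinite(v) or abs(v) > V_LIMIT_MV:
                raise ProtocolError(f"segment voltage {v} outside +/-{V_LIMIT_MV} mV")

    @property
    def is_ramp(self) -> bool:
        return self.v0_mV != self.v1_mV

    def voltage_at(self, t_ms: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of the command voltage within the segment."""
        frac = np.clip(np.asarray(t_ms, dtype=float) / self.dur_ms, 0.0, 1.0)
        return self.v0_mV + (self.v1_mV - self.v0_mV) * frac


@dataclass(frozen=True)
class VoltageProtocol:
    """A family of sweeps with identical timing and varying voltages."""

    holding_mV: float
    sweeps: tuple[tuple[Segment, ...], ...]
    inter_sweep_interval_ms: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sweeps) == 0:
            raise ProtocolError("protocol must contain at least one sweep")
        durs0 = [s.dur_ms for s in self.sweeps[0]]
        if not durs0:
            raise ProtocolError("sweeps must contain at least one segment")
        for sw in self.sweeps:
            if [s.dur_ms for s in sw] != durs0:
                raise ProtocolError("all sweeps must share segment count and durations")
        if self.inter_sweep_interval_ms < 0:
            raise ProtocolError("inter_sweep_interval_ms must be >= 0")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def sweep_duration_ms(self) -> float:
        return float(sum(s.dur_ms for s in self.sweeps[0]))

    def sweep_start_times_s(self) -> np.ndarray:
        """Absolute start time of each sweep (s), sweep clock for run-down."""
        period = self.sweep_duration_ms + self.inter_sweep_interval_ms
        return np.arange(self.n_sweeps) * period / 1000.0

    def segment_onsets_ms(self) -> np.ndarray:
        """Start time of each segment within a sweep (ms, sweep-local clock)."""
        durs = [s.dur_ms for s in self.sweeps[0]]
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def sample_voltage(self, sweep: int, dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample the command voltage of one sweep on a regular grid.

        Returns (time_ms, voltage_mV); the grid starts at 0 and covers the
        sweep with step ``dt_ms``.  The voltage at a grid point falling on a
        segment boundary is the value of the *starting* segment.
        """
        t = np.arange(0.0, self.sweep_duration_ms, dt_ms)
        v = np.empty_like(t)
        onsets = self.segment_onsets_ms()
        segs = self.sweeps[sweep]
        idx = np.searchsorted(onsets, t, side="right") - 1
        for i, seg in enumerate(segs):
            m = idx == i
            v[m] = seg.voltage_at(t[m] - onsets[i])
        return t, v

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "holding_mV": self.holding_mV,
            "inter_sweep_interval_ms": self.inter_sweep_interval_ms,
            "name": self.name,
            "sweeps": [
                [{"dur_ms": s.dur_ms, "v0_mV": s.v0_mV, "v1_mV": s.v1_mV} for s in sw]
                for sw in self.sweeps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        sweeps = tuple(
            tuple(Segment(s["dur_ms"], s["v0_mV"], s["v1_mV"]) for s in sw)
            for sw in d["sweeps"]
        )
        return cls(
            holding_mV=d["holding_mV"],
            sweeps=sweeps,
            inter_sweep_interval_ms=d.get("inter_sweep_interval_ms", 0.0),
            name=d.get("name", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "VoltageProtocol":
        return cls.from_dict(json.loads(s))


def make_double_pulse(
    p1_min: float = -100.0,
    p1_max: float = 60.0,
    p1_step: float = 10.0,
    p1_dur: float = 2000.0,
    p2_v: float = 0.0,
    p2_dur: float = 1000.0,
    holding: float = -80.0,
    return_dur: float = 500.0,
    inter_sweep_interval_ms: float = 5000.0,
    name: str = "",
) -> VoltageProtocol:
    """Double-pulse IV family: variable P1 step followed by a constant P2.

    One sweep per P1 level from ``p1_min`` to ``p1_max`` inclusive; each sweep
    is [holding settle, P1, P2, return-to-holding].
    """
    if p1_min > p1_max:
        raise ProtocolError("p1_min must be <= p1_max")
    if p1_step <= 0:
        raise ProtocolError("p1_step must be > 0")
    if p1_min < p1_max and p1_step > (p1_max - p1_min):
        raise ProtocolError("p1_step larger than the P1 range")
    n = int(round((p1_max - p1_min) / p1_step)) + 1
    levels = p1_min + p1_step * np.arange(n)
    sweeps = tuple(
        (
            Segment(HOLD_SETTLE_MS, holding, holding),
            Segment(p1_dur, float(v), float(v)),
            Segment(p2_dur, p2_v, p2_v),
            Segment(return_dur, holding, holding),
        )
        for v in levels
    )
    return VoltageProtocol(holding, sweeps, inter_sweep_interval_ms, name=name)


def make_pulse_train(
    test_v: float = 40.0,
    test_dur: float = 500.0,
    tail_v: float = -40.0,
    tail_dur: float = 1000.0,
    interval_s: float = 5.0,
    n_sweeps: int = 60,
    holding: float = -80.0,
    name: str = "",
) -> VoltageProtocol:
    """Repeated test pulse for run-down tracing (sweep starts interval_s apart)."""
    if n_sweeps < 1:
        raise ProtocolError("n_sweeps must be >= 1")
    sweep_dur = HOLD_SETTLE_MS + test_dur + tail_dur
    if interval_s * 1000.0 < sweep_dur:
        raise ProtocolError("inter-sweep interval shorter than the sweep itself")
    sweeps = tuple(
        (
            Segment(HOLD_SETTLE_MS, holding, holding),
            Segment(test_dur, test_v, test_v),
            Segment(tail_dur, tail_v, tail_v),
        )
        for _ in range(n_sweeps)
    )
    return VoltageProtocol(
        holding, sweeps, interval_s * 1000.0 - sweep_dur, name=name
    )


def make_ramp(
    v_start: float = -120.0,
    v_end: float = -40.0,
    ramp_dur: float = 500.0,
    interval_s: float = 2.0,
    n_sweeps: int = 150,
    holding: float = -80.0,
    name: str = "",
) -> VoltageProtocol:
    """Repeated voltage ramp (degenerates to a step when v_start == v_end)."""
    if ramp_dur <= 0:
        raise ProtocolError("ramp_dur must be > 0")
    sweep_dur = HOLD_SETTLE_MS + ramp_dur
    if interval_s * 1000.0 < sweep_dur:
        raise ProtocolError("inter-sweep interval shorter than the sweep itself")
    sweeps = tuple(
        (
            Segment(HOLD_SETTLE_MS, holding, holding),
            Segment(ramp_dur, v_start, v_end),
        )
        for _ in range(n_sweeps)
    )
    return VoltageProtocol(holding, sweeps, interval_s * 1000.0 - sweep_dur, name=name)


#: named presets used throughout the analysis scripts
PRESETS = {
    # 2 s isochronal double-pulse IV, P2 at 0 mV (standard)
    "iv2s": lambda: make_double_pulse(name="iv2s"),
    # same family with P2 at -40 mV
    "iv2s-p2m40": lambda: make_double_pulse(p2_v=-40.0, name="iv2s-p2m40"),
    # short-P1 variant of the IV family
    "iv200ms": lambda: make_double_pulse(p1_dur=200.0, name="iv200ms"),
    # 5-minute run-down tracer: 500 ms to +40 mV every 5 s
    "rundown": lambda: make_pulse_train(name="rundown"),
    # 5-minute ramp tracer: -120 to -40 mV every 2 s
    "ramp": lambda: make_ramp(name="ramp"),
}


def get_preset(name: str) -> VoltageProtocol:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ProtocolError(
            f"unknown protocol preset {name!r}; known: {sorted(PRESETS)}"
        ) from None
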