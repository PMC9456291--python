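"""Whole-cell recording container shared by the generator, analysis and IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .protocols import VoltageProtocol


class RecordingError(ValueError):
    """Raised for malformed recordings."""


@dataclass
class Recording:
    """Multi-sweep current recording on a common time grid.

    ``sweeps`` is an (n_sweeps, n_samples) array of currents in pA;
    ``voltage_mV`` the matching command voltages; ``sweep_start_s`` the
    absolute start time of each sweep (the run-down clock).
    """

    sweeps: np.ndarray
    time_ms: np.ndarray
    voltage_mV: np.ndarray
    protocol: VoltageProtocol
    sampling_interval_ms: float
    condition: dict = field(default_factory=dict)
    capacitance_pF: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.sweeps.ndim != 2:
            raise RecordingError("sweeps must be 2-D (n_sweeps, n_samples)")
        if self.sweeps.shape[1] != self.time_ms.size:
            raise RecordingError("sweep length does not match the time grid")
        if self.voltage_mV.shape != self.sweeps.shape:
            raise RecordingError("voltage array must match the sweep array")
        if self.sweeps.shape[0] != self.protocol.n_sweeps:
            raise RecordingError(
                f"{self.sweeps.shape[0]} sweeps but protocol defines "
                f"{self.protocol.n_sweeps}"
            )
        if not np.all(np.isfinite(self.sweeps)):
            raise RecordingError("non-finite current samples")
        if self.capacitance_pF <= 0:
            raise RecordingError("capacitance must be > 0")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def sweep_start_s(self) -> np.ndarray:
        return self.protocol.sweep_start_times_s()

    def segment_window_mask(
        self, segment_index: int, window_offset_ms: float, window_len_ms: float
    ) -> np.ndarray:
        """Boolean mask of samples inside a window of one protocol segment."""
        onsets = self.protocol.segment_onsets_ms()
        if not 0 <= segment_index < len(onsets):
            raise RecordingError(f"segment index {segment_index} out of range")
        seg = self.protocol.sweeps[0][segment_index]
        if window_offset_ms < 0 or window_offset_ms + window_len_ms > seg.dur_ms + 1e-9:
            raise RecordingError("window outside segment bounds")
        t0 = onsets[segment_index] + window_offset_ms
        t1 = t0 + window_len_ms
        mask = (self.time_ms >= t0 - 1e-9) & (self.time_ms < t1 - 1e-9)
        if not mask.any():
            raise RecordingError("window contains no samples")
        return mask
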