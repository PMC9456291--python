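"""Recording interchange: tidy CSV with a JSON sidecar, plus a minimal
Axon Text File (ATF 1.0) importer for externally supplied sweeps.

The native format is a long-form CSV with columns
``sweep, sweep_start_s, time_ms, voltage_mV, current_pA`` and a sidecar
``<name>.json`` carrying the protocol, condition, capacitance and seed, so
a Recording round-trips losslessly through text files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import VoltageProtocol
from .recording import Recording, RecordingError

CSV_COLUMNS = ["sweep", "sweep_start_s", "time_ms", "voltage_mV", "current_pA"]


def recording_frame(rec: Recording) -> pd.DataFrame:
    """Long-form DataFrame view of a Recording."""
    starts = rec.sweep_start_s
    frames = []
    for i in range(rec.n_sweeps):
        frames.append(
            pd.DataFrame(
                {
                    "sweep": i,
                    "sweep_start_s": starts[i],
                    "time_ms": rec.time_ms,
                    "voltage_mV": rec.voltage_mV[i],
                    "current_pA": rec.sweeps[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``<path>`` (CSV) and ``<path stem>.json`` (metadata sidecar)."""
    path = Path(path)
    recording_frame(rec).to_csv(path, index=False)
    sidecar = {
        "protocol": rec.protocol.to_dict(),
        "condition": rec.condition,
        "capacitance_pF": rec.capacitance_pF,
        "sampling_interval_ms": rec.sampling_interval_ms,
        "seed": rec.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a Recording written by :func:`write_recording`.

    Sweep blocks may appear in any order in the CSV; they are sorted into
    canonical order.  Malformed rows are reported with line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise RecordingError(f"{path}: empty recording file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: missing columns {missing}")
    bad = df.index[df[CSV_COLUMNS].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise RecordingError(
            f"{path}: malformed rows at lines {[int(i) + 2 for i in bad[:10]]}"
        )
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise RecordingError(f"{path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    protocol = VoltageProtocol.from_dict(meta["protocol"])

    sweep_ids = np.sort(df["sweep"].unique())
    expected = np.arange(protocol.n_sweeps)
    if not np.array_equal(sweep_ids, expected):
        raise RecordingError(
            f"{path}: sweep ids {sweep_ids.tolist()} do not match protocol "
            f"(expected 0..{protocol.n_sweeps - 1})"
        )
    groups = dict(tuple(df.groupby("sweep", sort=True)))
    n_t = len(groups[0])
    time_ms = groups[0].sort_values("time_ms")["time_ms"].to_numpy()
    sweeps = np.empty((protocol.n_sweeps, n_t))
    volts = np.empty_like(sweeps)
    for i in expected:
        g = groups[i].sort_values("time_ms")
        if len(g) != n_t:
            raise RecordingError(f"{path}: ragged sweep {i} ({len(g)} vs {n_t} rows)")
        sweeps[i] = g["current_pA"].to_numpy()
        volts[i] = g["voltage_mV"].to_numpy()
    return Recording(
        sweeps=sweeps,
        time_ms=time_ms,
        voltage_mV=volts,
        protocol=protocol,
        sampling_interval_ms=meta.get("sampling_interval_ms", float(np.median(np.diff(time_ms)))),
        condition=meta.get("condition", {}),
        capacitance_pF=meta.get("capacitance_pF", 12.0),
        seed=meta.get("seed"),
    )


def read_atf(path: str | Path) -> pd.DataFrame:
    """Minimal ATF 1.0 reader (tab-separated; header per the ATF spec).

    Returns a DataFrame with the file's column titles; the first column is
    conventionally time, the remaining ones one trace per sweep.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise RecordingError(f"{path}: not an ATF file (missing 'ATF' signature)")
    try:
        n_header, n_cols = (int(x) for x in lines[1].split())
    except (IndexError, ValueError):
        raise RecordingError(f"{path}: malformed ATF dimension line") from None
    title_line = lines[2 + n_header]
    titles = [t.strip().strip('"') for t in title_line.split("\t")]
    if len(titles) != n_cols:
        raise RecordingError(
            f"{path}: expected {n_cols} column titles, found {len(titles)}"
        )
    data = [
        [float(x) for x in ln.split("\t")]
        for ln in lines[3 + n_header :]
        if ln.strip()
    ]
    return pd.DataFrame(data, columns=titles)
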