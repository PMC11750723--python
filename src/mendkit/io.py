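"""Plain-text I/O for trace matrices, photometry recordings and schedules.

Formats
-------
* trace CSV: first column ``cell_id``, remaining columns one frame each;
* photometry CSV: columns ``time_s``, ``sig470``, ``iso405``;
* schedule JSON: ``{"fps" | "fs", "onsets", "duration", ...}``;
* event-table CSV: the rows produced by :func:`mendkit.calcium.event_table`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import TraceMatrix
from .photometry import PhotometryRecording

__all__ = [
    "read_traces_csv", "write_traces_csv",
    "read_photometry_csv", "write_photometry_csv",
    "read_schedule_json", "write_schedule_json",
]


def write_traces_csv(traces: TraceMatrix, path) -> None:
    df = pd.DataFrame(traces.values)
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)


def read_traces_csv(path, fps: float, epoch_onsets, epoch_duration: float) -> TraceMatrix:
    df = pd.read_csv(path)
    return TraceMatrix(
        values=df.drop(columns=["cell_id"]).to_numpy(dtype=float),
        fps=fps,
        epoch_onsets=np.asarray(epoch_onsets, dtype=float),
        epoch_duration=epoch_duration,
        cell_ids=df["cell_id"].to_numpy(),
    )


def write_photometry_csv(rec: PhotometryRecording, path) -> None:
    pd.DataFrame({"time_s": rec.time, "sig470": rec.signal_470,
                  "iso405": rec.isosbestic_405}).to_csv(path, index=False)


def read_photometry_csv(path, fs: float = 130.0, stim_onsets=None,
                        stim_duration: float = 5.0) -> PhotometryRecording:
    df = pd.read_csv(path)
    return PhotometryRecording(
        time=df["time_s"].to_numpy(dtype=float),
        signal_470=df["sig470"].to_numpy(dtype=float),
        isosbestic_405=df["iso405"].to_numpy(dtype=float),
        fs=fs, stim_onsets=stim_onsets, stim_duration=stim_duration,
    )


def write_schedule_json(path, **schedule) -> None:
    out = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in schedule.items()}
    Path(path).write_text(json.dumps(out, indent=2))


def read_schedule_json(path) -> dict:
    return json.loads(Path(path).read_text())
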