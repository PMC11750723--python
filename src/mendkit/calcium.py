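"""In vitro calcium-imaging trace statistics.

Operates on per-cell fluorescence traces (cells x frames) recorded around
repeated magnetic-field epochs:

* dF/F0 against the mean fluorescence in the 30 s before the first epoch;
* peak counting against half the mean per-cell standard deviation;
* per-cell, per-epoch responsiveness (3 sigma of the pre-stimulus baseline
  anywhere within 15 s of an epoch onset);
* population spiking probability (epochs whose cell-averaged trace exceeds
  3 sigma of its own baseline);
* stimulus-to-peak latency of responsive (cell, epoch) pairs.

All windows are half-open ``[start, end)``; frame timestamps are
``frame_index / fps`` (0-based); argmax ties resolve to the earliest frame.
Cells with non-positive baseline fluorescence or zero baseline variance are
excluded (NaN-masked) and logged, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraceMatrix",
    "AnalysisConfig",
    "compute_dff",
    "count_peaks",
    "classify_responsive",
    "ResponsivenessResult",
    "spiking_probability",
    "latency",
    "event_table",
]


@dataclass
class TraceMatrix:
    """Per-cell fluorescence time series with its stimulation schedule."""

    values: np.ndarray              # cells x frames, raw fluorescence (a.u.)
    fps: float                      # frames per second (1 or 10 typical)
    epoch_onsets: np.ndarray        # seconds, strictly increasing
    epoch_duration: float           # seconds
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a cells x frames matrix")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.epoch_onsets = np.asarray(self.epoch_onsets, dtype=float)
        if self.epoch_onsets.size == 0:
            raise ValueError("at least one epoch onset is required")
        if np.any(np.diff(self.epoch_onsets) <= 0):
            raise ValueError("epoch onsets must be strictly increasing")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows of the trace statistics.

    baseline_window (s) precedes the *first* epoch onset and defines F0 and
    the baseline sigma; response_window (s) follows each onset.
    ``peak_sd_scope`` selects whether the peak-height threshold uses the
    across-cell mean of per-cell SDs (the default reading of "mean standard
    deviation") or each cell's own SD.  ``sigma_scope`` selects per-cell
    (default) or pooled baseline sigma for responsiveness.
    """

    baseline_window: float = 30.0
    response_window: float = 15.0
    response_k: float = 3.0
    peak_threshold_factor: float = 0.5
    spike_k: float = 3.0
    peak_sd_scope: str = "mean"       # "mean" | "per_cell"
    sigma_scope: str = "per_cell"     # "per_cell" | "pooled"

    def __post_init__(self) -> None:
        for name in ("baseline_window", "response_window", "response_k",
                     "peak_threshold_factor", "spike_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_sd_scope not in ("mean", "per_cell"):
            raise ValueError("peak_sd_scope must be 'mean' or 'per_cell'")
        if self.sigma_scope not in ("per_cell", "pooled"):
            raise ValueError("sigma_scope must be 'per_cell' or 'pooled'")


def _window_idx(t0: float, t1: float, fps: float, n_frames: int) -> slice:
    """Frame slice for timestamps in the half-open interval [t0, t1)."""
    eps = 1e-9
    i0 = max(0, int(np.ceil(t0 * fps - eps)))
    i1 = min(n_frames, int(np.ceil(t1 * fps - eps)))
    return slice(i0, i1)


def _baseline_slice(traces: TraceMatrix, config: AnalysisConfig) -> slice:
    first = float(traces.epoch_onsets[0])
    if first < config.baseline_window - 1e-9:
        raise ValueError(
            f"baseline window ({config.baseline_window} s) does not fit before "
            f"the first onset at {first} s"
        )
    return _window_idx(first - config.baseline_window, first, traces.fps,
                       traces.n_frames)


def compute_dff(traces: TraceMatrix, config: AnalysisConfig = AnalysisConfig()) -> np.ndarray:
    """dF/F0 matrix; F0 is the per-cell baseline-window mean.

    Cells with F0 <= 0 are returned as all-NaN rows and logged.
    """
    sl = _baseline_slice(traces, config)
    f0 = traces.values[:, sl].mean(axis=1)
    bad = f0 <= 0
    if np.any(bad):
        logger.warning("excluding %d cell(s) with non-positive baseline F0",
                       int(bad.sum()))
    f0 = np.where(bad, np.nan, f0)
    return (traces.values - f0[:, None]) / f0[:, None]


def _strict_peak_indices(x: np.ndarray) -> np.ndarray:
    """Local maxima strictly above both neighbours; a plateau counts once,
    at its first frame.  Endpoints are never peaks."""
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int)
    # compress runs of equal consecutive values, remembering run starts
    keep = np.flatnonzero(np.r_[True, np.diff(x) != 0])
    xc = x[keep]
    if xc.size < 3:
        return np.empty(0, dtype=int)
    interior = np.flatnonzero((xc[1:-1] > xc[:-2]) & (xc[1:-1] > xc[2:])) + 1
    # plateaus touching either end of the trace are not peaks
    starts = keep[interior]
    run_ends = np.r_[keep[1:], n] - 1
    valid = (starts > 0) & (run_ends[interior] < n - 1)
    return starts[valid]


def count_peaks(
    dff: np.ndarray,
    traces: TraceMatrix,
    config: AnalysisConfig = AnalysisConfig(),
) -> np.ndarray:
    """Per-cell count of dF/F0 peaks above the half-mean-SD threshold.

    A peak is a strict local maximum whose height above the cell's baseline
    mean exceeds ``peak_threshold_factor`` times the mean (across valid
    cells) of the per-cell SD of dF/F0 over the full recording.  Invariant
    under adding a constant to any single trace only through the baseline
    mean; invariant under overall gain by construction of dF/F0.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.shape[1] < 3:
        raise ValueError("need at least 3 frames to count peaks")
    valid = ~np.isnan(dff).any(axis=1)
    per_cell_sd = np.nanstd(dff, axis=1)
    if config.peak_sd_scope == "mean":
        ref_sd = np.full(dff.shape[0], per_cell_sd[valid].mean() if valid.any() else np.nan)
    else:
        ref_sd = per_cell_sd
    sl = _baseline_slice(traces, config)
    base_mean = np.nanmean(dff[:, sl], axis=1)
    counts = np.zeros(dff.shape[0], dtype=int)
    for c in range(dff.shape[0]):
        if not valid[c]:
            continue
        idx = _strict_peak_indices(dff[c])
        thr = config.peak_threshold_factor * ref_sd[c]
        counts[c] = int(np.sum(dff[c, idx] - base_mean[c] > thr))
    return counts


@dataclass
class ResponsivenessResult:
    """Per-cell/per-epoch responsive flags plus per-epoch fractions."""

    flags: np.ndarray            # cells x epochs, bool
    valid: np.ndarray            # cells, bool (False: excluded cell)
    fraction_per_epoch: np.ndarray
    sigma: np.ndarray            # per-cell baseline sigma (NaN when excluded)


def classify_responsive(
    dff: np.ndarray,
    traces: TraceMatrix,
    config: AnalysisConfig = AnalysisConfig(),
) -> ResponsivenessResult:
    """3-sigma responsiveness per cell per epoch.

    A cell is responsive for an epoch iff dF/F0 exceeds
    ``response_k * sigma_baseline`` at any frame within
    ``[onset, onset + response_window)``; sigma is the SD of the cell's
    baseline window (or the pooled SD across valid cells if configured).
    Cells with zero baseline variance are excluded with a warning.
    """
    dff = np.asarray(dff, dtype=float)
    sl = _baseline_slice(traces, config)
    sigma = np.nanstd(dff[:, sl], axis=1)
    valid = ~np.isnan(dff).any(axis=1)
    zero_var = valid & (sigma == 0)
    if np.any(zero_var):
        logger.warning("excluding %d cell(s) with zero baseline variance",
                       int(zero_var.sum()))
        valid &= ~zero_var
    sigma = np.where(valid, sigma, np.nan)
    if config.sigma_scope == "pooled":
        pooled = np.sqrt(np.nanmean(sigma[valid] ** 2)) if valid.any() else np.nan
        sigma = np.where(valid, pooled, np.nan)
    n_epochs = traces.epoch_onsets.size
    flags = np.zeros((dff.shape[0], n_epochs), dtype=bool)
    for e, onset in enumerate(traces.epoch_onsets):
        w = _window_idx(onset, onset + config.response_window, traces.fps,
                        traces.n_frames)
        if w.start >= w.stop:
            raise ValueError(f"response window for epoch {e} lies outside the recording")
        peak = np.nanmax(dff[:, w], axis=1)
        flags[:, e] = valid & (peak > config.response_k * sigma)
    frac = flags[valid].mean(axis=0) if valid.any() else np.full(n_epochs, np.nan)
    return ResponsivenessResult(flags=flags, valid=valid,
                                fraction_per_epoch=frac, sigma=sigma)


def spiking_probability(
    dff: np.ndarray,
    traces: TraceMatrix,
    config: AnalysisConfig = AnalysisConfig(),
) -> float:
    """Fraction of epochs whose population-average dF/F0 "spikes".

    The cell-averaged trace is thresholded at ``spike_k`` times the SD of
    its own baseline window; an epoch spikes iff the average exceeds the
    threshold within the response window.
    """
    dff = np.asarray(dff, dtype=float)
    if traces.epoch_onsets.size == 0:
        raise ValueError("at least one epoch is required")
    avg = np.nanmean(dff, axis=0)
    sl = _baseline_slice(traces, config)
    sigma = np.std(avg[sl])
    hits = 0
    for onset in traces.epoch_onsets:
        w = _window_idx(onset, onset + config.response_window, traces.fps,
                        traces.n_frames)
        if np.max(avg[w]) > config.spike_k * sigma:
            hits += 1
    return hits / traces.epoch_onsets.size


def latency(
    dff: np.ndarray,
    traces: TraceMatrix,
    config: AnalysisConfig = AnalysisConfig(),
    responsiveness: ResponsivenessResult | None = None,
) -> pd.DataFrame:
    """Stimulus-to-peak latency for responsive (cell, epoch) pairs.

    Latency is the time of the dF/F0 maximum within the response window
    minus the epoch onset, at frame resolution.  Non-responsive pairs have
    no row (latency is undefined for them, not zero).

    Returns a DataFrame with columns cell_id, epoch_id, latency, peak_time,
    peak_amplitude.
    """
    dff = np.asarray(dff, dtype=float)
    if responsiveness is None:
        responsiveness = classify_responsive(dff, traces, config)
    rows = []
    for e, onset in enumerate(traces.epoch_onsets):
        w = _window_idx(onset, onset + config.response_window, traces.fps,
                        traces.n_frames)
        seg = dff[:, w]
        arg = np.argmax(seg, axis=1)            # earliest frame on ties
        for c in np.flatnonzero(responsiveness.flags[:, e]):
            peak_frame = w.start + arg[c]
            peak_time = peak_frame / traces.fps
            rows.append({
                "cell_id": traces.cell_ids[c],
                "epoch_id": e,
                "latency": peak_time - onset,
                "peak_time": peak_time,
                "peak_amplitude": seg[c, arg[c]],
            })
    return pd.DataFrame(rows, columns=["cell_id", "epoch_id", "latency",
                                       "peak_time", "peak_amplitude"])


def event_table(
    traces: TraceMatrix,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Full per-video analysis: event rows plus a summary dict.

    The summary reports responsiveness per epoch, spiking probability and
    latency mean/SD over responsive pairs.
    """
    dff = compute_dff(traces, config)
    resp = classify_responsive(dff, traces, config)
    lat = latency(dff, traces, config, responsiveness=resp)
    peaks = count_peaks(dff, traces, config)
    table = lat.copy()
    table["n_peaks"] = table["cell_id"].map(
        dict(zip(np.asarray(traces.cell_ids), peaks)))
    summary = {
        "responsiveness_per_epoch": resp.fraction_per_epoch.tolist(),
        "spiking_probability": spiking_probability(dff, traces, config),
        "latency_mean": float(lat["latency"].mean()) if len(lat) else float("nan"),
        "latency_sd": float(lat["latency"].std(ddof=1)) if len(lat) > 1 else float("nan"),
        "n_cells_valid": int(resp.valid.sum()),
    }
    return table, summary
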