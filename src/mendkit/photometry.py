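"""In vivo fibre-photometry processing and per-trial statistics.

Pipeline (order fixed): 25 Hz second-order Butterworth low-pass (zero
phase) -> two-term exponential debleaching per channel -> isosbestic
subtraction (470 nm minus 405 nm, removing shared motion/hemodynamic
artifacts) -> per-trial segmentation and dF/F0 -> 2-sigma / 20 s trial
classification with peak intensity, position and sigma/2 width.

Two window presets mirror the two fibre configurations used in practice:
30 s pre / 150 s post, and 15 s pre / 85 s post.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometryRecording",
    "TrialSegment",
    "TrialMetrics",
    "WINDOW_PRESETS",
    "lowpass",
    "debleach",
    "motion_subtract",
    "segment_trials",
    "classify_trial",
    "session_statistics",
    "run_pipeline",
]

#: (pre_window, post_window) in seconds for the two fibre configurations.
WINDOW_PRESETS = {"A": (30.0, 150.0), "B": (15.0, 85.0)}


@dataclass
class PhotometryRecording:
    """Two-channel photometry time series sampled uniformly at ``fs``."""

    time: np.ndarray
    signal_470: np.ndarray
    isosbestic_405: np.ndarray
    fs: float = 130.0
    stim_onsets: np.ndarray | None = None
    stim_duration: float = 5.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal_470 = np.asarray(self.signal_470, dtype=float)
        self.isosbestic_405 = np.asarray(self.isosbestic_405, dtype=float)
        if not (self.time.size == self.signal_470.size == self.isosbestic_405.size):
            raise ValueError("time and channel arrays must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-3, atol=1e-6):
                raise ValueError("recording must be uniformly sampled at fs")
        self.stim_onsets = (np.asarray(self.stim_onsets, dtype=float)
                            if self.stim_onsets is not None else np.empty(0))
        if self.stim_onsets.size and (
            self.stim_onsets.min() < self.time[0]
            or self.stim_onsets.max() > self.time[-1]
        ):
            raise ValueError("stimulation onsets must fall inside the recording")


@dataclass
class TrialSegment:
    """One trial's dF/F0 over [-pre_window, +post_window) around its onset."""

    dff: np.ndarray
    fs: float
    pre_window: float
    post_window: float
    onset_index: int
    onset_time: float
    f0: float

    @property
    def times(self) -> np.ndarray:
        """Seconds relative to stimulus onset."""
        n_pre = int(round(self.pre_window * self.fs))
        return (np.arange(self.dff.size) - n_pre) / self.fs


@dataclass
class TrialMetrics:
    """Per-trial statistics of the dF/F0 transient."""

    responsive: bool
    peak_intensity: float
    peak_position: float          # s from onset
    peak_width: float             # s between the sigma/2 crossings
    width_censored: bool
    sigma: float


def _butter(fs: float, cutoff: float, order: int):
    if fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz cannot support a {cutoff} Hz low-pass"
        )
    return signal.butter(order, cutoff, btype="low", fs=fs)


def lowpass(recording: PhotometryRecording, cutoff: float = 25.0,
            order: int = 2) -> PhotometryRecording:
    """Zero-phase (forward-backward) Butterworth low-pass on both channels.

    Forward-backward application squares the magnitude response and cancels
    phase lag, so transient peak positions are not shifted.  DC gain is
    exactly 1.
    """
    b, a = _butter(recording.fs, cutoff, order)
    return replace(
        recording,
        signal_470=signal.filtfilt(b, a, recording.signal_470),
        isosbestic_405=signal.filtfilt(b, a, recording.isosbestic_405),
    )


def lowpass_array(x: np.ndarray, fs: float, cutoff: float = 25.0,
                  order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a single channel."""
    b, a = _butter(fs, cutoff, order)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def _exp2(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def _exp1(t, a, b, c):
    return a * np.exp(b * t) + c


def _log_linear_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Decay-rate initial guess from a log-linear fit; never positive."""
    floor = max(np.max(np.abs(y)) * 1e-6, 1e-12)
    z = np.log(np.clip(y, floor, None))
    slope = np.polyfit(t, z, 1)[0]
    return min(slope, -1e-9)


def debleach(
    channel: np.ndarray,
    time: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Subtract a fitted two-term exponential photobleaching trend.

    Fits ``a exp(b t) + c exp(d t)`` (a, c >= 0; b, d <= 0: decay only) by
    nonlinear least squares and returns ``(residual, info)``; the fit is
    evaluated and subtracted over the whole recording even when ``mask``
    (True = use sample in the fit) excludes, e.g., stimulation windows.
    Falls back to a single exponential plus constant with a warning when the
    two-term fit does not converge.

    Initialisation: the slow amplitude/rate from a log-linear fit to the
    last third of the signal, the fast term from the first third of what
    that leaves over.
    """
    y = np.asarray(channel, dtype=float)
    t = np.asarray(time, dtype=float)
    if y.size < 100:
        raise ValueError("need at least 100 samples to fit a bleaching trend")
    if mask is None:
        mask = np.ones(y.size, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != y.size or mask.sum() < 100:
            raise ValueError("mask must keep at least 100 samples")
    tf, yf = t[mask], y[mask]
    t0 = tf[0]
    ts = tf - t0                      # fit in shifted time for conditioning
    n3 = ts.size // 3
    c0 = max(float(np.mean(yf[-n3:])), 1e-12)
    d0 = _log_linear_rate(ts[-n3:], yf[-n3:] / c0) if c0 > 0 else -1e-9
    resid_fast = yf[:n3] - c0 * np.exp(d0 * ts[:n3])
    a0 = max(float(resid_fast[0]), 1e-12)
    b0 = _log_linear_rate(ts[:n3], np.clip(resid_fast, 1e-12, None) / a0)
    info: dict = {"model": "exp2"}
    try:
        popt, _ = optimize.curve_fit(
            _exp2, ts, yf, p0=[a0, b0, c0, d0],
            bounds=([0.0, -np.inf, 0.0, -np.inf], [np.inf, 0.0, np.inf, 0.0]),
            maxfev=20000,
        )
        fit = _exp2(t - t0, *popt)
        info["params"] = tuple(float(p) for p in popt)
    except RuntimeError:
        logger.warning("two-term exponential fit did not converge; "
                       "falling back to a single exponential")
        popt, _ = optimize.curve_fit(
            _exp1, ts, yf, p0=[a0, b0, c0],
            bounds=([0.0, -np.inf, 0.0], [np.inf, 0.0, np.inf]),
            maxfev=20000,
        )
        fit = _exp1(t - t0, *popt)
        info = {"model": "exp1", "params": tuple(float(p) for p in popt)}
    return y - fit, info


def motion_subtract(corrected_470: np.ndarray,
                    corrected_405: np.ndarray) -> np.ndarray:
    """Elementwise 470 - 405 of the debleached channels.

    A motion artifact shared by both channels cancels; an artifact present
    only on the isosbestic channel appears inverted in the output (this is
    the documented subtraction contract, not an error).
    """
    a = np.asarray(corrected_470, dtype=float)
    b = np.asarray(corrected_405, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel length mismatch")
    return a - b


def segment_trials(
    sig: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    pre: float,
    post: float,
    reference: np.ndarray | None = None,
) -> list[TrialSegment]:
    """Cut per-trial dF/F0 segments over [-pre, +post) around each onset.

    F0 is the pre-window mean of ``reference`` when given (e.g. the
    filtered raw 470 nm channel, so F0 reflects actual fluorescence and
    stays positive after baseline correction has centred ``sig`` near
    zero), otherwise of ``sig`` itself.  dF/F0 =
    (sig - pre-window mean of sig) / F0.  Trials whose window leaves the
    recording are dropped with a warning; trials with F0 <= 0 are excluded
    and logged.
    """
    sig = np.asarray(sig, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    ref = sig if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != sig.shape:
        raise ValueError("reference must match the signal length")
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    out: list[TrialSegment] = []
    prev_end = -math.inf
    for onset in onsets:
        if onset - pre < prev_end:
            logger.info("trial at %.1f s overlaps the previous trial's "
                        "post-window", onset)
        prev_end = onset + post
        i = int(round(onset * fs))
        lo, hi = i - n_pre, i + n_post
        if lo < 0 or hi > sig.size:
            logger.warning("dropping trial at %.1f s: window [%g, %g) leaves "
                           "the recording", onset, onset - pre, onset + post)
            continue
        f0 = float(ref[lo:i].mean())
        if f0 <= 0:
            logger.warning("excluding trial at %.1f s: non-positive F0", onset)
            continue
        base = float(sig[lo:i].mean())
        out.append(TrialSegment(
            dff=(sig[lo:hi] - base) / f0,
            fs=fs, pre_window=pre, post_window=post,
            onset_index=i, onset_time=float(onset), f0=f0,
        ))
    return out


def _interp_crossing(t0, y0, t1, y1, level):
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def classify_trial(
    segment: TrialSegment,
    sigma: float | None = None,
    response_window: float = 20.0,
    width_level_factor: float = 0.5,
) -> TrialMetrics:
    """2-sigma trial classification and transient shape statistics.

    The trial is responsive iff dF/F0 >= 2 sigma (sigma = SD of the
    pre-window baseline, computed per trial unless supplied) at any sample
    in [0, response_window).  Peak intensity/position are the post-onset
    maximum and its time; the width is the interval between the last
    crossing of ``sigma/2`` before the maximum and the first after it
    (linear interpolation between samples).  If the trace never returns to
    sigma/2 after the maximum the width is right-censored to the segment
    end and flagged.
    """
    t = segment.times
    y = segment.dff
    pre = t < 0
    if sigma is None:
        sigma = float(np.std(y[pre]))
    win = (t >= 0) & (t < response_window)
    responsive = bool(np.any(y[win] >= 2.0 * sigma))
    post = t >= 0
    ip = np.flatnonzero(post)
    k = ip[np.argmax(y[ip])]
    peak_intensity = float(y[k])
    peak_position = float(t[k])
    level = width_level_factor * sigma
    # last crossing at or below `level` before the peak
    before = np.flatnonzero(y[:k + 1] <= level)
    if before.size:
        j = before[-1]
        left = _interp_crossing(t[j], y[j], t[j + 1], y[j + 1], level) if j < k else t[j]
    else:
        left = t[0]
    after = np.flatnonzero(y[k:] <= level)
    censored = after.size == 0
    if censored:
        right = t[-1]
    else:
        j = k + after[0]
        right = _interp_crossing(t[j - 1], y[j - 1], t[j], y[j], level) if j > k else t[j]
    return TrialMetrics(
        responsive=responsive,
        peak_intensity=peak_intensity,
        peak_position=peak_position,
        peak_width=float(right - left),
        width_censored=bool(censored),
        sigma=float(sigma),
    )


def session_statistics(metrics_per_animal: dict) -> dict:
    """Per-animal spiking probability and its across-animal mean +/- SD.

    ``metrics_per_animal`` maps animal id -> list of :class:`TrialMetrics`.
    The spiking probability of an animal is its fraction of responsive
    trials; animals with no trials are excluded with a warning.  The SD is
    the sample SD (ddof=1) across animals, 0.0 for a single animal.
    """
    per_animal = {}
    for animal, metrics in metrics_per_animal.items():
        if len(metrics) == 0:
            logger.warning("excluding animal %r: no trials", animal)
            continue
        per_animal[animal] = float(np.mean([m.responsive for m in metrics]))
    if not per_animal:
        raise ValueError("no animal contributed any trial")
    vals = np.array(list(per_animal.values()))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {
        "per_animal": per_animal,
        "mean": float(vals.mean()),
        "sd": sd,
    }


def run_pipeline(
    recording: PhotometryRecording,
    pre: float = 15.0,
    post: float = 85.0,
    response_window: float = 20.0,
    mask_stimulation: bool = True,
) -> tuple[list[TrialSegment], list[TrialMetrics]]:
    """Full chain: filter -> debleach -> subtract -> segment -> classify.

    Stimulation windows ``[onset - 1 s, onset + post + 5 s)`` are masked
    from the bleaching fits when ``mask_stimulation`` so evoked transients
    do not distort the trend estimate; the fitted trends are still
    subtracted everywhere.  The filtered raw 470 nm channel serves as the
    F0 reference for dF/F0.
    """
    filt = lowpass(recording)
    mask = None
    if mask_stimulation and filt.stim_onsets.size:
        mask = np.ones(filt.time.size, dtype=bool)
        for onset in filt.stim_onsets - filt.time[0]:
            lo = int(round((onset - 1.0) * filt.fs))
            hi = int(round((onset + post + 5.0) * filt.fs))
            mask[max(lo, 0):min(hi, mask.size)] = False
    c470, _ = debleach(filt.signal_470, filt.time, mask=mask)
    c405, _ = debleach(filt.isosbestic_405, filt.time, mask=mask)
    corrected = motion_subtract(c470, c405)
    segments = segment_trials(corrected, filt.fs, filt.stim_onsets - filt.time[0],
                              pre, post, reference=filt.signal_470)
    metrics = [classify_trial(s, response_window=response_window)
               for s in segments]
    return segments, metrics
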