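"""Synthetic fluorescence datasets with exact ground truth.

Generators emulate the statistical structure the analysis modules assume —
GCaMP-like stimulus-locked transients with Bernoulli per-cell / per-trial
responsiveness, truncated-normal stimulus-to-peak latencies, two-term
exponential photobleaching, a motion artifact shared by both photometry
channels, and slow secondary transients — and return the planted truth
alongside the data so every detector can be scored exactly.

Two points where the generators go beyond white noise, both deliberate:

* baseline variability includes a low-amplitude quasi-periodic component
  (slow network-activity-like fluctuation per cell in vitro; an ongoing
  slow calcium oscillation on the 470 nm channel in vivo).  Real baselines
  are dominated by bounded physiological fluctuations, and the
  max-over-window sigma-rules of the analysis are calibrated against
  exactly that structure; see docs/methods.md.
* planted transient *peaks* (not onsets) land on the acquisition grid, so
  the stored ground-truth latency is precisely what an ideal detector can
  read back at the recording's frame resolution.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy import stats

from .calcium import TraceMatrix
from .photometry import PhotometryRecording
from .transduction import ParticleGeometry, interparticle_spacing

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumSimConfig",
    "PhotometrySimConfig",
    "CalciumGroundTruth",
    "PhotometryGroundTruth",
    "CALCIUM_PRESETS",
    "PHOTOMETRY_PRESETS",
    "calcium_preset",
    "photometry_preset",
    "gen_calcium_dataset",
    "gen_photometry_session",
    "gen_particle_layout",
    "dexp_kernel",
    "kernel_peak_time",
]


def kernel_peak_time(rise: float, decay: float) -> float:
    """Peak time of the difference-of-exponentials kernel."""
    if not (0 < rise < decay):
        raise ValueError("need 0 < rise < decay")
    return math.log(decay / rise) / (1.0 / rise - 1.0 / decay)


def dexp_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalised to peak 1 at
    :func:`kernel_peak_time`; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    tp = kernel_peak_time(rise, decay)
    norm = math.exp(-tp / decay) - math.exp(-tp / rise)
    tt = np.maximum(t, 0.0)
    out = np.where(t >= 0, np.exp(-tt / decay) - np.exp(-tt / rise), 0.0)
    return out / norm


def _truncnorm_symmetric(rng, mean, sd, upper_cap, size):
    """Truncated normal whose bounds are symmetric about the mean (so the
    truncated mean equals ``mean`` exactly), clipped into [0, upper_cap]."""
    hi = min(2.0 * mean, upper_cap)
    lo = max(0.0, 2.0 * mean - hi)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


# ---------------------------------------------------------------------------
# in vitro calcium traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumSimConfig:
    """Study conditions for a synthetic in vitro calcium video.

    Defaults describe the 1-fps recordings: a 30 s pre-stimulus baseline,
    five 2 s field epochs at 30 s intervals, 300 cells, per-cell per-epoch
    Bernoulli responsiveness, and stimulus-to-peak latencies drawn from a
    truncated normal with mean 3.9 s and SD 2.9 s.  The GCaMP6s-like kernel
    (0.2 s rise, 1.5 s decay) and the baseline-fluctuation/noise levels are
    literature-typical stand-ins, not values fixed by the emulated study.
    """

    n_cells: int = 300
    fps: float = 1.0
    n_epochs: int = 5
    baseline: float = 30.0            # s before the first onset
    epoch_duration: float = 2.0       # s
    inter_epoch_interval: float = 30.0
    tail: float = 20.0                # s after the last epoch window
    p_response: float = 0.741
    latency_mean: float = 3.9         # s, stimulus to transient peak
    latency_sd: float = 2.9
    latency_cap: float = 15.0         # s, never beyond the response window
    kernel_rise: float = 0.2
    kernel_decay: float = 1.5
    amplitude: float = 1.0            # dF/F0 units
    noise_sd: float = 0.005           # dF/F0 units, white
    drift_amplitude: float = 0.02     # dF/F0 units, slow quasi-periodic
    drift_freq: float = 0.1           # Hz, jittered +-30% per cell
    spontaneous_rate: float = 0.0     # events per second per cell
    baseline_f0: float = 100.0        # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_response <= 1.0:
            raise ValueError("p_response must lie in [0, 1]")
        if self.fps <= 0 or self.n_cells <= 0 or self.n_epochs <= 0:
            raise ValueError("fps, n_cells and n_epochs must be positive")
        if self.latency_sd <= 0 or self.latency_mean < 0:
            raise ValueError("invalid latency distribution")

    @property
    def epoch_onsets(self) -> np.ndarray:
        step = self.epoch_duration + self.inter_epoch_interval
        return self.baseline + step * np.arange(self.n_epochs)

    @property
    def duration(self) -> float:
        return float(self.epoch_onsets[-1] + self.epoch_duration + self.tail)


#: Named study conditions.  The three density presets carry the responsive
#: fractions measured at 0.75 / 0.5 / 0.25 µg mm^-2 particle density; the
#: fast preset is the 10-fps configuration with sub-second latencies
#: (2 s epochs at 10 s intervals; analyse it with response_window=10 s so
#: windows do not reach into the next epoch).
CALCIUM_PRESETS: dict[str, dict] = {
    "invitro-0.75": {"p_response": 0.741},
    "invitro-0.5": {"p_response": 0.463},
    "invitro-0.25": {"p_response": 0.276},
    "fast-10fps": {
        "p_response": 0.9, "fps": 10.0, "inter_epoch_interval": 10.0,
        "latency_mean": 0.857, "latency_sd": 0.069, "latency_cap": 10.0,
    },
    "fast-10fps-6f": {
        "p_response": 0.9, "fps": 10.0, "inter_epoch_interval": 10.0,
        "latency_mean": 0.827, "latency_sd": 0.477, "latency_cap": 10.0,
        "kernel_decay": 0.7,
    },
}


def calcium_preset(name: str, seed: int = 0, **overrides) -> CalciumSimConfig:
    """Build a :class:`CalciumSimConfig` from a named preset."""
    if name not in CALCIUM_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(CALCIUM_PRESETS)}")
    kw = dict(CALCIUM_PRESETS[name])
    kw.update(overrides)
    return CalciumSimConfig(seed=seed, **kw)


@dataclass
class CalciumGroundTruth:
    """Planted truth for one calcium video."""

    responded: np.ndarray        # cells x epochs, bool
    latencies: np.ndarray        # cells x epochs, s (NaN if not responding)
    peak_times: np.ndarray       # cells x epochs, s (NaN if not responding)
    spontaneous_times: list      # per cell, array of event times (s)


def gen_calcium_dataset(config: CalciumSimConfig) -> tuple[TraceMatrix, CalciumGroundTruth]:
    """Simulate a calcium video and its ground truth.

    Per cell and epoch, responding ~ Bernoulli(p_response); a responding
    pair gets one kernel whose peak falls at onset + latency with latency
    drawn from the truncated normal and snapped to the frame grid.
    Fluorescence is ``F0 * (1 + drift + sum kernels) + white noise``,
    clipped at a small positive floor (clipping is logged).
    """
    rng = np.random.default_rng(config.seed)
    onsets = config.epoch_onsets
    n_frames = int(round(config.duration * config.fps))
    t = np.arange(n_frames) / config.fps
    tp = kernel_peak_time(config.kernel_rise, config.kernel_decay)

    responded = rng.random((config.n_cells, config.n_epochs)) < config.p_response
    raw_lat = _truncnorm_symmetric(
        rng, config.latency_mean, config.latency_sd, config.latency_cap,
        size=(config.n_cells, config.n_epochs),
    )
    lat = np.round(raw_lat * config.fps) / config.fps   # frame-grid latencies
    lat[~responded] = np.nan
    peak_times = onsets[None, :] + lat

    drift_f = config.drift_freq * rng.uniform(0.7, 1.3, size=config.n_cells)
    drift_phi = rng.uniform(0, 2 * np.pi, size=config.n_cells)

    values = np.empty((config.n_cells, n_frames))
    spont_times: list[np.ndarray] = []
    for c in range(config.n_cells):
        rel = config.drift_amplitude * np.sin(2 * np.pi * drift_f[c] * t + drift_phi[c])
        for e in range(config.n_epochs):
            if responded[c, e]:
                start = peak_times[c, e] - tp
                rel += config.amplitude * dexp_kernel(t - start,
                                                      config.kernel_rise,
                                                      config.kernel_decay)
        if config.spontaneous_rate > 0:
            n_spont = rng.poisson(config.spontaneous_rate * config.duration)
            times_c = np.sort(rng.uniform(0, config.duration, size=n_spont))
            for ts in times_c:
                rel += config.amplitude * dexp_kernel(t - ts,
                                                      config.kernel_rise,
                                                      config.kernel_decay)
        else:
            times_c = np.empty(0)
        spont_times.append(times_c)
        values[c] = config.baseline_f0 * (1.0 + rel)
    values += rng.normal(0.0, config.noise_sd * config.baseline_f0,
                         size=values.shape)
    floor = 1e-6 * config.baseline_f0
    n_clip = int(np.sum(values < floor))
    if n_clip:
        logger.warning("clipping %d negative fluorescence sample(s)", n_clip)
        values = np.maximum(values, floor)

    traces = TraceMatrix(values=values, fps=config.fps, epoch_onsets=onsets,
                         epoch_duration=config.epoch_duration)
    truth = CalciumGroundTruth(responded=responded, latencies=lat,
                               peak_times=peak_times,
                               spontaneous_times=spont_times)
    return traces, truth


# ---------------------------------------------------------------------------
# in vivo photometry sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotometrySimConfig:
    """Study conditions for a synthetic two-channel photometry session.

    Defaults describe the 100 Hz / 5 s configuration: a 5 min baseline
    (rapid early photobleaching), 20 stimulation trials, per-trial Bernoulli
    responsiveness, a fast primary transient plus a slow (~80 s decay)
    secondary transient on responsive trials, two-term exponential bleaching
    on each channel, a shared band-limited (0-5 Hz) motion artifact, and an
    ongoing slow calcium oscillation on the signal channel only.
    """

    fs: float = 130.0
    baseline: float = 300.0
    n_trials: int = 20
    inter_trial: float = 120.0
    stim_duration: float = 5.0
    p_trial: float = 0.791
    # bleaching: (fast amp, fast tau s, slow amp, slow tau s) per channel
    bleach_470: tuple[float, float, float, float] = (20.0, 60.0, 80.0, 2000.0)
    bleach_405: tuple[float, float, float, float] = (19.0, 70.0, 76.0, 2200.0)
    motion_amplitude: float = 0.01    # fractional, shared realisation
    motion_band: float = 5.0          # Hz
    osc_amplitude: float = 0.01       # fractional, 470 nm only
    osc_freq: float = 0.25            # Hz
    primary_amplitude: float = 0.05   # fractional
    primary_rise: float = 0.5         # s
    primary_decay: float = 8.0        # s
    primary_latency_mean: float = 2.0  # s, onset to transient peak
    primary_latency_sd: float = 0.5
    secondary_amplitude: float = 0.01
    secondary_rise: float = 5.0
    secondary_decay: float = 80.0
    noise_sd: float = 0.001           # fractional, per channel
    pre_window: float = 15.0
    post_window: float = 85.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_trial <= 1.0:
            raise ValueError("p_trial must lie in [0, 1]")
        if self.fs <= 50.0:
            raise ValueError("sampling rate must exceed 50 Hz (filter precondition)")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    @property
    def stim_onsets(self) -> np.ndarray:
        return self.baseline + self.inter_trial * np.arange(self.n_trials)

    @property
    def duration(self) -> float:
        return float(self.stim_onsets[-1] + self.post_window + 35.0)


#: The two in vivo field configurations: 5 s epochs of 100 Hz AMF (15/85 s
#: windows, new fibre) and 2 s epochs of 150 Hz AMF (30/150 s windows,
#: trials every 180 s), with their measured per-trial response fractions.
PHOTOMETRY_PRESETS: dict[str, dict] = {
    "vta-100hz": {"p_trial": 0.791, "stim_duration": 5.0,
                  "pre_window": 15.0, "post_window": 85.0,
                  "inter_trial": 120.0},
    "vta-150hz": {"p_trial": 0.659, "stim_duration": 2.0,
                  "pre_window": 30.0, "post_window": 150.0,
                  "inter_trial": 180.0},
}


def photometry_preset(name: str, seed: int = 0, **overrides) -> PhotometrySimConfig:
    """Build a :class:`PhotometrySimConfig` from a named preset."""
    if name not in PHOTOMETRY_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PHOTOMETRY_PRESETS)}")
    kw = dict(PHOTOMETRY_PRESETS[name])
    kw.update(overrides)
    return PhotometrySimConfig(seed=seed, **kw)


@dataclass
class PhotometryGroundTruth:
    """Planted truth for one photometry session."""

    responded: np.ndarray        # trials, bool
    peak_times: np.ndarray       # s from onset (NaN if not responding)
    amplitudes: np.ndarray       # fractional primary amplitude
    motion: np.ndarray           # shared fractional artifact trace
    bleach_470: np.ndarray
    bleach_405: np.ndarray


def _bleach_curve(t: np.ndarray, params) -> np.ndarray:
    a1, tau1, a2, tau2 = params
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _bandlimited_noise(rng, n: int, fs: float, band: float, sd: float) -> np.ndarray:
    white = rng.normal(size=n)
    b, a = _signal.butter(2, band, btype="low", fs=fs)
    x = _signal.filtfilt(b, a, white)
    s = x.std()
    return sd * x / s if s > 0 else x


def gen_photometry_session(
    config: PhotometrySimConfig,
) -> tuple[PhotometryRecording, PhotometryGroundTruth]:
    """Simulate a two-channel photometry session and its ground truth.

    470 nm channel: ``bleach(t) * (1 + transients + oscillation + motion
    + noise)``; isosbestic 405 nm: ``bleach405(t) * (1 + motion + noise)``
    with the *identical* motion realisation.  Transients appear only on the
    470 nm channel and only on trials drawn responsive.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    onsets = config.stim_onsets

    responded = rng.random(config.n_trials) < config.p_trial
    tp = kernel_peak_time(config.primary_rise, config.primary_decay)
    lat = stats.truncnorm.rvs(
        (tp - config.primary_latency_mean) / config.primary_latency_sd,
        (config.pre_window - config.primary_latency_mean) / config.primary_latency_sd,
        loc=config.primary_latency_mean, scale=config.primary_latency_sd,
        size=config.n_trials, random_state=rng,
    )
    lat[~responded] = np.nan

    rel = np.zeros(n)
    amps = np.where(responded, config.primary_amplitude, 0.0)
    for i, onset in enumerate(onsets):
        if not responded[i]:
            continue
        start = onset + lat[i] - tp
        rel += amps[i] * dexp_kernel(t - start, config.primary_rise,
                                     config.primary_decay)
        if config.secondary_amplitude > 0:
            rel += config.secondary_amplitude * dexp_kernel(
                t - onset, config.secondary_rise, config.secondary_decay)

    # slow ongoing calcium oscillation, 470 only: sinusoid with a slowly
    # wandering phase so successive baseline windows are not identical
    phase = 2 * np.pi * config.osc_freq * t + np.cumsum(
        rng.normal(0, 0.3 / np.sqrt(config.fs), size=n))
    osc = config.osc_amplitude * np.sin(phase + rng.uniform(0, 2 * np.pi))

    motion = _bandlimited_noise(rng, n, config.fs, config.motion_band,
                                config.motion_amplitude)
    b470 = _bleach_curve(t, config.bleach_470)
    b405 = _bleach_curve(t, config.bleach_405)
    s470 = b470 * (1.0 + rel + osc + motion
                   + rng.normal(0, config.noise_sd, size=n))
    s405 = b405 * (1.0 + motion + rng.normal(0, config.noise_sd, size=n))
    floor = 1e-6 * max(b470[0], b405[0])
    n_clip = int(np.sum(s470 < floor) + np.sum(s405 < floor))
    if n_clip:
        logger.warning("clipping %d negative sample(s)", n_clip)
        s470 = np.maximum(s470, floor)
        s405 = np.maximum(s405, floor)

    rec = PhotometryRecording(time=t, signal_470=s470, isosbestic_405=s405,
                              fs=config.fs, stim_onsets=onsets,
                              stim_duration=config.stim_duration)
    truth = PhotometryGroundTruth(responded=responded, peak_times=lat,
                                  amplitudes=amps, motion=motion,
                                  bleach_470=b470, bleach_405=b405)
    return rec, truth


# ---------------------------------------------------------------------------
# particle layouts
# ---------------------------------------------------------------------------

def gen_particle_layout(
    density: float,
    area: float,
    geometry: ParticleGeometry | None = None,
    mode: str = "lattice",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Place particles at a surface mass density and measure spacings.

    Parameters
    ----------
    density : surface mass density, µg mm^-2.
    area : patch area, mm^2 (a square patch).
    mode : "lattice" (square grid; nearest-neighbour distance equals
        n^(-1/2) exactly) or "poisson" (uniform random; mean
        nearest-neighbour distance tends to 0.5 n^(-1/2)).

    Returns ``(positions, nn_distances)`` in mm.  Nearest neighbours are
    computed with periodic boundaries so edge effects do not bias the
    Poisson statistics.
    """
    from scipy.spatial import cKDTree

    if density <= 0 or area <= 0:
        raise ValueError("density and area must be positive")
    spacing = interparticle_spacing(density, geometry)
    count = int(round(spacing.count_per_mm2 * area))
    if count < 1:
        raise ValueError("fewer than one particle in the requested area")
    side = math.sqrt(area)
    rng = np.random.default_rng(seed)
    if mode == "lattice":
        pitch = (count / area) ** -0.5
        m = int(math.ceil(math.sqrt(count)))
        gx, gy = np.meshgrid(np.arange(m), np.arange(m))
        pos = np.column_stack([gx.ravel(), gy.ravel()])[:count] * pitch
        box = m * pitch
    elif mode == "poisson":
        pos = rng.uniform(0, side, size=(count, 2))
        box = side
    else:
        raise ValueError("mode must be 'lattice' or 'poisson'")
    if count == 1:
        return pos, np.empty(0)
    tree = cKDTree(np.mod(pos, box), boxsize=box)
    dist, _ = tree.query(np.mod(pos, box), k=2)
    return pos, dist[:, 1]
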