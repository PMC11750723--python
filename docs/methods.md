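# Methods

This note records the models implemented in `mendkit`, their assumptions,
the tunable parameters that matter, the synthetic-data design, and the
choices made where the design was genuinely open.

## Transduction chain

The magnetoelectric coefficient α_ME (mV mT⁻¹ cm⁻¹) is treated as an
empirical material property. The single-particle membrane potential is the
exact unit conversion V₀ = α_ME · H_AMF · L. The characteristic length L is
the disc diameter (250 nm) by default and is an explicit parameter: with the
measured peak coefficient (150 mV mT⁻¹ cm⁻¹) and a 10 mT AMF this
reproduces the 37.5 µV benchmark arithmetically, but no other length scale
is ruled out by first principles, so L is exposed rather than hidden.

`MECoefficientModel` is separable, α(f, H) = α_ref (f/f_ref)^p · G(H)/G(H_ref):

* the frequency dependence is a power law with exponent p (default 1)
  because below the megahertz piezoelectric resonance the coefficient only
  rises with frequency; the exponent is meant to be calibrated to measured
  grids via `fit_freq_exponent` (noiseless grids are recovered exactly).
* G(H) is a Gaussian bump centred at the 220 mT saturation field with a
  free width (default 80 mT); only the peak location is constrained by
  measurement, the shape is a smooth unimodal stand-in.

Dosimetry: particle mass is the layered-disc volume times per-layer
handbook densities (Fe₃O₄ 5.17, CoFe₂O₄ 5.30, BaTiO₃ 6.02 g cm⁻³; the
default 230/30 nm core with two 5 nm shells fills the 250/50 nm disc
exactly, volume-weighted mean 5.423 g cm⁻³). When nominal layers underfill
the outer disc the slack is treated as void (massless). Spacing uses the
square-lattice convention n^(−1/2); the Poisson nearest-neighbour mean
0.5·n^(−1/2) is reported alongside because particles on membranes are
closer to randomly placed than gridded.

## Membrane model

A deliberately minimal model of repetitive subthreshold depolarisation:

* **events**: each AMF half-cycle deposits one increment, at times
  (k+½)/(2f); both half-cycles depolarise (rectified increments). This is
  required for the monotone rise of V(t) during an epoch.
* **spatial summation**: a 1-D chain of particles at spacing d whose
  contributions decay as exp(−distance/λ_eff); the on-site factor is the
  geometric lattice sum g(d), implemented as the truncated series (terms
  below 1e−12 dropped) and tested against the closed form.
* **integration**: lossless by default (τ_int = ∞). The printed anchor
  24.5 µV ≈ 15 mV / 600 half-cycles implies near-perfect summation over a
  2 s epoch, so leak is off by default; a finite-τ mode exists (relaxation
  toward rest between events) for sensitivity analyses.
* **calibration**: κ·g(0.25a) = (V_th − V_rest)/(m · V₀_anchor) with m the
  event count; κ is fixed at 1 and λ_eff solved analytically from the
  inverted lattice sum (λ_eff = 0.0544a). A synthetic anchor generated from
  any known (κ, λ) round-trips to the same product.
* **presets**: rest −70 mV / threshold −55 mV is the default pairing used
  with the 2 s anchor; a −75 mV rest preset (`REST_MINUS_75`) ships because
  parts of the source literature quote that value. The model intentionally
  omits conduction block above 150 Hz, ion-channel kinetics, fluctuation
  summation, diffuse-charge effects and current injection.

A caveat on "threshold independent of spacing": the bare exponential
lattice sum diverges as d → 0, so the statement that V₀ < 24.5 µV cannot
fire a neuron *regardless of d* holds over physically admissible spacings —
250 nm particles on a ~1 µm-radius cell cannot sit closer than d ≈ 0.25a —
and the test suite asserts the floor on that domain. With the calibrated
λ_eff, g saturates within a radius, so threshold V₀ is effectively flat in
d above contact distance (see `examples/02_membrane_model.py`).

Numerical details: crossings are reported at event times (half-open
interval convention); bisection tolerance is 0.05 µV with a doubling
bracket and a diagnostic error if no bracket is found; the default horizon
is 30 s; V(t) resets to rest between epochs.

## Calcium-event analysis

All windows are half-open [start, end); frame timestamps are
frame_index/fps (0-based); argmax ties resolve to the earliest frame.
F₀ and the baseline σ come from the 30 s before the *first* epoch onset.
Defaults: response window 15 s, responsiveness threshold 3σ, population
spike threshold 3σ of the cell-averaged trace's baseline, peak threshold
0.5 × "mean standard deviation".

Open readings resolved here (alternatives remain available via config):

* "mean standard deviation" = per-cell SD of ΔF/F₀ over the full recording,
  averaged across cells, applied uniformly (`peak_sd_scope="per_cell"` for
  the per-cell alternative);
* the 3σ responsiveness rule uses each cell's own baseline σ
  (`sigma_scope="pooled"` pools across cells);
* peak height is measured relative to the cell's baseline mean of ΔF/F₀.

Cells with non-positive F₀ or zero baseline variance are excluded and
logged, never imputed. Peak detection is a strict local-maximum scan with
plateaus counted once at their first frame (this tie rule is why it is not
delegated to a generic peak finder); an O(n²) brute-force scan verifies it.

## Photometry analysis

Pipeline order is fixed: 25 Hz second-order Butterworth low-pass applied
forward-backward (zero phase, so peak positions are not lag-shifted; DC
gain exactly 1) → two-term exponential debleach per channel → isosbestic
subtraction → segmentation → 2σ/20 s trial classification.

Debleaching fits a·e^(bt) + c·e^(dt) with a, c ≥ 0 and b, d ≤ 0 (decay
only — an unconstrained fit can chase evoked transients with growing
exponentials). Initialisation: slow term from a log-linear fit to the last
third, fast term from the first third of the remainder. Non-convergence
falls back to a single exponential plus constant with a warning. The full
pipeline masks stimulation windows from the fit (the trend is still
subtracted everywhere), so evoked transients do not bias the trend.

ΔF/F₀ normalisation: after debleaching the residual baseline is near zero,
so dividing a trial by its own residual pre-window mean is ill-posed. Each
trial's ΔF is the baseline-centred corrected signal, normalised by the
pre-window mean of the *filtered raw 470 nm channel* (positive, reflects
actual fluorescence). The 2σ classification is invariant to this choice of
denominator, and ΔF/F₀ is invariant under a common gain on both channels.

σ for the 2σ rule is computed per trial from that trial's pre-window
(a pooled value can be passed explicitly). Peak width is the interval
between the σ/2 crossings bracketing the maximum, linearly interpolated;
a trace that never returns to σ/2 yields a right-censored width with a
flag. Trials whose windows leave the recording are dropped with a warning;
windows overlapping a previous trial's post-window are allowed and logged.
Window presets: A = 30/150 s, B = 15/85 s.

## Synthetic data

The generators' defaults *are* the emulated study conditions: 300 cells,
5 × 2 s epochs at 30 s intervals at 1 fps with per-cell response
probabilities 0.741 / 0.463 / 0.276 for the three density presets and
stimulus-to-peak latency 3.9 ± 2.9 s; a 10-fps preset with 2 s epochs at
10 s intervals and latency 0.857 ± 0.069 s; photometry sessions at 130 Hz
with 20 trials, per-trial probabilities 0.791 (100 Hz / 5 s epochs,
15/85 s windows, 120 s spacing) and 0.659 (150 Hz / 2 s epochs, 30/150 s
windows, 180 s spacing), and a 5 min pre-stimulus baseline.

Design choices the emulated study does not pin down, chosen once on
literature-typical grounds:

* **kernels**: difference of exponentials, normalised to unit peak; calcium
  rise 0.2 s / decay 1.5 s ("6s"-like; a faster-decay "6f" preset exists),
  photometry primary 0.5/8 s, secondary 5/80 s with ~80 s decay enabled in
  the in vivo presets only. The per-event amplitude is 1.0 ΔF/F₀ in vitro
  and 0.05 (primary) / 0.01 (secondary) fractional in vivo.
* **latency truncation**: the planted distribution is a normal truncated
  *symmetrically about its mean* (bounds [max(0, 2µ−hi), hi] with
  hi = min(2µ, window end)). One-sided truncation at 0 would shift the
  realised mean of N(3.9, 2.9²) to ≈4.4 s, i.e. the generator would not
  plant the condition it claims to plant; the symmetric bounds keep the
  planted mean exactly at `latency_mean` while still excluding negative
  and out-of-window latencies.
* **peak alignment**: transients are placed so the kernel *peak* (the
  quantity the latency statistic measures) lands on the planted latency,
  snapped to the frame grid. Ground truth is thereby expressed at the
  resolution the measurement can recover; unsnapped continuous peaks would
  add an asymmetric-kernel quantisation bias (~+0.2 s at 1 fps) to the
  recovered mean that is an artifact of the comparison, not of the method.
* **baseline structure**: in addition to white Gaussian noise (SD 0.005
  ΔF/F₀ in vitro, 0.001 fractional per photometry channel), baselines carry
  a bounded quasi-periodic component — a per-cell slow fluctuation
  (amplitude 0.02 ΔF/F₀, ~0.1 Hz, frequency jittered ±30% per cell)
  mimicking slow spontaneous network activity in culture, and an ongoing
  slow calcium oscillation (amplitude 0.01, ~0.25 Hz with a wandering
  phase) on the 470 nm channel in vivo. This is not cosmetic: a
  max-over-window σ-threshold rule fires with high probability on *any*
  stationary Gaussian baseline regardless of noise scale (the max of
  hundreds of effectively independent samples exceeds 2–3σ almost surely),
  whereas real recordings — whose baseline variance is dominated by bounded
  physiological fluctuations (a sinusoid's max is only √2 its SD) — make
  the rule selective. With this structure the classifiers recover the
  planted Bernoulli draws essentially exactly, which is precisely the
  regime the σ-rules were designed for.
* **photometry channels**: 470 = bleach(t)·(1 + transients + oscillation +
  motion + noise), 405 = bleach(t)·(1 + motion + noise) with the identical
  motion realisation (band-limited 0–5 Hz Gaussian, SD 0.01). The two
  bleach curves (20·e^(−t/60) + 80·e^(−t/2000) vs 19·e^(−t/70) +
  76·e^(−t/2200)) are similar but not identical, so subtraction suppresses
  the artifact >10× rather than perfectly. Fluorescence is clipped at a
  small positive floor (clipping logged).
* **10-fps preset analysis**: response window 10 s (instead of 15 s)
  because the fast configuration spaces epochs 12 s apart and a 15 s
  window would reach into the next epoch's transient.

What passing recovery tests shows — and does not. The loop "generate with
planted parameters → analyse → recover" validates the analysis rules,
window conventions, σ estimation and the pipeline plumbing end-to-end. It
does not validate behaviour on features the generator omits: non-stationary
baseline drift faster than the bleach model, hemodynamic contamination that
differs between channels, overlapping multi-event responses within one
window, cell-to-cell amplitude heterogeneity, or detector saturation. On
real data the σ-rules inherit the false-positive behaviour of whatever
baseline structure is actually present.

## Problem sizes

Stochastic quantities in tests and in `scripts/acceptance.py` use 10
generated datasets per quantity (10 × 300 cells × 5 epochs in vitro;
10 × 20 trials in vivo), matching the study-scale presets while keeping
the whole suite in the minutes range on a single CPU. Monte-Carlo oracles
for false-positive rates use 2 × 10⁴ draws; Poisson layout checks use
≥10⁴ particles with periodic boundaries (edge effects would otherwise bias
the nearest-neighbour mean by ~2/√n).
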