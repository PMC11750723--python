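# mendkit

Modelling and trace-analysis tools for **magnetoelectric nanodisc (MEND)
neuromodulation**: how disc-shaped Fe₃O₄–CoFe₂O₄–BaTiO₃ particles convert
applied magnetic fields into sub-millivolt membrane potentials, how those
potentials sum to fire neurons, and how the resulting calcium-imaging and
fibre-photometry recordings are quantified. A synthetic-data module
generates both data modalities with exact ground truth, so every analysis
stage can be validated by parameter recovery without any experimental data.

Intended for computational neuroscientists and bioelectronics researchers
who want to reason quantitatively about magnetoelectric stimulation doses,
or to reuse/benchmark the trace-statistics pipelines.

## The models

**Transduction.** A particle in an offset field H_OMF (magnetising it near
saturation) and an alternating field H_AMF at frequency f develops a surface
polarisation summarised by the magnetoelectric coefficient α_ME
(mV mT⁻¹ cm⁻¹). The potential presented to an adjacent membrane is

    V₀ = α_ME · H_AMF · L,

with L a characteristic length (the 250 nm disc diameter by default):
150 mV mT⁻¹ cm⁻¹ × 10 mT × 250 nm = **37.5 µV**. An empirical separable
model α(f, H) = α_ref (f/f_ref)^p G(H) captures the sub-resonance rise with
frequency and the peak near the saturating offset field (220 mT).

**Membrane model.** V₀ is three orders of magnitude below the ~15 mV needed
to reach threshold, so excitation relies on *temporal summation*: each AMF
half-cycle deposits a rectified increment

    ΔV = κ · g(d) · V₀,      g(d) = 1 + 2 Σₙ e^(−n·d/λ_eff)

(g is the cable-theory lattice sum over neighbouring particles at spacing d,
closed form 1 + 2e^(−x)/(1−e^(−x))), integrated losslessly at 2f events per
second from rest (−70 mV) toward threshold (−55 mV). Calibrating to the
printed anchor — V₀ = 24.5 µV at d = 0.25a and 150 Hz reaches threshold in
exactly 2 s — fixes κ·g(0.25a) = 15000/(600 × 24.5) = 1.0204. Threshold V₀,
time-to-threshold and full trajectories are exposed, with bisection checked
against closed forms.

**Calcium events (in vitro).** ΔF/F₀ against a 30 s pre-stimulus baseline;
peak counting above half the mean per-cell SD; a cell is *responsive* for an
epoch when ΔF/F₀ exceeds 3σ of its baseline within 15 s of onset; the
population *spiking probability* counts epochs whose cell-averaged trace
exceeds 3σ; *latency* is the stimulus-to-peak time of responsive pairs.

**Photometry (in vivo).** 130 Hz two-channel recordings are low-pass
filtered (25 Hz, second-order Butterworth, zero phase), each channel is
debleached by subtracting a fitted two-term exponential, the isosbestic
405 nm channel is subtracted from the 470 nm channel to cancel shared
motion artifacts, and trials are segmented (30/150 s or 15/85 s windows)
and classified responsive when ΔF/F₀ ≥ 2σ within 20 s of onset, with peak
intensity/position and the σ/2 width reported.

## Worked example

```python
from mendkit.synthetic import calcium_preset, gen_calcium_dataset
from mendkit.calcium import event_table

traces, truth = gen_calcium_dataset(calcium_preset("invitro-0.75", seed=42))
table, summary = event_table(traces)
print([round(x, 3) for x in summary["responsiveness_per_epoch"]])
print(round(summary["latency_mean"], 2), "s")
```

prints

```
[0.727, 0.707, 0.737, 0.74, 0.747]
3.92 s
```

— the per-epoch fractions of responsive cells scatter around the preset's
planted probability 0.741 (binomial noise over 300 cells), and the mean
stimulus-to-peak latency recovers the planted 3.9 s distribution. The
`examples/` directory holds one short narrative script per capability
(transduction, membrane model, calcium events, photometry, particle
layouts); each prints the numbers it computes and what they mean.

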