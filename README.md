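# neurotracekit

Analysis toolkit for cellular neurophysiology experiments on cultured
neurons: whole-cell patch-clamp excitability and conductance measurements,
miniature EPSC statistics, somatic calcium-imaging synchrony,
nuclear/cytoplasmic fluorescence ratios, and RT-qPCR compartment
proportions — together with ground-truth simulators that make every
analysis verifiable without access to raw recordings.

It is written for electrophysiologists and imaging labs who want the
quantities their figures report — rheobase, AP half width, Kir/HCN/A-type
slope conductances, mEPSC frequency and amplitude, synchronous-event
frequency, Crtc-style localization ratios — computed by transparent,
tested code instead of point-and-click software.

## What it computes

* **AP excitability** (`spike_features`): AP threshold at the point where
  dV/dt exceeds 20 mV/ms; amplitude, half width, AHP amplitude and delay
  measured relative to that threshold; rheobase (minimum 1 s current step
  evoking an AP); input/output curves; accommodation index
  (t_N − t_{N−1})/(t_2 − t_1) on trains of ≥ 6 APs.
* **Passive properties** (`passive_membrane`): resting potential, input
  resistance R_in = dV/dI from hyperpolarizing steps, whole-cell
  capacitance C = ∫I_transient dt / ΔV, access-resistance QC at 25 MΩ.
* **Voltage-clamp conductances** (`vclamp_conductances`): from 1 s steps
  −60→−130 mV, g_Kir as the instantaneous-slope difference between
  −110…−130 and −70…−90 mV, and g_HCN as the slope of steady-minus-
  instantaneous current over −110…−130 mV; g_A from the 4-AP-sensitive
  digitally subtracted current peaking 3–13 ms after depolarization, fit
  over −20…+35 mV.
* **mEPSCs** (`mepsc`): event detection with amplitude/prominence/rise-time
  criteria; events < 10 ms after the previous one count toward frequency
  but are excluded from amplitude statistics; 200-event sufficiency flag.
* **Calcium synchrony** (`fluorescence`): ΔF/F₀ = (F−F₀)/F₀ on
  background-subtracted traces; synchronous network events are population
  ΔF/F peaks reaching at least 1/10 of the reference transient evoked by
  bicuculline at the end of the recording.
* **Localization** (`fluorescence.nuc_cyto_ratio`): nucleus from the
  nuclear-stain channel (Otsu), ratio of mean nuclear to mean cytoplasmic
  marker intensity.
* **qPCR fractions** (`qpcr_fractions`): nuclear proportion
  2^(−Ct_nuc)/(2^(−Ct_nuc)+2^(−Ct_cyt)), arcsine-transformed summaries,
  2^(−ΔΔCt) fold changes.
* **Statistics** (`stats_report`): Shapiro–Wilk-gated choice between a
  two-tailed t test (mean ± SD) and an exact two-sample Kolmogorov–Smirnov
  test (median ± IQR); ratio paired t tests; BH / Holm / Holm–Šidák /
  Bonferroni adjustments implemented in-package; two-way and
  repeated-measures ANOVA with Greenhouse–Geisser correction.
* **Simulators** (`synth`): a Hodgkin–Huxley-style single-compartment
  neuron (current clamp), closed-form voltage-clamp current families,
  Poisson mEPSC trains, multi-ROI calcium fields with a bicuculline
  reference segment, two-channel cell images and Ct tables — each returning
  a `GroundTruth` record sufficient to score its matching analysis.

All recordings move through one container (`SweepSeries` of `Trace`s with a
`StepProtocol`), stored as an inspectable columnar text format (or HDF5)
with lossless round trips.  Junction-potential correction (−10 mV) is
applied explicitly, flagged, and refuses double application.

## Worked example

Simulate a current-clamp step family (0–100 pA, 10 pA increments, 1 s
steps) of the default model neuron, apply the junction correction, and
extract its excitability profile:

```python
import numpy as np
from neurotracekit.synth import (NeuronParams, simulate_current_clamp,
                                 standard_current_clamp_protocol)
from neurotracekit.spike_features import rheobase_analysis
from neurotracekit.trace_io import apply_junction_correction

params = NeuronParams(seed=42)
series, truth = simulate_current_clamp(params, standard_current_clamp_protocol())
series = apply_junction_correction(series, jp=10.0)
exc = rheobase_analysis(series)
print(f"rheobase: {exc.rheobase:.0f} pA   (simulator ground truth: {truth.rheobase:.0f} pA)")
ap = exc.first_ap
print(f"threshold: {ap.threshold_V:.1f} mV   amplitude: {ap.amplitude:.1f} mV")
print(f"half width: {ap.half_width:.2f} ms   AHP: {ap.ahp_amplitude:.1f} mV after {ap.ahp_delay:.1f} ms")
print(f"accommodation index: {exc.accommodation_index:.3f}")
print("I/O curve:", {int(k): v for k, v in exc.io_curve.items()})
```

prints

```
rheobase: 50 pA   (simulator ground truth: 50 pA)
threshold: -61.9 mV   amplitude: 97.3 mV
half width: 1.72 ms   AHP: 25.2 mV after 5.0 ms
accommodation index: 1.029
I/O curve: {0: 0, 10: 0, 20: 0, 30: 0, 40: 0, 50: 1, 60: 27, 70: 31, 80: 34, 90: 36, 100: 38}
```

The first spiking step (50 pA) matches the simulator's ground truth; the
junction-corrected threshold sits near −62 mV; the accommodation index
slightly above 1 reflects the default adaptation conductance.  The same
analyses are available from the shell:

```bash
neurotracekit simulate cc family.txt --seed 42
neurotracekit spikes family.txt
neurotracekit run --seed 1 --out results/   # two-cohort demo pipeline
```

`neurotracekit run` simulates a control and a shifted-excitability cohort,
extracts per-cell features, and compares them with the gated statistics
layer, writing tidy `features.csv` and `stats.csv` tables.

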