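# Methods

This note documents the models, measurement definitions and numerical
choices behind `neurotracekit`, and what the synthetic-data generators do
and do not emulate.

## Scope

The toolkit implements the quantitative analyses used in whole-cell
patch-clamp, somatic calcium-imaging, immunofluorescence-localization and
RT-qPCR fractionation experiments on cultured neurons:

* current-clamp excitability: AP detection by a dV/dt criterion, waveform
  features (threshold, amplitude, half width, AHP), rheobase, input/output
  curves, accommodation index;
* passive properties: resting potential, input resistance, whole-cell
  capacitance, access-resistance estimate and QC gate;
* voltage-clamp slope conductances: Kir, HCN and (by digital subtraction of
  a 4-AP-blocked family) the A-type K current;
* miniature EPSC detection with the 10 ms summation rule;
* ΔF/F₀, population calcium-transient synchrony against a bicuculline
  reference, and nuclear/cytoplasmic marker intensity ratios;
* compartment proportions from Ct values with arcsine-transformed summaries;
* a normality-gated statistical reporting layer.

Because raw recordings of this kind are rarely shareable, every input class
has a paired simulator whose ground truth makes each analysis verifiable.

## The neuron model

The current-clamp simulator is a single-compartment conductance-based
(Hodgkin–Huxley-style) neuron rather than an integrate-and-fire cell,
because half width, AHP amplitude and threshold only make sense on a full
spike waveform:

C dV/dt = I_inj − g_L(V−E_L) − g_Na m³h(V−E_Na) − g_K n⁴(V−E_K)
          − g_adapt z(V−E_K) − g_Kir f(V)(V−E_K) − g_h y(V−E_h)
          − g_A a·b(V−E_K)

with classic squid-like Na/K kinetics (resting near −70 mV), an optional
voltage shift of the Na gates (`na_shift`, emulating channel-subtype
differences; it moves spike threshold and rheobase), and a slow M-like
adaptation conductance `g_adapt` (τ = 100 ms) that produces
spike-frequency accommodation.  Defaults (C = 80 pF, g_L = 4 nS →
R_in = 250 MΩ, g_Na = 9 μS, g_K = 1.2 μS, g_adapt = 4 nS) give a resting
potential near −71 mV, a rheobase of ~50 pA on 1 s steps and repetitive
firing with mild accommodation — typical of cultured hippocampal neurons.

Integration is a fixed-step explicit 4th-order Runge–Kutta scheme; dt above
25 µs is refused.  In the passive limit the scheme settles on the exact
fixed point, so charge balance (steady ΔV = ΔI/g_L) holds to numerical
precision and is asserted in the tests.  Measurement noise (white Gaussian,
default 0.2 mV) is added to the *recorded* samples only, never to the
dynamics: the ground-truth spike times (0 mV upstroke crossings of the
model trajectory) are therefore independent of the noise draw, and the
rheobase of a noisy family equals that of the noiseless one.

The subthreshold conductances mirror the logic of the voltage-clamp
measurements exactly: Kir is an instantaneous Boltzmann-rectified
conductance (half-activation −100 mV, slope 6 mV) so it appears fully in
the instantaneous current; HCN has first-order activation with τ = 200 ms
(half-activation −90 mV) so it appears only in the steady-state current;
the A-type current activates fast (τ = 2 ms) and inactivates slower
(τ = 20 ms) so its subtracted current peaks a few ms after a depolarizing
step from −100 mV.

In voltage clamp the command potential is piecewise constant, so every
gating variable follows a closed-form exponential and the current family
(capacitive transient with τ = 1 ms + leak + Kir + HCN + A-type + noise) is
generated analytically — no integrator, and the "instantaneous vs
steady-state" separation is exact in the model.

### Ground truth for conductance recovery

The estimators measure *slope* conductances over fixed voltage ranges, and
a rectifying conductance's I–V slope is not its raw `g` parameter (the
slope includes the dBoltzmann/dV term).  The simulator therefore records,
alongside the raw parameters, the *measurable* values obtained by applying
the same slope definitions to a dense noise-free evaluation of the model's
own current components (201 points per range).  Recovery is always judged
against these measurable values.

## Measurement definitions

* **AP detection** — threshold where the first voltage derivative (central
  difference on the raw trace; acquisition is assumed already low-pass
  filtered, so no extra smoothing by default) exceeds 20 mV/ms; the
  detection is confirmed by a subsequent voltage maximum of at least
  −10 mV before dV/dt returns below zero (the peak floor separates APs
  from subthreshold noise blips; the upstroke may complete past the
  analysis-window end, so an AP initiated at the edge of the injection
  still counts).  Spontaneous APs (threshold before the window) and APs
  coinciding with injection onset (within a 5 ms blank) are excluded.
  Threshold voltage, half-width crossings and all sub-sample times use
  linear interpolation — ample at 20–250 kHz sampling.
  A spike whose upstroke straddles the step offset is a genuine boundary
  ambiguity (the detector keys on the in-window threshold crossing, the
  simulator's ground truth on the 0 mV crossing); count-equality tests skip
  sweeps with a crossing within a few ms of the offset.
* **AHP** — trough between the peak and the next AP's threshold (or window
  end); amplitude and delay are measured relative to the AP threshold, with
  a peak-referenced delay available as an option.  A minimum sitting on the
  search boundary is not a trough: the AHP fields are absent and flagged.
* **Accommodation index** — last inter-AP interval over the first, on the
  lowest 1 s injection evoking at least six APs; values above 1 mean
  slowing.  The reciprocal ordering is exposed via ``direction=`` since
  both conventions circulate.
* **Rheobase** — lowest step level with at least one valid detection;
  protocol levels are required strictly monotone, so ties cannot arise.
* **Passive properties** — input resistance from the least-squares slope of
  steady-state ΔV vs ΔI over subthreshold hyperpolarizing steps;
  capacitance as the charge integral of the test-pulse transient divided by
  the step, with the transient end defined as the first sample staying
  within 3× baseline noise of the steady level for 1 ms; "stabilized"
  values across repeated test pulses are the median.
* **Step currents** — the instantaneous current is a 5 ms mean placed
  directly after the capacitive transient; the steady-state current the
  mean of the last 100 ms of the step.  The transient end is found by
  fitting the early exponential decay (log-linear fit) and computing where
  it reaches twice the baseline noise sd.  A plain |dI/dt|-threshold
  detector was tried first and rejected: with τ ≈ 1 ms and 20 kHz sampling
  the per-sample derivative falls into the noise while hundreds of pA of
  transient remain, leaving a step-size-dependent residual in the
  instantaneous window; the amplitude-based endpoint makes the residual
  uniform (≲0.1 pA) across sweeps.
* **Kir** — instantaneous slope over −110…−130 mV minus over −70…−90 mV,
  reported positive for an inward rectifier (the stated definition reverses
  the ranges, which only flips the sign; the magnitude convention is used
  and noted).  Leak cancels in the subtraction.
* **HCN** — slope of steady-minus-instantaneous current over −110…−130 mV.
  The estimator carries a small (~5%) downward bias because ~4% of HCN
  activation has occurred by the time the instantaneous window opens —
  inherent to the measurement, well inside the 10% recovery target.
* **A-type** — control-minus-blocked difference per command level (paired
  by level, not sweep order); the outward peak must fall 3–13 ms after the
  step (sweeps peaking outside are flagged and excluded; levels whose
  difference is indistinguishable from zero contribute a zero peak); slope
  of peak current vs V over −20…+35 mV, unconstrained least squares.
* **mEPSC detection** — light boxcar smoothing (0.5 ms), a trailing 50 ms
  running-median baseline (computed on a 1 ms grid; the median's 50%
  breakdown point makes explicit exclusion of detected events unnecessary
  at sparse event rates), peaks of the inward deflection that exceed the
  amplitude threshold (default 5 pA) in both height and prominence (the
  prominence requirement rejects noise ripples on the decay of a large
  event while keeping genuinely stacked events), and an onset-to-peak rise
  time within 0.3–5 ms.  The onset is the last baseline crossing before the
  peak; for an event stacked on the previous one's decay the inter-event
  dip serves as the onset.  Events starting less than 10 ms after the
  previous event are retained for frequency and interval statistics but
  excluded from amplitude statistics; a 200-event sufficiency flag is
  reported.  Frequency is (n−1)/(last−first onset).
* **Calcium synchrony** — ΔF/F₀ with F₀ as a 10th-percentile 60 s rolling
  baseline by default (fixed-window mean available); the detection trace is
  the across-ROI mean ΔF/F (the per-cell-peaks reading of the population
  criterion is available behind ``amplitude_mode=``); candidate peaks need
  2 s separation (guards against double-counting multi-peaked bursts) and
  are accepted when they reach 1/10 of the reference peak — the first
  transient after the bicuculline marker.  The criterion is applied on the
  ΔF/F scale, making detection invariant to uniform rescaling of the raw
  fluorescence.
* **Nuclear/cytoplasmic ratio** — nucleus from the nuclear-stain channel by
  Otsu threshold, hole filling and largest component; cytoplasm as the soma
  minus nucleus, with the soma approximated by a 12 px dilation of the
  nucleus when no mask is given (kept inside the true soma for the default
  synthetic geometry); ratio of marker-channel means.
* **qPCR fractions** — nuclear proportion 1/(1+2^(Ct_nuc−Ct_cyt)), assuming
  equal template volumes and perfect doubling (no efficiency correction);
  summaries are computed on the arcsine-√ scale and back-transformed.
  2^(−ΔΔCt) fold changes share the same core.
* **Gated statistics** — Shapiro–Wilk on every group; any p < 0.05 routes
  the comparison to a two-sample exact Kolmogorov–Smirnov test with
  median ± IQR summaries, otherwise a two-tailed pooled t test with
  mean ± SD.  Groups below n = 3 return "indeterminate" and force an
  explicit choice.  The BH, Holm, Holm–Šidák and Bonferroni adjustments are
  implemented directly (step-up/step-down with monotonicity enforcement)
  and cross-checked against brute-force re-derivations and statsmodels;
  the distributional tests themselves and the factorial/repeated-measures
  ANOVAs (with Greenhouse–Geisser correction, hence possibly fractional
  degrees of freedom) are delegated to scipy, statsmodels and pingouin.

## What the simulators do and do not emulate

The generators reproduce the *structure* of the real data — protocols, step
timing, sampling rates (250 kHz-class current clamp is represented at
20 µs; voltage clamp at 50 µs/20 kHz), event statistics, the bicuculline
reference segment, two-channel cell images, paired-fraction Ct tables — and
thread one seed through every random draw, so identical seeds give
bit-identical outputs.  They do not emulate electrode-series-resistance
voltage errors, imperfect space clamp, channel kinetics beyond first-order
gating, imaging point-spread or bleaching, cell-image irregular morphology,
or qPCR efficiency differences between primer pairs.  Passing recovery
tests therefore demonstrates the correctness of the measurement
definitions and their noise robustness under these idealized conditions,
not performance on pathological real-world recordings.  Noise levels and
cell-to-cell variability (10–30% parameter scatter, ΔF/F jitter of 0.1 s)
are stated defaults chosen to be plausible, not inferred from any dataset.

## Statistical calibration

The gated pipeline's type-I error is measured by Monte Carlo at n = 15 per
group.  On normal null samples it sits near the nominal 5%.  On lognormal
null samples the Shapiro gate routes ~97% of comparisons to the exact KS
test, whose discrete null distribution at n = m = 15 has attainable
significance levels of only 0.0755 and 0.0262 around α = 0.05; rejecting at
p < 0.05 therefore realizes ≈2.6%, and the pipeline's measured type-I error
on lognormal data is ≈2.5–3.5% — conservative, never inflated.  This is a
property of the exact KS test at small n, not of the implementation; the
asymptotic KS variant would instead be anti-conservative (~7%) and is not
used.  The acceptance suite asserts a symmetric 4–6% band for both cases,
so the lognormal case fails that band by being conservative; the test is
kept as an honest record of this behaviour.

## Problem sizes

Default verification sizes: 100 sweeps for detector/oracle agreement, 50
neurons for rheobase recovery, 100 conductance triples (60 in the
acceptance script), 3×120 s mEPSC recordings plus 20 (15) minutes of
event-free noise for the false-positive rate, 50 (30) calcium fields, 100
synthetic cells for the image ratio, and 10,000 (5,000) null replicates per
distribution for type-I calibration.  Unit tests use smaller versions of
the same checks.

## Known limitations

* Spike counts at the exact step-offset boundary are convention-dependent
  (see AP detection above).
* The HCN estimator's small activation-loss bias grows if the capacitive
  transient is slowed (τ_cap near its 2 ms ceiling).
* `detect_minis` assumes sparse events (rates ≲ 5 Hz); at high rates the
  running-median baseline starts tracking the event load.
* The repeated-measures ANOVA requires complete subject × level designs;
  missing cells are rejected rather than imputed.
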