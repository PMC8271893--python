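# Methods

## Study design being modelled

A Go/Nogo sign-comparison task: three traffic-sign shapes (triangle,
circle, rectangle), 20 trials per shape per subject, stimuli "different"
with probability 0.75, response (left/right click) required within
1.8 s; a wrong click or a timeout counts as incorrect.  Two groups of 10
subjects (elderly, youth).  EEG is epoched from −1 s to +2 s around
stimulus onset; analysis works on averaged traces and on the
N200/P300/N400/P600 latencies detected in them.

## Synthetic data model

Each epoch is

```
x(t) = Σ_c A_c · exp(−(t − λ_c)² / 2σ_c²) + ε(t)
```

with one Gaussian bump per component and band-limited noise ε.

* **Latencies λ_c** (correct condition): the group-average reference
  values — elderly 236/398/509/640 ms, youth 220/396/507/626 ms for
  N200/P300/N400/P600.  In the incorrect condition each λ_c is shifted
  by the group's published gap time (elderly +12/+29/+14/−12 ms, youth
  +32/+31/−7/+20 ms), so the generator's shift parameter is the ground
  truth that detection-based gap estimates are judged against.
* **Amplitudes A_c**: −5/+8/−4/+5 µV — field-typical magnitudes with the
  correct polarity (N components negative, P components positive).
* **Widths σ_c**: 20/22/22/28 ms.  A Gaussian bump is a deliberately
  stylised component; widths were chosen narrow enough that the closest
  configured spacing (73 ms, shifted youth P300→N400) leaves each
  extremum displaced by less than one sample on a noiseless trace, so
  the noiseless parameter-recovery contract is exact.  Real P300s are
  broader and asymmetric.
* **Noise ε**: white Gaussian filtered to 4–30 Hz (the analysis band)
  and rescaled to `noise_sd_uV` — default 10 µV single-trial, roughly
  EEG-like relative to the bump amplitudes.  Incorrect-condition noise
  is multiplied by `fluctuation_gain_incorrect` (default 2), encoding
  the observation that incorrect-trial traces fluctuate more.  Because
  incorrect trials are also *rarer* (error rates ~12–25 %), their
  averages are much noisier — the generator reproduces that property of
  the real data automatically.
* **Behaviour**: per-shape error rates default to the reference
  incorrect/(correct+incorrect) ratios (elderly ≈ 0.25/0.18/0.20, youth
  ≈ 0.12/0.16/0.16); 20 % of incorrect trials are timeouts
  (`response=none`), the remainder wrong clicks; correct-response times
  are normal(650, 150) ms clipped to [200, 1800] ms, wrong clicks
  normal(950, 250) ms.  The wrong-click/timeout split and the response
  time model are not constrained by the reference tables; they only
  need to produce valid logs.  Stimulus duration is recorded as 200 ms
  metadata.

What the generator does **not** emulate: multichannel topography (the
ROI averaging operation is exercised on synthetic multichannel arrays),
ocular/muscle artifacts, 1/f background spectra, inter-subject latency
variability beyond noise, and amplitude effects of age or attention.
Passing tests therefore demonstrate the *pipeline's* correctness under
the stated statistical structure, not fidelity to any particular
recording.

## Preprocessing variants

1. `original_avg` — identity on the averaged trace.
2. `smoothed` — centred moving average, window 20 ms forced to an odd
   sample count (21 samples at 1 kHz); edges use shrinking windows so no
   data is invented and constants are preserved.
3. `zero_phase` — Butterworth band-pass of order 4 (4–30 Hz) applied
   forward and backward (`sosfiltfilt`), giving zero net phase shift:
   the lag of the peak cross-correlation between any in-band sinusoid
   and its filtered version is 0.  The filter family is a design choice;
   only "zero-phase band-pass 4–30 Hz" is prescribed.
4. `zero_phase_smoothed` — (3) followed by (2), exactly composition.

The default 12-channel ROI (CP1, CPz, CP2, P3, Pz, P4, PO3, POz, PO4,
O1, Oz, O2) covers the centro-parietal/occipital area engaged by shape
recognition; the exact channel set is configurable since only the
region, not the channel names, is fixed by the design.

## Detection

All detectors operate on interior local extrema of the search range,
ties broken toward the earliest time (latency is the quantity of
interest), with a fallback to the range extremum when no interior
extremum exists.  The P300 stage accepts a candidate only if it occurs
after the N200 and exceeds a configurable prominence threshold
(`prominence_uV`, default 0, i.e. any interior local maximum — the
notion of an "appropriate" maximum is formalised here as prominence).
If no candidate survives, the fixed-gap-time fallback searches
n200 + 250 ± 100 ms (the ±100 ms half-width is a design choice; only
the 250 ms gap is prescribed), guaranteeing
|p300 − (n200 + 250)| ≤ 100 ms whenever `via_fgt` is set.  N400 and
P600 searches are constrained to start after the previously detected
component because the textbook ranges overlap; without the constraint
the same dip could be counted twice.  An empty constrained range (e.g.
P300 ≥ 600 ms) yields an absent N400 rather than an error.

Feature windows are the half-open 1 s segment starting at the detected
N200, linearly resampled at 70 evenly spaced points (inclusive of both
ends, so resampling at the native length is the identity).

## Summary arithmetic

Population SD (divisor *n*) is used throughout because the reference
tables report dispersion of complete small groups, not sample
estimates.  The error rate is the ratio of mean counts
(mean incorrect / mean total); the alternative mean-of-per-subject-
ratios is also computed (`error_rate_mean_of_ratios`) since the two
conventions differ and published per-shape percentages are not fully
consistent with either.  Gap times are incorrect-minus-correct mean
latencies, rounded to whole milliseconds by default.

## Classifiers

**GMM.**  Observation model: each amplitude sample of a 1 s feature
window is one univariate observation; the correct-answer model is a
10-component univariate mixture over the group's pooled correct
windows, and a trace (or a subject's pooled windows) is scored by its
summed log-likelihood.  EM uses deterministic initialisation (means at
the (k+½)/K quantiles, equal weights, pooled variance), a relative
log-likelihood tolerance of 1e-6, at most 500 iterations, and a
variance floor of 1e-6 × total variance (floored components are
flagged).  The log-likelihood is asserted non-decreasing every
iteration.  Scoring uses log-sum-exp.  Per-trace granularity is
supported by calling `gmm_loglik` per window; per-subject pooling is
the default in the pipeline because subject-level summaries are the
reporting unit.

**MLP.**  70-20-10-1, ReLU hidden / logistic output, binary
cross-entropy, full-batch Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), 500
epochs, He initialisation, deterministic per seed.  Inputs are
standardised with training-set statistics (stored on the model) — the
raw µV scale is otherwise awkward for fixed-hyperparameter training.
Forward/backward passes are explicit so analytic gradients can be (and
are) checked against central finite differences.  A probability of
exactly 0.5 maps to class 1, fixed convention.  Cross-validation is
stratified 4-fold with seeded shuffling; fold accuracies are aggregated
as mean ± population SD.

## Pipeline and problem sizes

`run_pipeline` simulates the configured groups (default 10 subjects,
20 trials/shape), averages per subject × shape × condition, applies one
variant, detects latencies, and evaluates both classifiers per group on
the ~60 resulting traces.  At default noise the incorrect-condition
cell averages contain only ~4 trials, so the per-cell latency table is
dominated by detection jitter — as in real recordings with few error
trials.  Gap-time recovery is therefore demonstrated on grand-average
traces (all correct vs all incorrect epochs of a group), where the
detected elderly P300 gap re-finds the configured 29 ms shift to within
a few milliseconds.

Monte-Carlo checks use: 100 simulated subjects (60-trial averages,
single-trial noise 4 µV = half the P300 amplitude) for the
latency-recovery RMSE, pooled across the four components; 50 seeds for
grand-average gap recovery; 20 seeds for two-component mixture
recovery; 10 seeds for end-to-end cross-validated accuracy.  These
sizes keep the whole acceptance run around two minutes on one CPU while
leaving the Monte-Carlo error well below the quantities' tolerances.

## Known limitations

* The Gaussian-bump ERP model is stylised; detection robustness numbers
  (e.g. the <5 ms RMSE) are specific to it.  Sharp bumps lose some
  sub-4 Hz energy to the band-pass, which can nudge detected latencies
  by a few milliseconds on filtered variants — visible as a small bias,
  absent on the smoothed variant.
* Published per-subject dispersion cells (count SDs and latency SDs)
  are computed from unrounded subject-level data that is not available,
  so they cannot be reproduced from the printed per-shape values; the
  package reproduces the means, error rates, gap times and CV
  aggregation exactly, and documents the dispersion mismatch in its
  acceptance test.
* EDF or vendor-format import is out of scope; the epoch-bundle HDF5
  container and CSV logs are the only on-disk formats.
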