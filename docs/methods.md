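# Methods

## What the pipeline computes

`ergosc` analyzes *spontaneous* (non-evoked) electroretinogram recordings:
minutes of corneal or skin-electrode voltage sampled at 1 kHz with no flash
stimulus.  The working hypothesis is that intrinsic retinal oscillations —
band-structured activity at 0.3–2, 10–20, and 20–40 Hz in humans and
0.1–10 Hz in rodents — carry information about systemic metabolic status
(overweight, obesity, metabolic syndrome, diabetes without retinopathy)
before the evoked oscillatory potentials change.  The pipeline turns a raw
recording into normalized wavelet band features, trains random-forest
screening models on them, and provides the explanatory statistics (PCA, LDA,
Welch ANOVA, correlations) used to interpret such models.

Because no patient data ship with the package, a first-class synthetic
cohort generator provides ground truth for every stage; all quantitative
claims the test suite and `scripts/acceptance.py` make are claims about that
generator's output, not about clinical data (see *What the synthetic data do
and do not show* below).

## Signal conditioning

1. **Band-limiting.** High-pass at 0.1 Hz (rodents) or 0.3 Hz (humans), with
   an optional 50 Hz mains notch.  The filter is realized in the frequency
   domain: the squared magnitude of a 4th-order Butterworth high-pass —
   identical to the steady-state response of the same filter applied
   forward-backward — and a Gaussian notch whose half-power width matches a
   quality-30 IIR notch (`f0/Q` ≈ 1.7 Hz).  Rationale: a recursive filter
   with a sub-hertz cutoff has edge transients of several seconds (pole
   radius ≈ 0.9993 at 1 kHz) that no padding removes and that leak ~10%
   spurious RMS into minute-scale records; the spectral realization is
   zero-phase, strictly linear, has no transients, and makes the notch
   attenuate a 60-s mains tone below 0.01% RMS.  The cost is the implicit
   circular (periodic) signal model, which is also assumed by the wavelet
   stage and masked there by the cone of influence.  The nominal acquisition
   low-pass "at 1 kHz" is an analog anti-alias setting of the amplifier and
   has no digital counterpart at a 1 kHz sampling rate.
2. **Artifact rejection** precedes normalization: any sample with
   |v| > 100 μV (strict inequality) marks an excursion.  Default granularity
   rejects the whole recording; segment granularity keeps the clean
   fixed-length segments instead.  Blink artifacts are orders of magnitude
   larger than the spontaneous signal, so a plain amplitude rule suffices.
3. **Normalization** maps the whole recording affinely onto [−1, +1]
   (idempotent; constant signals are rejected).  Per-recording rather than
   per-epoch, matching the conditioning order filter → reject → normalize.
4. **Epoching.** `segment_epochs` returns ⌊T/w⌋ consecutive complete
   windows from t = 0; `sample_fragments` extracts seeded random one-minute
   fragments, by default all complete non-overlapping ones on the aligned
   grid (a 300-s recording yields five).

## Wavelet band features

The Morlet transform is an FFT filterbank: for analysis frequency *f* the
signal's FFT is multiplied by the Gaussian gain
G_f(ν) = 2·exp(−(ν−f)²/(2σ_f²)), σ_f = f/m, over positive frequencies
(analytic convention) and inverse-transformed; |W(f,t)|² is the scalogram.

* **Cycles m = 7** (configurable): the common fixed time-frequency
  trade-off; the wavelet spans m/f seconds, so a 0.3 Hz estimate uses ~23 s
  of signal.
* **Output grids** are 0.05 Hz × 0.01 s — interpreted as output resolutions,
  not wavelet bandwidths.  The human band 0.3–40 Hz therefore yields 795
  power features per fragment.
* **Peak gain 2** at the center frequency makes a unit sinusoid produce unit
  scalogram power regardless of frequency, so equal-amplitude tones give
  equal peaks and band peak frequencies are directly comparable.
* **Cone of influence.** Samples within m/(2f) seconds of either edge are
  masked and excluded from time averages by default (configurable to
  include, since published pipelines rarely state their edge handling).
* **Fast path.** By Parseval's identity the time-averaged power equals
  (1/n²)Σ_k|X_k|²G_f(ν_k)², so per-fragment spectra are computed without
  inverse FFTs (`epoch_power_spectrum`); this equals averaging the full
  scalogram over *all* samples (COI included) and is pinned against the
  explicit route by a test.  The feature pipeline uses this path.
* **Normalization.** "Normalized power" is defined as unit trapezoidal
  integral over the analysis band, making band AUC features read as the
  fraction of in-band power; the choice is recorded in every output
  (`norm_mode`), and `none` is available.  Band AUC is a trapezoidal
  integral; band peak frequency is the in-band argmax with ties broken
  toward the lower frequency.

## Synthetic cohorts

`synthcohort` generates what the analysis assumes, not retinal biophysics:

* **Components**: band-limited Gaussian processes (white noise band-passed
  around a center frequency, rescaled to a target RMS) or pure sinusoids
  when the bandwidth is zero.  Human control defaults: 0.5 Hz (band I,
  4 μV RMS, 0.4 Hz wide), 15 Hz (band II, 3 μV, 4 Hz wide), 27 Hz (band
  III, 3 μV, 4 Hz wide) — one consistent peak inside each analysis band.
  Published signals are normalized, so absolute amplitudes are free
  parameters; these defaults put components well above the noise floor
  without being trivially separable at the single-fragment level.
* **Background**: 1/f noise (exponent 1), 1 μV RMS.
* **Disease effects**: signed per-band peak shifts plus component-amplitude
  changes.  The pooled-disease human profile shifts band III by +2 Hz and
  raises the slow component by 3 μV (= 3× noise sd); per-group profiles
  grade both effects with disease stage (overweight +0.5 Hz … diabetes
  +2 Hz).  Rodent profiles put activity at 0.4/1.4/3 Hz with the mid-low
  peak drifting down by 0.025 Hz per disease week.
* **Blink artifacts**: Poisson-placed 200 ms biphasic transients whose peak
  amplitude must exceed 100 μV whenever the rate is positive, so generated
  artifacts deterministically trip the rejection rule.
* **Metadata** are truncated normals using the published five-group means
  and dispersions (used as printed; the table footnote's s.d./s.e.m.
  ambiguity is deliberately not resolved — `dispersion_scale` exposes it),
  followed by rejection sampling until the labeling rules re-derive the
  declared group.  Truncation keeps draws inside the declared group's
  feasible region (BMI class bounds, glucose below/above the 126 mg/dl
  diabetes cut, waist above the sex-specific cut for the MetS group);
  without it, male MetS rows are nearly unsampleable because the group's
  printed waist mean (88 cm) sits below the 94 cm male criterion.  Two
  printed group means conflict with the criteria themselves (MetS glycemia
  144.8 mg/dl exceeds the diabetes cut; obesity BMI 29.93 is below 30);
  truncation resolves both in favor of the criteria.
* **Determinism**: every stream descends from one seed through
  `numpy.random.SeedSequence` spawning; identical (configuration, seed)
  reproduces byte-identical cohorts.

### What passing tests show — and what they do not

The generator reproduces the *statistical skeleton* the analysis relies on:
band-structured spectra, 1/f background, super-threshold artifacts,
criteria-consistent metadata.  It does not model electrode drift, eye
movements, cardiorespiratory contamination (beyond adding a component by
hand), device transfer functions, inter-subject spectral variability, or any
real covariance between metabolic state and retinal oscillations.  Passing
calibration/power tests therefore demonstrates that the pipeline recovers
effects it is pointed at and reports chance when there are none — it says
nothing about effect sizes in real cohorts.

## Clinical labeling

Glycemia cuts: normoglycemia < 6.1 mmol/l, diabetes ≥ 7.0 mmol/l
(126 mg/dl; conversion 18.0).  BMI: overweight 25–29.99, obesity ≥ 30.
MetS: central obesity (BMI > 30 or waist ≥ 94/80 cm male/female) plus ≥ 2
of raised TG (≥ 150 mg/dl), reduced HDL (< 40/50), raised BP (≥ 130/85),
raised fasting glucose (≥ 100 mg/dl) — the canonical IDF thresholds, all
configurable, since the study cites the IDF definition without numbers (and
lists further "raised" analytes that the four-factor rule deliberately
ignores).  Precedence: diabetes > MetS > obesity > overweight > control.
Fasting glucose 6.1–6.9 mmol/l with no other finding falls through to the
BMI rules and is tagged "intermediate".  Derived indices: BMI = weight/height²,
HOMA-I = glucose·insulin/405, atherogenic index = log₁₀(TG/HDL).

## Classification

Feature tables hold one fragment per row (795 power columns for the human
band plus band AUC/peak-frequency columns).  Classes are balanced by seeded
undersampling; the split is 80/20.  Fragment-level splitting reproduces the
published protocol but lets one subject's fragments straddle the split;
subject-level splitting is provided and recommended, and reports record the
unit used.  Forests are tuned by exhaustive grid search with stratified
5-fold cross-validation — selection by mean CV AUC (binary) or accuracy
(multiclass), ties toward the smallest ntrees, then depth, then leaf size
(none of this is stated in the source protocol; these are the package's
choices).  `RFGrid.paper()` reproduces the published 528-cell grid;
simulation studies and tests use `RFGrid.small()` because the full grid
buys nothing on synthetic cohorts of a few hundred fragments.  Evaluation:
ROC from sorted positive-class probabilities, AUC by trapezoid (identical
to the Mann–Whitney pairwise probability, which a test enforces
exhaustively), confusion matrix at the 0.5 probability threshold, and the
six scalar metrics computed from it.  The hierarchical five-class model
gates on a binary control/disease forest and sends predicted-disease rows
to a four-class forest; stage-1 control calls are final.  The longitudinal
model is a single multiclass forest over week labels.

## Explanatory statistics

* **CoV selection**: top-k variables by sd/|mean|, zero-mean variables
  excluded with a warning, ties by name.
* **PCA**: SVD of centered (by default standardized — spectral power and
  plasma analytes mix scales) complete cases; contributions are squared
  loadings normalized per component.
* **SO score**: Σⱼ PC1-loadingⱼ·xⱼ.  "Real value" is taken as the
  standardized value when the PCA was standardized (consistency over
  literalism; `so_score` also accepts raw values), making the score equal
  the PC1 score — a property a test enforces.
* **LDA**: per-group recall under resubstitution or leave-one-out; the
  three-group mode maps overweight/obesity/MetS to a single risk-factor
  class.  Near-singular covariance falls back to a shrinkage solver.
* **Welch ANOVA**: the heteroscedastic F with Satterthwaite-type df,
  implemented directly and cross-checked against an independent
  implementation; Games–Howell pairwise comparisons (pingouin) feed the
  compact-letter group annotations.

## Numerical choices and degenerate inputs

Artifact threshold comparisons are strict (a sample at exactly ±100 μV is
kept).  Constant signals cannot be normalized; zero spectra cannot be
unit-normalized; a frequency with no COI-valid samples is a hard error
naming the frequency.  Band features require the band inside the spectrum
grid.  `isolate_ops` needs fs ≥ 1 kHz; at exactly 1 kHz the 100–500 Hz band
upper edge coincides with Nyquist and the realized filter is the 100 Hz
high-pass.  Single-class test sets yield metrics where defined and an
undefined AUC.  Ratios with zero denominators come back as NaN (metrics) or
None (OP features) rather than raising mid-pipeline.

## Problem sizes used by the tests and the acceptance script

Simulation studies run at desk scale, chosen as the smallest sizes at which
the statistical checks are stable: 100 one-minute fragments per arm
(20 five-minute recordings) for the calibration/power study, 20 seeds for
the null, 6 recordings per cohort for the peak-shift recovery, 40 fragments
per group for the five-group models, 90 subjects for the three-group LDA,
and 2000 replicates for the Welch type-I calibration.

## Known limitations

The OP extractor implements extremum bookkeeping, not ISCEV waveform
modeling, and its 10–60 ms window and 5% prominence are conventions, not
fitted values.  The generator's group effects are monotone by construction,
so multiclass accuracy on synthetic cohorts is optimistic relative to any
real cohort.  EDF files can be read (via mne) but not written.  Published
headline performance numbers were computed on undeposited patient and
animal recordings and cannot be reproduced here; the package reproduces the
method, its bookkeeping identities, and its behavior under known ground
truth.
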