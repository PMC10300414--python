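# Methods

## Overview

`somnoscreen` implements a two-stage analysis of overnight sleep EEG:

1. **Sleep staging.** Six-channel EEG (F3, F4, C3, C4, O1, O2 at 200 Hz)
   is bandpass filtered to 0.5–50 Hz, cut into 30-s epochs, and each
   epoch is reduced to 48 spectral features (8 per channel). Classical
   classifiers (SVM-RBF, kNN, MLP) map epoch features to the five AASM
   stages W, N1, N2, N3, R.
2. **OSA screening.** Each subject is summarized by the mean feature
   vector over REM epochs and over pooled NREM (N1∪N2∪N3) epochs —
   96 numbers, optionally plus an SpO₂ scalar — and the same classifier
   family is trained against the OSA diagnosis. The deployed screener is
   trained on the healthy and severe groups only (the mild-to-moderate
   group has intermediate, poorly separable features) and applied to all
   comers; any non-healthy prediction is reported as "osa". The
   *integrated* screen feeds the screener with aggregates computed over
   machine-predicted, not expert, stage labels.

## Feature model

Each epoch/channel is transformed with an STFT using 1-s Hann windows at
50% overlap: a 30-s epoch yields 2·30 − 1 = 59 windows with 1-Hz
frequency bins (0…100 Hz, no zero padding); window power is the squared
magnitude of the windowed DFT. Every window's power spectrum is
normalized by its own sum over the analysis range (0.5, 50] Hz, making
all downstream features relative (amplitude-invariant) and each window a
probability vector over in-band bins.

Band membership is half-open and upper-inclusive, (low, high]; with 1-Hz
bins: low_delta (0.5, 2] → bins {1, 2}; delta (1, 4] → {2, 3, 4}; theta
(4, 8] → {5–8}; alpha (8, 12] → {9–12}; sigma (12, 15] → {13–15}; beta
(15, 30] → {16–30}. low_delta and delta deliberately overlap at 2 Hz —
they quantify slow-wave activity and the K-complex band respectively.

Per channel, eight features summarize the 59 window band fractions:
means of low_delta, theta, alpha and beta, and for delta and sigma the
**maximum** over the 59 windows (`K_comp_1`, `spindle_1`) together with
the **mean of the remaining 58** windows after removing the argmax
window (`K_comp_2`, `spindle_2`; ties broken at the lowest window
index). The max/mean-of-rest split is an event detector: a single
0.5–1.5 s K-complex or sleep spindle dominates one window and lifts the
maximum well above the background mean. All features lie in [0, 1] and
`K_comp_1 ≥ K_comp_2`, `spindle_1 ≥ spindle_2` by construction.

Degenerate inputs: a window with zero in-band power gets all-zero
relative values and is flagged; an entirely zero epoch is an error
(relative PSD undefined).

## Classifiers

All models share one fitting policy: per-feature z-scoring with
statistics learned on the training data only (the scaler travels inside
the fitted pipeline), followed by an exhaustive grid search over fixed
candidate lists with stratified 3-fold inner cross-validation on the
training set, selecting by mean accuracy and breaking ties in favour of
the first-listed candidate:

- **SVM** (RBF kernel): C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1,
  1, 10} — 20 candidates.
- **kNN**: n_neighbors ∈ {1, 3, …, 19} × weights {uniform, distance} ×
  metric {euclidean, manhattan} — 40 candidates.
- **MLP** (Adam, ReLU, ≤200 iterations): hidden layouts {16, 32, 64} for
  one layer plus all 3×3 two-layer combinations — 12 candidates.

A single integer seed controls fold shuffling and MLP initialization;
fixed seed ⇒ identical selected hyperparameters and predictions. No
class rebalancing is applied: models train on the natural stage
distribution.

## Evaluation harness

The reference protocol is stratified 5-fold cross-validation repeated 10
times on freshly shuffled data — 50 held-out accuracies per model, plus
per-stage one-vs-rest f1 and a summed 5×5 confusion matrix. Folds can be
cut at the epoch level (stratified by stage) or at the subject level
(all of a subject's epochs stay on one side of every fold; subject folds
stratified by age group × OSA class when available). Both protocols are
first-class and recorded in the result's config. A stage absent from
both the reference and the prediction has *undefined* (NaN) f1, excluded
from aggregates rather than zero-filled.

Model variants are compared with classical one-way fixed-effects ANOVA
computed from sums of squares, df = (groups − 1, N − groups), at
significance level 0.01; significant omnibus tests are followed by
Bonferroni-corrected pairwise pooled-variance t-tests. When every
observation equals the grand mean, F is defined as 0. Cross-age
validation trains subject-level k-fold models within one age group and
scores them both on their own held-out folds and on the entire other
group (Y-Y, Y-O, O-O, O-Y). Inter-subject homogeneity is measured as
pairwise Pearson correlation between subjects' stage-mean feature
vectors, summarized as the mean off-diagonal correlation per group.

## Synthetic cohort generator

Clinical polysomnography cannot be redistributed, so the package ships a
seeded generator that emulates the statistical structure the pipeline
relies on — not physiologically realistic EEG.

- **Hypnograms** are first-order Markov chains over the five stages with
  a default transition matrix giving realistic dwell times and all five
  stages within a simulated night.
- **Backgrounds** are Gaussian noise with stage-specific relative band
  powers (alpha-dominant wake; theta-heavy N1; mixed N2; low-frequency-
  dominated N3; mixed REM with elevated beta), built by shaping a white
  complex-Gaussian spectrum per band and inverting — this gives direct,
  exact control of the relative PSD, which is the feature space.
- **Events** occur in N2 at 0.5/epoch each (one per two epochs),
  durations uniform in 0.5–1.5 s: K-complexes are Hann-windowed biphasic
  wavelets centered at 2.5 Hz with amplitude 5× the background SD (the
  center frequency sits inside the 1–4 Hz detection band; at 1-Hz bin
  resolution a slower ~1 Hz wave would leave most of its energy below
  the band and be invisible to the detector); spindles are
  Hann-enveloped 13.5 Hz bursts at 3× background SD.
- **Channels** share a common stage component plus 20% independent
  per-channel noise, so the six channels are correlated but not
  redundant. Per-subject lognormal jitter (σ = 0.08) on band powers and
  a lognormal overall gain create between-subject variability.
- **OSA severity** acts multiplicatively: K-complex amplitude and rate
  fall (×0.80/0.80 mild-to-moderate, ×0.55/0.60 severe), background beta
  rises (×1.18, ×1.40), REM sigma rises (×1.10, ×1.25), and background
  low-frequency power falls (×0.93, ×0.85). The low-frequency decline is
  what lets the *background* delta features (K_comp_2) fall with
  severity, as single transients only move the max feature; the default
  magnitudes are calibrated so that the group-mean NREM K-complex
  decrease and beta increase are ANOVA-significant (p < 0.01) at
  25 subjects per class, the generator's stated fidelity property.
- **SpO₂** is drawn per subject from its age × severity cell's normal
  distribution (means 73–89%, SDs 4–11% across cells), truncated to
  (0, 100].

Everything is reproducible from one master seed; per-subject seeds
derive from it, so any subject can be regenerated independently
(`cohort_plan` / `regenerate_subject`), which also lets large cohorts be
featurized subject-by-subject without holding raw signals in memory.

What passing tests on this generator do **not** show: robustness to real
EEG artifacts, 1/f background structure, stage-transition context
effects (the reason real N1 accuracy is low), electrode montage or
referencing effects, or real OSA physiology beyond the modeled
band-power directions.

## Problem sizes used in the shipped experiments

Chosen as the package's default experiment scale:

- Stage-classification recovery: 30 subjects × 200 epochs, ~20% of
  subjects held out (subject-level split, never epoch-level).
- Screening recovery: 60 healthy + 60 severe subjects × 100 epochs
  (100 epochs keeps both REM and NREM present for essentially every
  subject), 10 + 10 held out; the stage classifier inside the integrated
  screen trains on a 25-epoch-per-subject subsample of the training
  split.
- Effect-direction fidelity: 25 subjects per severity class × 60 epochs.

## Numerical and policy choices

- Bandpass: 4th-order Butterworth applied forward-backward
  (zero-phase), so transients are not phase-distorted; recordings at
  other sampling rates are rejected by default (the window arithmetic
  assumes 200 Hz) with optional polyphase resampling.
- Epoch-count/hypnogram-length mismatches truncate to the shorter side
  with a warning (clinical exports commonly differ by a trailing epoch).
- STFT taper: periodic Hann; the test oracle computes the DFT from its
  definition with the identical taper.
- NREM aggregation pools epochs (not per-stage means), so stages
  contribute in proportion to their prevalence.
- A subject missing the REM (or NREM) aggregate at screening time is
  imputed with training-population means and flagged; missing both is
  reported "unscreenable", never silently guessed.
- EDF files are written by a minimal built-in 16-bit writer (physical
  dimension µV, 1-s records, per-channel symmetric ranges; quantization
  error ≤ range/65535) and read through `mne`.

## Known limitations

- Epoch-independent classification ignores stage-sequence context;
  real-world N1 performance is known to suffer from exactly this.
- The generator's class separations are larger than clinical reality;
  synthetic recovery accuracies (≈0.95+) say the pipeline is correct,
  not that clinical accuracy would be comparable.
- SpO₂ is a single scalar of unspecified statistic (mean vs minimum
  saturation); the interface accepts whatever the metadata provides.
- No artifact rejection by default, by design: artifacts carry
  stage-discriminative information in this feature set.
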