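# somnoscreen

Automatic sleep-stage classification and obstructive sleep apnea (OSA)
screening from spectral features of sleep EEG.

Scoring a night of polysomnography by hand takes an expert through
~1,000 thirty-second epochs, and diagnosing OSA on top of that requires
respiration channels that home or wearable setups rarely have.
`somnoscreen` is a toolkit for the EEG-only alternative: it classifies
the five AASM sleep stages (W, N1, N2, N3, R) from six EEG channels
(F3, F4, C3, C4, O1, O2 at 200 Hz) and then screens for OSA using only
the stage-conditioned EEG feature profile — no airflow or oximetry
required (SpO₂ can be added as an optional covariate). It is aimed at
sleep researchers and methods developers who need a transparent,
classical (non-deep-learning) baseline pipeline plus the evaluation
machinery to study it.

## Method

Each 30-s epoch x(t) of each channel is reduced to eight relative
band-power features. An STFT with 1-s Hann windows at 50% overlap gives
59 windows per epoch with 1-Hz bins; each window's PSD is normalized by
its sum over (0.5, 50] Hz, so features are amplitude-invariant. With
P_w(b) the relative power of window w in band b:

- `low_delta`, `theta`, `alpha`, `beta` — mean of P_w(b) over the 59
  windows for b = (0.5, 2], (4, 8], (8, 12], (15, 30] Hz;
- `K_comp_1` = max_w P_w(delta), delta = (1, 4] Hz, and
  `K_comp_2` = mean of the remaining 58 windows — a K-complex detector:
  one 0.5–1.5 s high-amplitude delta transient dominates a single
  window;
- `spindle_1` = max_w P_w(sigma), sigma = (12, 15] Hz, and
  `spindle_2` = mean of the remaining 58 — the sleep-spindle analogue.

Six channels × 8 features give a 48-vector per epoch. Stage classifiers
(SVM-RBF, kNN, MLP) are grid-searched over fixed hyperparameter lists
with inner stratified 3-fold selection and z-scored features. For OSA
screening a subject is summarized by the mean 48-vector over REM epochs
and over pooled NREM epochs (96 features, + SpO₂ optionally); the
deployed screener is trained healthy-vs-severe and applied to everyone,
with any non-healthy call reported as "osa". The *integrated* screen
chains both models on a raw recording: bandpass → epochs → features →
predicted stages → stage-conditioned profile → screening call.

Validation follows repeated stratified cross-validation (10 × 5-fold =
50 accuracies per model) with one-way ANOVA (α = 0.01) and Bonferroni
post-hoc t-tests for model comparison; epoch- and subject-level splits
are both supported. A seeded synthetic polysomnography generator
(stage-dependent spectra, K-complex/spindle transients, severity
effects, SpO₂ distributions) makes the whole pipeline testable without
clinical data. See `docs/methods.md` for the full model description.

## Worked example

Simulate a small cohort, featurize it, train an SVM stager and score
held-out subjects:

```python
from somnoscreen.synthetic import CohortSpec
from somnoscreen.pipeline import simulate_and_featurize, _split_subjects
from somnoscreen import staging, evaluate as ev

spec = CohortSpec(subjects_per_cell=2, epochs_per_subject=60, seed=0)
feats, metadata, _ = simulate_and_featurize(spec)
print(f"featurized {len(feats)} epochs from {len(metadata)} subjects")

train_ids, test_ids = _split_subjects(metadata, 0.25, 0)
train = feats[feats.subject_id.isin(train_ids)]
test = feats[feats.subject_id.isin(test_ids)]
model = staging.fit_staging_model(train, "svm", seed=0)
print("selected hyperparameters:", model.hyperparams)
m = ev.stage_metrics(test["stage"], model.predict(test))
print(f"held-out accuracy: {m.accuracy:.3f}")
```

prints

```
featurized 720 epochs from 12 subjects
selected hyperparameters: {'C': 10.0, 'gamma': 0.01}
held-out accuracy: 1.000
```

720 epochs is 12 subjects × 60 epochs; the grid search picked C = 10,
γ = 0.01 from the 20-candidate SVM grid; accuracy 1.000 means every
held-out epoch was assigned its true stage — the default synthetic
stages are far more separable than clinical EEG, so this certifies the
pipeline, not clinical performance.

The same flow is available from the shell:

```sh
somnoscreen simulate --subjects-per-cell 2 --epochs 60 --seed 0 --out data/
somnoscreen extract-features --edf data/y_healthy_000.edf \
    --hypnogram data/y_healthy_000_hypnogram.csv --out feats.csv
somnoscreen train-staging --features feats.csv --algorithm svm --out stager.model
somnoscreen run-all --seed 0 --out run/    # full pipeline in one step
```

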