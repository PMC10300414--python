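"""End-to-end orchestration: simulate → featurize → train → evaluate → screen.

A single :class:`PipelineConfig` pins down every knob of the pipeline
(preprocessing band, feature scheme, grids seed, evaluation protocol,
screening task).  ``run_pipeline`` executes the whole flow and writes a
self-contained run directory: the fully resolved configuration, feature
CSVs, staging and screening models, evaluation JSON and screening JSON,
plus a JSON-lines log with per-stage counts.  A completed run can be
re-executed from its saved config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import features as feat
from . import osa as osa_mod
from . import staging
from .io import Hypnogram, bandpass, segment_epochs, write_hypnogram
from .synthetic import (Cohort, CohortSpec, cohort_plan, simulate_cohort,
                        simulate_subject)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline",
           "featurize_cohort", "simulate_and_featurize"]

logger = logging.getLogger("somnoscreen")


class ConfigError(ValueError):
    """The pipeline configuration failed schema validation."""


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (YAML-serializable).

    Defaults describe a small smoke-scale synthetic run; the evaluation
    experiments in ``scripts/`` override cohort sizes explicitly.
    """

    # preprocessing
    band_low: float = 0.5
    band_high: float = 50.0
    filter_order: int = 4
    # synthetic cohort
    subjects_per_cell: int = 2
    epochs_per_subject: int = 60
    # models
    algorithms: tuple[str, ...] = ("svm", "knn", "mlp")
    screening_algorithm: str = "mlp"
    seed: int = 0
    # evaluation
    cv_folds: int = 5
    cv_reps: int = 2
    split_unit: str = "subject"
    eval_algorithm: str = "knn"
    # screening
    screening_use_spo2: bool = False
    test_fraction: float = 0.25
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        problems = []
        if not 0 < self.band_low < self.band_high:
            problems.append(
                f"band edges must satisfy 0 < low < high, got "
                f"({self.band_low}, {self.band_high})")
        if self.filter_order < 1:
            problems.append("filter_order must be >= 1")
        if self.subjects_per_cell < 1 or self.epochs_per_subject < 1:
            problems.append("cohort sizes must be >= 1")
        bad = [a for a in (*self.algorithms, self.screening_algorithm,
                           self.eval_algorithm) if a not in staging.ALGORITHMS]
        if bad:
            problems.append(f"unknown algorithms {sorted(set(bad))}")
        if self.split_unit not in ("subject", "epoch"):
            problems.append("split_unit must be 'subject' or 'epoch'")
        if self.cv_folds < 2 or self.cv_reps < 1:
            problems.append("cv_folds must be >= 2 and cv_reps >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            problems.append("test_fraction must be in (0, 1)")
        if problems:
            raise ConfigError("; ".join(problems))
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "algorithms" in d:
            d = {**d, "algorithms": tuple(d["algorithms"])}
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path


def featurize_cohort(
    cohort: Cohort, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Bandpass, epoch and featurize every recording of a cohort."""
    config = config or PipelineConfig()
    frames = []
    for sid, rec in cohort.recordings.items():
        filtered = bandpass(rec, config.band_low, config.band_high,
                            config.filter_order)
        epochs = segment_epochs(filtered, cohort.hypnograms[sid])
        frames.append(feat.featurize_epochs(epochs, filtered.fs,
                                            subject_id=sid))
    return pd.concat(frames, ignore_index=True)


def simulate_and_featurize(
    spec: CohortSpec, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a cohort subject-by-subject and keep only features.

    Raw signals are discarded as soon as each subject is featurized, so
    memory stays flat regardless of cohort size.  Returns the feature
    matrix, the metadata table and the (small) expert hypnograms.
    """
    config = config or PipelineConfig()
    frames, rows, hypnograms = [], [], {}
    for meta, seed in cohort_plan(spec):
        rec, hyp, spo2 = simulate_subject(meta, spec, seed)
        filtered = bandpass(rec, config.band_low, config.band_high,
                            config.filter_order)
        epochs = segment_epochs(filtered, hyp)
        frames.append(feat.featurize_epochs(epochs, filtered.fs,
                                            subject_id=meta.subject_id))
        rows.append({"subject_id": meta.subject_id,
                     "age_group": meta.age_group,
                     "osa_class": meta.osa_class, "spo2": spo2})
        hypnograms[meta.subject_id] = hyp
    return pd.concat(frames, ignore_index=True), pd.DataFrame(rows), hypnograms


def _split_subjects(meta: pd.DataFrame, test_fraction: float, seed: int):
    """Stratified (age_group × osa_class) train/test subject split."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, cell in meta.groupby(["age_group", "osa_class"], sort=True):
        ids = list(cell["subject_id"])
        order = rng.permutation(len(ids))
        n_test = max(1, int(round(test_fraction * len(ids))))
        for i, j in enumerate(order):
            (test if i < n_test else train).append(ids[j])
    return sorted(train), sorted(test)


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.t0 = time.time()

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "elapsed_s": round(time.time() - self.t0, 2),
               **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        logger.info("%s: %s", stage, fields)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full synthetic pipeline and write the artifact tree."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log = _JsonlLog(out / "run_log.jsonl")
    config.to_yaml(out / "config_resolved.yaml")

    spec = CohortSpec(subjects_per_cell=config.subjects_per_cell,
                      epochs_per_subject=config.epochs_per_subject,
                      seed=config.seed)
    cohort = simulate_cohort(spec)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    log.event("simulate", subjects=len(cohort.recordings),
              epochs_per_subject=config.epochs_per_subject)

    features = featurize_cohort(cohort, config)
    features.to_csv(out / "features.csv", index=False)
    log.event("features", rows=len(features),
              columns=len(feat.feature_columns(features)))

    train_ids, test_ids = _split_subjects(
        cohort.metadata, config.test_fraction, config.seed)
    train_df = features[features["subject_id"].isin(train_ids)]
    test_df = features[features["subject_id"].isin(test_ids)]

    staging_models = {}
    staging_report = {}
    for alg in config.algorithms:
        model = staging.fit_staging_model(train_df, alg, config.seed)
        staging.save_model(model, out / f"staging_{alg}.model")
        staging_models[alg] = model
        pred = model.predict(test_df)
        m = ev.stage_metrics(test_df["stage"], pred)
        staging_report[alg] = {
            "test_accuracy": m.accuracy,
            "per_stage_f1": {k: None if np.isnan(v) else v
                             for k, v in m.f1.items()},
            "hyperparams": model.hyperparams,
        }
        log.event("train_staging", algorithm=alg, accuracy=m.accuracy)

    strata = {r.subject_id: (r.age_group, r.osa_class)
              for r in cohort.metadata.itertuples()}
    cv = ev.repeated_cv(train_df, config.eval_algorithm, k=config.cv_folds,
                        reps=config.cv_reps, split_unit=config.split_unit,
                        seed=config.seed, strata=strata)
    evaluation = {
        "staging_test": staging_report,
        "repeated_cv": {
            "algorithm": config.eval_algorithm,
            "accuracies": cv.accuracies.tolist(),
            "mean_accuracy": float(cv.accuracies.mean()),
            "confusion": cv.confusion.tolist(),
            "config": cv.config,
        },
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    log.event("evaluate", n_scores=len(cv.accuracies),
              mean_accuracy=float(cv.accuracies.mean()))

    metas = cohort.metas
    profiles = osa_mod.profiles_from_features(features, metas)
    train_profiles = [p for p in profiles if p.subject_id in train_ids]
    task = osa_mod.ScreeningTask(("healthy", "severe"),
                                 use_spo2=config.screening_use_spo2)
    table = osa_mod.build_profile_table(train_profiles, task)
    table.to_csv(out / "profiles.csv", index=False)
    osa_model = osa_mod.fit_osa_model(table, config.screening_algorithm,
                                      config.seed)
    staging.save_model(osa_model, out / "osa.model")
    log.event("train_osa", subjects=len(table),
              algorithm=config.screening_algorithm)

    screening = {}
    stager = staging_models[config.screening_algorithm]
    for sid in test_ids:
        res = osa_mod.integrated_screen(stager, osa_model,
                                        cohort.recordings[sid])
        truth = cohort.metadata.set_index("subject_id").loc[sid, "osa_class"]
        screening[sid] = {
            "label": res.label, "osa_class": res.osa_class,
            "true_class": str(truth), "n_epochs": res.n_epochs,
        }
        if res.predicted_hypnogram is not None:
            write_hypnogram(res.predicted_hypnogram,
                            out / f"predicted_{sid}.csv")
    screenable = {k: v for k, v in screening.items()
                  if v["label"] != "unscreenable"}
    correct = sum(
        (v["label"] == "healthy") == (v["true_class"] == "healthy")
        for v in screenable.values()
    )
    summary = {
        "subjects": screening,
        "accuracy": correct / len(screenable) if screenable else None,
        "n_screened": len(screenable),
    }
    (out / "screening.json").write_text(json.dumps(summary, indent=2))
    log.event("screen", n_screened=len(screenable),
              accuracy=summary["accuracy"])
    return out
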