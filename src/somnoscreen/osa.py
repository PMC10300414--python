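"""Obstructive sleep apnea screening from stage-conditioned EEG features.

A subject is summarized by the unweighted mean of the 48 epoch features
over REM epochs and over pooled NREM (N1∪N2∪N3) epochs — 96 numbers, plus
an optional SpO₂ scalar — and a classifier (same algorithms and grids as
sleep staging) is trained on these profiles against the OSA diagnosis.
Two task variants exist: three-class (healthy / mild-to-moderate /
severe) and the healthy-vs-severe screener, which is trained without the
intermediate mild-to-moderate group and then deployed on all comers.

The integrated screen composes the full pipeline on a raw recording:
bandpass → epochs → features → predicted stages → profile aggregated over
the *predicted* labels → screening prediction, with any OSA class other
than healthy reported as "osa".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .io import Recording, SubjectMeta, bandpass, segment_unlabeled
from .staging import TrainedModel, _fit_classifier, predict_stages

__all__ = [
    "NREM_STAGES",
    "SubjectProfile",
    "ScreeningTask",
    "THREE_CLASS",
    "HEALTHY_SEVERE",
    "ScreenResult",
    "aggregate_profile",
    "profiles_from_features",
    "build_profile_table",
    "fit_osa_model",
    "screen_profile",
    "integrated_screen",
]

NREM_STAGES: tuple[str, ...] = ("N1", "N2", "N3")


@dataclass
class SubjectProfile:
    """Per-subject aggregate of epoch features by REM/NREM stage class.

    ``rem`` / ``nrem`` are 48-vectors (means over the respective epochs)
    or ``None`` when the subject has no epoch of that kind.  Wake epochs
    never contribute.
    """

    subject_id: str
    rem: np.ndarray | None
    nrem: np.ndarray | None
    feature_names: tuple[str, ...]
    spo2: float | None = None
    osa_class: str | None = None
    age_group: str | None = None

    @property
    def missing(self) -> list[str]:
        return [k for k, v in (("rem", self.rem), ("nrem", self.nrem)) if v is None]


@dataclass(frozen=True)
class ScreeningTask:
    """Which diagnosis classes to train on and whether SpO₂ is a feature."""

    class_set: tuple[str, ...]
    use_spo2: bool = False

    def __post_init__(self) -> None:
        if tuple(self.class_set) not in (
            ("healthy", "mtom", "severe"),
            ("healthy", "severe"),
        ):
            raise ValueError(
                "class_set must be (healthy, mtom, severe) or (healthy, severe), "
                f"got {self.class_set}"
            )


THREE_CLASS = ScreeningTask(("healthy", "mtom", "severe"))
HEALTHY_SEVERE = ScreeningTask(("healthy", "severe"))


def aggregate_profile(
    feats_df: pd.DataFrame, meta: SubjectMeta | None = None
) -> SubjectProfile:
    """Aggregate one subject's epoch features into REM/NREM means.

    NREM pools N1, N2 and N3 epochs at the epoch level (each epoch counts
    once regardless of its stage); wake epochs are excluded entirely.
    Raises if the subject has neither REM nor NREM epochs.
    """
    if meta is None:
        sid = str(feats_df["subject_id"].iloc[0]) if "subject_id" in feats_df else ""
        spo2 = osa_class = age_group = None
    else:
        sid, spo2 = meta.subject_id, meta.spo2
        osa_class, age_group = meta.osa_class, meta.age_group
    cols = feat.feature_columns(feats_df)
    stages = feats_df["stage"].to_numpy()

    def stage_mean(mask: np.ndarray) -> np.ndarray | None:
        if not mask.any():
            return None
        return feats_df.loc[mask, cols].to_numpy(dtype=float).mean(axis=0)

    rem = stage_mean(stages == "R")
    nrem = stage_mean(np.isin(stages, NREM_STAGES))
    if rem is None and nrem is None:
        raise ValueError(
            f"subject {sid!r} has neither REM nor NREM epochs; cannot aggregate"
        )
    return SubjectProfile(
        subject_id=sid, rem=rem, nrem=nrem, feature_names=tuple(cols),
        spo2=spo2, osa_class=osa_class, age_group=age_group,
    )


def profiles_from_features(
    feats_df: pd.DataFrame, metas: Sequence[SubjectMeta]
) -> list[SubjectProfile]:
    """Aggregate a multi-subject feature matrix, one profile per subject."""
    by_id = {m.subject_id: m for m in metas}
    profiles = []
    for sid, group in feats_df.groupby("subject_id", sort=False):
        profiles.append(aggregate_profile(group, by_id.get(str(sid))))
    return profiles


def _profile_row(profile: SubjectProfile, use_spo2: bool,
                 impute: dict[str, float] | None = None) -> dict[str, float]:
    row: dict[str, float] = {}
    for prefix, vec in (("rem", profile.rem), ("nrem", profile.nrem)):
        for j, name in enumerate(profile.feature_names):
            col = f"{prefix}.{name}"
            if vec is not None:
                row[col] = float(vec[j])
            elif impute is not None and col in impute:
                row[col] = impute[col]
            else:
                row[col] = np.nan
    if use_spo2:
        if profile.spo2 is not None:
            row["spo2"] = float(profile.spo2)
        elif impute is not None and "spo2" in impute:
            row["spo2"] = impute["spo2"]
        else:
            row["spo2"] = np.nan
    return row


def build_profile_table(
    profiles: Sequence[SubjectProfile], task: ScreeningTask
) -> pd.DataFrame:
    """Design table for screening-model training.

    One row per subject in the task's class set, columns
    ``subject_id, osa_class, age_group`` + 48 ``rem.*`` + 48 ``nrem.*``
    features (+ ``spo2`` when the task uses it).  Subjects outside the
    class set, or with a missing REM or NREM aggregate, are dropped (the
    latter with a warning).
    """
    rows = []
    for p in profiles:
        if p.osa_class not in task.class_set:
            continue
        if p.missing:
            warnings.warn(
                f"subject {p.subject_id!r} dropped from the training table: "
                f"missing {p.missing} aggregate"
            )
            continue
        if task.use_spo2 and p.spo2 is None:
            warnings.warn(
                f"subject {p.subject_id!r} dropped: task uses SpO2 but none recorded"
            )
            continue
        row = {"subject_id": p.subject_id, "osa_class": p.osa_class,
               "age_group": p.age_group}
        row.update(_profile_row(p, task.use_spo2))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty or table["osa_class"].nunique() < 2:
        raise ValueError(
            "fewer than 2 diagnosis classes remain after filtering; "
            "cannot train a screener"
        )
    return table


def fit_osa_model(
    table: pd.DataFrame, algorithm: str, seed: int
) -> TrainedModel:
    """Fit an OSA screening classifier on a profile table.

    Same grids, inner selection and scaling policy as the staging models.
    Column means of the training table are stored in the model's extras
    for imputing missing aggregates at screening time.
    """
    cols = [c for c in table.columns
            if c.startswith(("rem.", "nrem.")) or c == "spo2"]
    X = table.loc[:, cols].to_numpy(dtype=float)
    y = table["osa_class"].to_numpy()
    means = {c: float(m) for c, m in zip(cols, X.mean(axis=0))}
    return _fit_classifier(X, y, cols, algorithm, seed,
                           extras={"training_means": means})


@dataclass
class ScreenResult:
    """Outcome of screening one recording."""

    label: str                       # "healthy", "osa" or "unscreenable"
    osa_class: str | None            # raw class predicted by the screener
    predicted_hypnogram: object | None
    n_epochs: int
    imputed: list[str] = field(default_factory=list)


def screen_profile(
    osa_model: TrainedModel, profile: SubjectProfile
) -> ScreenResult:
    """Apply a trained screener to one subject profile.

    A subject missing both aggregates is unscreenable; a single missing
    aggregate (or missing SpO₂ for a SpO₂ model) is imputed with the
    training-population mean, with a warning.
    """
    if profile.rem is None and profile.nrem is None:
        return ScreenResult("unscreenable", None, None, 0)
    use_spo2 = "spo2" in osa_model.feature_names
    impute = osa_model.extras.get("training_means", {})
    row = _profile_row(profile, use_spo2, impute=impute)
    imputed = [c for c in row
               if np.isnan(row[c]) or (
                   (profile.rem is None and c.startswith("rem."))
                   or (profile.nrem is None and c.startswith("nrem."))
                   or (use_spo2 and c == "spo2" and profile.spo2 is None))]
    if any(np.isnan(v) for v in row.values()):
        return ScreenResult("unscreenable", None, None, 0, imputed)
    if imputed:
        warnings.warn(
            f"subject {profile.subject_id!r}: imputed {len(imputed)} missing "
            "profile values with training-population means"
        )
    x = pd.DataFrame([row])
    pred = str(osa_model.predict(x)[0])
    label = "healthy" if pred == "healthy" else "osa"
    return ScreenResult(label, pred, None, 0, imputed)


def integrated_screen(
    staging_model,
    osa_model: TrainedModel,
    rec: Recording,
    scheme: feat.BandScheme = feat.DEFAULT_SCHEME,
    band: tuple[float, float] = (0.5, 50.0),
    filter_order: int = 4,
) -> ScreenResult:
    """Screen a raw recording using machine-predicted sleep stages.

    ``staging_model`` may be any object exposing ``predict(features_df)``
    (duck-typed so a perfect staging oracle can be substituted in tests).
    """
    filtered = bandpass(rec, *band, order=filter_order)
    blocks = segment_unlabeled(filtered)
    df = feat.featurize_epochs(
        [(b, "W") for b in blocks], filtered.fs, scheme,
        subject_id=rec.subject_id, channels=filtered.channel_names,
    )
    hyp = predict_stages(staging_model, df, subject_id=rec.subject_id)
    df["stage"] = list(hyp.stages)
    try:
        profile = aggregate_profile(df)
    except ValueError:
        # e.g. an all-wake predicted hypnogram: explicitly unscreenable
        return ScreenResult("unscreenable", None, hyp, len(blocks))
    result = screen_profile(osa_model, profile)
    result.predicted_hypnogram = hyp
    result.n_epochs = len(blocks)
    return result
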