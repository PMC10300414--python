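"""Five-class sleep-stage classifiers: SVM-RBF, kNN and MLP.

Hyperparameters are selected by grid search over fixed candidate lists
(20 SVM, 40 kNN, 12 MLP combinations) with stratified 3-fold inner
cross-validation on the training data, selecting by mean accuracy with
ties broken in favour of the first-listed candidate.  Features are
z-scored with statistics learned on the training folds only; the scaler
travels inside the fitted pipeline.  All randomness (fold shuffling, MLP
weight initialization) is controlled by a single integer seed.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns
from .io import Hypnogram

__all__ = [
    "ALGORITHMS",
    "TrainedModel",
    "SerializationError",
    "build_grid",
    "grid_size",
    "fit_staging_model",
    "predict_stages",
    "save_model",
    "load_model",
    "read_model_metadata",
]

ALGORITHMS: tuple[str, ...] = ("svm", "knn", "mlp")

SVM_C = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA = (0.001, 0.01, 0.1, 1.0, 10.0)
KNN_NEIGHBORS = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)
KNN_WEIGHTS = ("uniform", "distance")
KNN_P = (2, 1)  # euclidean, manhattan (Minkowski exponent)
#: 3 one-hidden-layer layouts plus 3x3 two-layer layouts = 12 candidates.
MLP_LAYOUTS = tuple(
    [(n,) for n in (16, 32, 64)]
    + [(a, b) for a in (16, 32, 64) for b in (16, 32, 64)]
)
MLP_MAX_ITER = 200

_MAGIC = b"SOMNOMDL"
_FORMAT_VERSION = 1


class SerializationError(ValueError):
    """A model file is corrupted or from an incompatible format version."""


def build_grid(algorithm: str) -> dict[str, list]:
    """Hyperparameter grid for one algorithm, keyed for the fit pipeline."""
    if algorithm == "svm":
        return {"clf__C": list(SVM_C), "clf__gamma": list(SVM_GAMMA)}
    if algorithm == "knn":
        return {
            "clf__n_neighbors": list(KNN_NEIGHBORS),
            "clf__weights": list(KNN_WEIGHTS),
            "clf__p": list(KNN_P),
        }
    if algorithm == "mlp":
        return {"clf__hidden_layer_sizes": list(MLP_LAYOUTS)}
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def grid_size(algorithm: str) -> int:
    """Number of candidate hyperparameter combinations."""
    grid = build_grid(algorithm)
    n = 1
    for values in grid.values():
        n *= len(values)
    return n


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "svm":
        return SVC(kernel="rbf")
    if algorithm == "knn":
        return KNeighborsClassifier()
    if algorithm == "mlp":
        return MLPClassifier(
            solver="adam",
            activation="relu",
            max_iter=MLP_MAX_ITER,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply and audit it."""

    algorithm: str
    hyperparams: dict
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    pipeline: Pipeline
    extras: dict = field(default_factory=dict)

    @property
    def scaler_center(self) -> np.ndarray:
        """Per-feature centers of the training-data z-score scaler."""
        return self.pipeline.named_steps["scaler"].mean_

    @property
    def scaler_scale(self) -> np.ndarray:
        return self.pipeline.named_steps["scaler"].scale_

    def _matrix(self, feats: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(feats, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in feats.columns]
            if missing:
                raise ValueError(
                    f"feature matrix is missing training columns {missing}"
                )
            return feats.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(feats, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {X.shape[1]}"
            )
        return X

    def predict(self, feats: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted class labels, applying the stored scaler first."""
        return self.pipeline.predict(self._matrix(feats))

    def save(self, path: str | Path) -> Path:
        return save_model(self, path)


def _fit_classifier(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    algorithm: str,
    seed: int,
    inner_folds: int = 3,
    extras: dict | None = None,
) -> TrainedModel:
    """Grid-searched fit shared by the staging and OSA trainers."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training set contains a single class {classes.tolist()}; "
            "need at least 2"
        )
    grid = build_grid(algorithm)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    min_count = int(np.bincount(pd.factorize(y)[0]).min())
    if min_count >= 2:
        folds = max(2, min(inner_folds, min_count))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        # a class with a single member cannot be stratified
        from sklearn.model_selection import KFold

        cv = KFold(n_splits=2, shuffle=True, random_state=seed)
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("clf", _base_estimator(algorithm, seed)),
    ])
    search = GridSearchCV(
        pipe,
        grid,
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(X, y)
    best = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    if algorithm == "mlp":
        # lists, not tuples, so the value survives the JSON metadata header
        best["hidden_layer_sizes"] = list(best["hidden_layer_sizes"])
        best.update(optimizer="adam", activation="relu", max_iter=MLP_MAX_ITER)
    if algorithm == "knn":
        best["metric"] = {1: "manhattan", 2: "euclidean"}[best.pop("p")]
    return TrainedModel(
        algorithm=algorithm,
        hyperparams=best,
        feature_names=tuple(feature_names),
        classes=tuple(str(c) for c in classes),
        pipeline=search.best_estimator_,
        extras=extras or {},
    )


def fit_staging_model(
    train: pd.DataFrame,
    algorithm: str,
    seed: int,
    label_col: str = "stage",
) -> TrainedModel:
    """Fit a sleep-stage classifier on a feature matrix with stage labels.

    ``train`` is a feature matrix as produced by
    :func:`somnoscreen.features.featurize_epochs`: metadata columns plus
    48 named feature columns and a ``stage`` column.
    """
    cols = feature_columns(train)
    X = train.loc[:, cols].to_numpy(dtype=float)
    y = train[label_col].to_numpy()
    return _fit_classifier(X, y, cols, algorithm, seed)


def predict_stages(
    model: TrainedModel, feats: pd.DataFrame, subject_id: str = ""
) -> Hypnogram:
    """Predict one stage label per feature-matrix row."""
    labels = model.predict(feats)
    return Hypnogram(tuple(str(s) for s in labels), subject_id=subject_id)


# ---------------------------------------------------------------------------
# Serialization: JSON metadata header + joblib payload in one container
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Write a model container: magic, JSON metadata header, joblib payload.

    The header (algorithm, winning hyperparameters, feature names, class
    order) is readable with :func:`read_model_metadata` without unpickling
    the fitted estimator.
    """
    path = Path(path)
    header = json.dumps({
        "format_version": _FORMAT_VERSION,
        "algorithm": model.algorithm,
        "hyperparams": model.hyperparams,
        "feature_names": list(model.feature_names),
        "classes": list(model.classes),
        "extras": model.extras,
    }).encode()
    buf = _io.BytesIO()
    joblib.dump(model.pipeline, buf)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(buf.getvalue())
    return path


def _read_header(fh) -> dict:
    magic = fh.read(len(_MAGIC))
    if magic != _MAGIC:
        raise SerializationError("not a somnoscreen model file (bad magic)")
    try:
        hlen = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(hlen).decode())
    except (ValueError, UnicodeDecodeError) as exc:
        raise SerializationError(f"corrupted model header: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise SerializationError(
            f"unsupported model format version {meta.get('format_version')}"
        )
    return meta


def read_model_metadata(path: str | Path) -> dict:
    """Read only the JSON header of a saved model."""
    with open(path, "rb") as fh:
        return _read_header(fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        meta = _read_header(fh)
        try:
            pipeline = joblib.load(_io.BytesIO(fh.read()))
        except Exception as exc:
            raise SerializationError(f"corrupted model payload: {exc}") from exc
    return TrainedModel(
        algorithm=meta["algorithm"],
        hyperparams=meta["hyperparams"],
        feature_names=tuple(meta["feature_names"]),
        classes=tuple(meta["classes"]),
        pipeline=pipeline,
        extras=meta.get("extras", {}),
    )
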