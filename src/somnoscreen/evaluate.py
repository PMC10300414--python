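"""Model validation: repeated k-fold CV, per-stage metrics, ANOVA.

The reference protocol is stratified 5-fold cross-validation repeated 10
times (each repetition on a freshly shuffled dataset), giving 50 held-out
accuracy values per model.  Model variants are compared by one-way ANOVA
on those 50-value samples at significance level 0.01, with Bonferroni-
corrected pairwise independent-samples t-tests as post-hoc analysis.

Folds can be cut at the epoch level (stratified by stage) or at the
subject level (no subject ever appears on both sides of a fold; folds
stratified by subject-level strata such as age group × OSA class when
provided).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import STAGES
from .staging import _fit_classifier

__all__ = [
    "CVResult",
    "StageMetrics",
    "AnovaReport",
    "repeated_cv",
    "stage_metrics",
    "one_way_anova",
    "cross_group_validation",
    "stage_mean_features",
    "inter_subject_correlation",
]


@dataclass
class StageMetrics:
    accuracy: float
    f1: dict[str, float]                  # per stage; NaN when undefined
    confusion: np.ndarray                 # (5, 5) counts, rows = true stage
    confusion_normalized: np.ndarray      # rows divided by true-stage counts

    @property
    def macro_f1(self) -> float:
        vals = [v for v in self.f1.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class CVResult:
    accuracies: np.ndarray                # k·reps values
    per_stage_f1: dict[str, np.ndarray]   # stage -> k·reps values (NaN allowed)
    confusion: np.ndarray                 # summed over all folds
    config: dict = field(default_factory=dict)


@dataclass
class AnovaReport:
    F: float
    df_between: int
    df_within: int
    p: float
    posthoc: list[dict] = field(default_factory=list)


def stage_metrics(true, pred, labels: tuple[str, ...] = STAGES) -> StageMetrics:
    """Accuracy, one-vs-rest per-stage f1 and the confusion matrix.

    ``true`` and ``pred`` are equal-length label sequences (Hypnograms
    iterate as label sequences).  A stage absent from both sequences gets
    an undefined (NaN) f1, excluded from macro averages.
    """
    t = np.asarray(list(true), dtype=object)
    p = np.asarray(list(pred), dtype=object)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted")
    from sklearn.metrics import confusion_matrix, f1_score

    acc = float(np.mean(t == p))
    conf = confusion_matrix(t, p, labels=list(labels))
    f1_vals = f1_score(t, p, labels=list(labels), average=None,
                       zero_division=np.nan)
    f1 = {s: float(v) for s, v in zip(labels, f1_vals)}
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, conf / row_sums, np.nan)
    return StageMetrics(acc, f1, conf, norm)


def _subject_folds(
    subjects: np.ndarray, k: int, rng: np.random.Generator,
    strata: dict | None = None,
) -> dict:
    """Assign each subject a fold id 0..k-1, round-robin within strata."""
    unique = pd.unique(subjects)
    if len(unique) < k:
        raise ValueError(f"need at least k={k} subjects, have {len(unique)}")
    fold_of: dict = {}
    groups: dict = {}
    for s in unique:
        key = strata.get(s) if strata else None
        groups.setdefault(key, []).append(s)
    start = 0
    for key in sorted(groups, key=str):
        members = groups[key]
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            fold_of[members[j]] = (start + i) % k
        start += len(members)
    return fold_of


def repeated_cv(
    data: pd.DataFrame,
    algorithm: str,
    k: int = 5,
    reps: int = 10,
    split_unit: str = "subject",
    seed: int = 0,
    label_col: str = "stage",
    subject_col: str = "subject_id",
    strata: dict | None = None,
    labels: tuple[str, ...] = STAGES,
) -> CVResult:
    """Repeated stratified k-fold cross-validation (k·reps scores).

    Every repetition reshuffles the dataset; each fold fits a model (with
    its inner grid search) on the other k−1 folds and scores the held-out
    fold.  With ``split_unit="subject"`` all epochs of a subject stay on
    one side of every fold.
    """
    if data.empty:
        raise ValueError("empty feature matrix")
    if split_unit not in ("epoch", "subject"):
        raise ValueError("split_unit must be 'epoch' or 'subject'")
    from sklearn.model_selection import StratifiedKFold

    from .features import feature_columns

    cols = feature_columns(data)
    X = data.loc[:, cols].to_numpy(dtype=float)
    y = data[label_col].to_numpy()
    subjects = data[subject_col].to_numpy() if subject_col in data else None
    if split_unit == "subject" and subjects is None:
        raise ValueError("subject splits need a subject_id column")

    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    accs, f1s = [], {s: [] for s in labels}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for rep_seed in rep_seeds:
        rep_seed = int(rep_seed)
        if split_unit == "epoch":
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = skf.split(X, y)
        else:
            rng = np.random.default_rng(rep_seed)
            fold_of = _subject_folds(subjects, k, rng, strata)
            fold_ids = np.array([fold_of[s] for s in subjects])
            splits = (
                (np.flatnonzero(fold_ids != j), np.flatnonzero(fold_ids == j))
                for j in range(k)
            )
        for train_idx, test_idx in splits:
            present_train = set(np.unique(y[train_idx]))
            if set(np.unique(y[test_idx])) - present_train:
                warnings.warn(
                    "a test fold contains a class absent from its training folds"
                )
            model = _fit_classifier(
                X[train_idx], y[train_idx], cols, algorithm, rep_seed
            )
            pred = model.predict(X[test_idx])
            m = stage_metrics(y[test_idx], pred, labels=labels)
            accs.append(m.accuracy)
            for s in labels:
                f1s[s].append(m.f1[s])
            confusion += m.confusion
    return CVResult(
        accuracies=np.array(accs),
        per_stage_f1={s: np.array(v) for s, v in f1s.items()},
        confusion=confusion,
        config={"k": k, "reps": reps, "split_unit": split_unit,
                "seed": seed, "algorithm": algorithm},
    )


def one_way_anova(groups, alpha: float = 0.01) -> AnovaReport:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    ``groups`` is a list of ≥2 value vectors (≥2 values each).  When the
    omnibus test is significant at ``alpha``, Bonferroni-corrected
    pairwise pooled-variance t-tests are run as post-hoc comparisons.
    If every observation equals the grand mean (zero variance everywhere),
    F is defined as 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(len(a) for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        F = 0.0 if ms_between == 0.0 else float("inf")
    else:
        F = float(ms_between / ms_within)
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0

    posthoc = []
    if p < alpha:
        pairs = list(itertools.combinations(range(len(arrs)), 2))
        for i, j in pairs:
            t, p_raw = stats.ttest_ind(arrs[i], arrs[j], equal_var=True)
            p_adj = min(1.0, float(p_raw) * len(pairs))
            posthoc.append({
                "pair": (i, j), "t": float(t), "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            })
    return AnovaReport(F=F, df_between=df_b, df_within=df_w, p=p, posthoc=posthoc)


def cross_group_validation(
    data: pd.DataFrame,
    group_col: str,
    algorithm: str,
    seed: int = 0,
    k: int = 5,
    label_col: str = "stage",
    subject_col: str = "subject_id",
    labels: tuple[str, ...] = STAGES,
) -> dict[tuple[str, str], np.ndarray]:
    """Within- and cross-group validation scores for every ordered pair.

    For each training group, subject-level k-fold models are fitted; the
    same-group entry holds the k held-out fold accuracies, while each
    cross-group entry holds the same k models scored on the *entire*
    other group (e.g. Y-Y, Y-O, O-O, O-Y for two age groups).
    """
    from .features import feature_columns

    groups = [str(g) for g in pd.unique(data[group_col])]
    if len(groups) < 2:
        raise ValueError(f"need at least two groups in {group_col!r}")
    cols = feature_columns(data)
    if group_col in cols:
        cols.remove(group_col)
    out: dict[tuple[str, str], list[float]] = {}
    rng = np.random.default_rng(seed)
    for tg in groups:
        sub = data[data[group_col].astype(str) == tg]
        X = sub.loc[:, cols].to_numpy(dtype=float)
        y = sub[label_col].to_numpy()
        subjects = sub[subject_col].to_numpy()
        fold_of = _subject_folds(subjects, k, rng)
        fold_ids = np.array([fold_of[s] for s in subjects])
        others = {
            eg: data[data[group_col].astype(str) == eg] for eg in groups if eg != tg
        }
        for j in range(k):
            train_idx = np.flatnonzero(fold_ids != j)
            model = _fit_classifier(X[train_idx], y[train_idx], cols,
                                    algorithm, seed)
            test_idx = np.flatnonzero(fold_ids == j)
            acc = stage_metrics(y[test_idx], model.predict(X[test_idx]),
                                labels=labels).accuracy
            out.setdefault((tg, tg), []).append(acc)
            for eg, other in others.items():
                Xo = other.loc[:, cols].to_numpy(dtype=float)
                yo = other[label_col].to_numpy()
                acc_o = stage_metrics(yo, model.predict(Xo),
                                      labels=labels).accuracy
                out.setdefault((tg, eg), []).append(acc_o)
    return {pair: np.array(v) for pair, v in out.items()}


def stage_mean_features(
    data: pd.DataFrame, stage: str, subject_col: str = "subject_id"
) -> pd.DataFrame:
    """Per-subject mean feature vector over epochs of one stage."""
    from .features import feature_columns

    cols = feature_columns(data)
    sub = data[data["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no epochs of stage {stage!r}")
    return sub.groupby(subject_col, sort=False)[cols].mean()


def inter_subject_correlation(
    stage_means: pd.DataFrame, groups: dict | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Pearson correlations between subjects' stage-mean vectors.

    ``stage_means`` is subjects × features (see :func:`stage_mean_features`).
    Pairs involving a constant vector get NaN.  With a subject→group map,
    the mean off-diagonal correlation within each group is reported —
    higher values mean a more homogeneous group.
    """
    if len(stage_means) < 2:
        raise ValueError("need at least 2 subjects")
    M = stage_means.to_numpy(dtype=float)
    sd = M.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(M)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    cdf = pd.DataFrame(corr, index=stage_means.index, columns=stage_means.index)
    summary: dict[str, float] = {}
    if groups:
        for g in sorted(set(groups.values()), key=str):
            members = [s for s in stage_means.index if groups.get(s) == g]
            if len(members) < 2:
                continue
            block = cdf.loc[members, members].to_numpy()
            off = block[~np.eye(len(members), dtype=bool)]
            summary[str(g)] = float(np.nanmean(off))
    return cdf, summary
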