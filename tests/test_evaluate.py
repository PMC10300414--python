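"""Repeated CV, per-stage metrics, ANOVA and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnoscreen import evaluate as ev
from somnoscreen.io import STAGES


def labeled_frame(rng, n_per_class=20, n_subjects=10, separation=6.0,
                  classes=STAGES):
    rows = []
    for i, c in enumerate(classes):
        X = rng.standard_normal((n_per_class, 3)) + i * separation
        for j in range(n_per_class):
            rows.append({"subject_id": f"s{(len(rows)) % n_subjects}",
                         "stage": c, "f0": X[j, 0], "f1": X[j, 1],
                         "f2": X[j, 2]})
    return pd.DataFrame(rows)


class TestStageMetrics:
    def test_identical_sequences(self):
        m = ev.stage_metrics(["W", "N1", "N2", "N3", "R"],
                             ["W", "N1", "N2", "N3", "R"])
        assert m.accuracy == 1.0
        assert all(v == 1.0 for v in m.f1.values())
        assert np.trace(m.confusion) == 5

    def test_hand_computed_example(self):
        # W: precision 1/1, recall 1/2 -> f1 = 2/3
        # N2: precision 2/3, recall 2/2 -> f1 = 4/5
        m = ev.stage_metrics(["W", "W", "N2", "N2"], ["W", "N2", "N2", "N2"])
        assert m.accuracy == pytest.approx(0.75)
        assert m.f1["W"] == pytest.approx(2 / 3)
        assert m.f1["N2"] == pytest.approx(0.8)

    def test_absent_stage_f1_undefined_and_excluded(self):
        m = ev.stage_metrics(["W", "N2"], ["W", "N2"])
        assert np.isnan(m.f1["N3"])
        assert m.macro_f1 == pytest.approx(1.0)

    def test_confusion_conservation_and_trace(self, rng):
        t = rng.choice(STAGES, size=200)
        p = rng.choice(STAGES, size=200)
        m = ev.stage_metrics(t, p)
        assert m.confusion.sum() == 200
        assert m.accuracy == pytest.approx(np.trace(m.confusion) / 200)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.stage_metrics(["W"], ["W", "N1"])


class TestAnova:
    def test_identical_groups_f_zero(self):
        rep = ev.one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert rep.F == pytest.approx(0.0)
        assert rep.posthoc == []

    def test_df_shape_for_three_groups_of_fifty(self, rng):
        groups = [rng.normal(m, 1, 50) for m in (0, 0.1, 0.2)]
        rep = ev.one_way_anova(groups)
        assert (rep.df_between, rep.df_within) == (2, 147)

    def test_matches_brute_force_and_scipy(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        rep = ev.one_way_anova(groups)
        # brute-force sums of squares
        allv = np.concatenate([np.asarray(g, float) for g in groups])
        grand = allv.mean()
        ssb = sum(3 * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        expected_F = (ssb / 2) / (ssw / 6)
        assert rep.F == pytest.approx(expected_F, abs=1e-10)
        F_sp, p_sp = stats.f_oneway(*groups)
        assert rep.F == pytest.approx(F_sp, abs=1e-10)
        assert rep.p == pytest.approx(p_sp, abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0, 1, 2)]
        base = ev.one_way_anova(groups).F
        shifted = ev.one_way_anova([g + 100 for g in groups]).F
        scaled = ev.one_way_anova([g * 7.5 for g in groups]).F
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_posthoc_bonferroni_when_significant(self, rng):
        groups = [rng.normal(m, 0.5, 50) for m in (0, 0, 5)]
        rep = ev.one_way_anova(groups)
        assert rep.p < 0.01 and len(rep.posthoc) == 3
        by_pair = {tuple(h["pair"]): h for h in rep.posthoc}
        assert by_pair[(0, 2)]["significant"]
        assert not by_pair[(0, 1)]["significant"]
        t, p_raw = stats.ttest_ind(groups[0], groups[2])
        assert by_pair[(0, 2)]["p_bonferroni"] == pytest.approx(
            min(1.0, p_raw * 3))

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            ev.one_way_anova([[1, 2, 3]])


class TestRepeatedCV:
    def test_k_times_reps_scores(self, rng):
        df = labeled_frame(rng, n_per_class=12, classes=("W", "N2"))
        res = ev.repeated_cv(df, "knn", k=3, reps=2, split_unit="epoch",
                             seed=0)
        assert len(res.accuracies) == 6
        assert res.confusion.sum() == 2 * len(df)
        assert res.config["split_unit"] == "epoch"

    def test_perfect_separation_all_ones(self, rng):
        df = labeled_frame(rng, n_per_class=15, classes=("W", "N2", "R"),
                           separation=30.0)
        res = ev.repeated_cv(df, "knn", k=3, reps=2, split_unit="epoch",
                             seed=1)
        assert np.all(res.accuracies == 1.0)
        for s in ("W", "N2", "R"):
            assert np.all(res.per_stage_f1[s] == 1.0)

    def test_deterministic_given_seed(self, rng):
        df = labeled_frame(rng, n_per_class=12, separation=1.0,
                           classes=("W", "N2"))
        r1 = ev.repeated_cv(df, "knn", k=3, reps=2, split_unit="epoch", seed=5)
        r2 = ev.repeated_cv(df, "knn", k=3, reps=2, split_unit="epoch", seed=5)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)

    def test_subject_split_never_splits_a_subject(self, rng):
        # subjects have near-duplicate epochs: epoch-level folds let a 1-NN
        # memorize its neighbour, subject-level folds cannot
        rows = []
        for s in range(10):
            center = rng.standard_normal(3) * 0.05
            label = "W" if s % 2 == 0 else "N2"
            for e in range(12):
                x = center + 1e-4 * rng.standard_normal(3)
                rows.append({"subject_id": f"s{s}", "stage": label,
                             "f0": x[0], "f1": x[1], "f2": x[2]})
        df = pd.DataFrame(rows)
        folds = ev._subject_folds(df["subject_id"].to_numpy(), 5,
                                  np.random.default_rng(0))
        assert sorted(folds) == [f"s{i}" for i in range(10)]
        assert set(folds.values()) == set(range(5))
        epoch_cv = ev.repeated_cv(df, "knn", k=5, reps=1, split_unit="epoch",
                                  seed=0)
        subj_cv = ev.repeated_cv(df, "knn", k=5, reps=1, split_unit="subject",
                                 seed=0)
        assert epoch_cv.accuracies.mean() > 0.99
        assert subj_cv.accuracies.mean() < 0.9  # leakage would give ~1.0


class TestCrossGroupValidation:
    def test_four_ordered_pairs_and_cross_penalty(self, rng):
        rows = []
        for g, (offset, label_shift) in (("younger", (0.0, 0)),
                                         ("older", (40.0, 1))):
            for s in range(6):
                for e in range(10):
                    stage = STAGES[(s + e + label_shift) % 2]
                    base = 5.0 if stage == "W" else -5.0
                    rows.append({
                        "subject_id": f"{g}{s}", "stage": stage,
                        "age_group": g,
                        "f0": base + offset + rng.standard_normal(),
                        "f1": rng.standard_normal(),
                    })
        df = pd.DataFrame(rows)
        out = ev.cross_group_validation(df, "age_group", "knn", seed=0, k=3)
        assert set(out) == {("younger", "younger"), ("younger", "older"),
                            ("older", "older"), ("older", "younger")}
        # disjoint feature supports: same-group beats cross-group
        assert out[("younger", "younger")].mean() \
            >= out[("younger", "older")].mean()

    def test_same_distribution_groups_indistinguishable(self, rng):
        rows = []
        for g in ("younger", "older"):
            for s in range(8):
                for e in range(12):
                    stage = STAGES[(s + e) % 2]
                    base = 4.0 if stage == "W" else -4.0
                    rows.append({"subject_id": f"{g}{s}", "stage": stage,
                                 "age_group": g,
                                 "f0": base + rng.standard_normal(),
                                 "f1": rng.standard_normal()})
        df = pd.DataFrame(rows)
        out = ev.cross_group_validation(df, "age_group", "knn", seed=0, k=4)
        same = out[("younger", "younger")]
        cross = out[("younger", "older")]
        # overlapping 95% intervals under the same generating distribution
        ci = lambda a: (a.mean() - 2 * a.std() / np.sqrt(len(a)) - 0.05,
                        a.mean() + 2 * a.std() / np.sqrt(len(a)) + 0.05)
        lo1, hi1 = ci(same)
        lo2, hi2 = ci(cross)
        assert max(lo1, lo2) <= min(hi1, hi2)


class TestInterSubjectCorrelation:
    def test_identical_subjects_correlate_perfectly(self):
        v = np.linspace(0, 1, 48)
        df = pd.DataFrame([v, v], index=["a", "b"])
        corr, _ = ev.inter_subject_correlation(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        v = np.linspace(-1, 1, 48)
        df = pd.DataFrame([v, -v], index=["a", "b"])
        corr, _ = ev.inter_subject_correlation(df)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_vector_flagged_nan(self):
        df = pd.DataFrame([np.linspace(0, 1, 10), np.full(10, 0.5)],
                          index=["a", "b"])
        corr, _ = ev.inter_subject_correlation(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_homogeneous_group_more_correlated(self, rng):
        template = np.linspace(0, 1, 48)
        subjects, groups = [], {}
        for i in range(6):
            subjects.append(template + 0.02 * rng.standard_normal(48))
            groups[f"h{i}"] = "homogeneous"
        for i in range(6):
            subjects.append(template + 0.5 * rng.standard_normal(48))
            groups[f"x{i}"] = "heterogeneous"
        df = pd.DataFrame(subjects,
                          index=[*(f"h{i}" for i in range(6)),
                                 *(f"x{i}" for i in range(6))])
        _, summary = ev.inter_subject_correlation(df, groups)
        assert summary["homogeneous"] > summary["heterogeneous"]
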