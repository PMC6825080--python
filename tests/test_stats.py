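"""Evaluation statistics: group tests, ROC/AUC, DeLong, ICC, confusion."""

import numpy as np
import pandas as pd
import pytest

from abustex.errors import DegenerateVarianceError, ParameterError
from abustex.stats import (
    anova_per_feature,
    confusion_metrics,
    delong_compare,
    feature_correlation_matrix,
    icc_two_reader,
    landis_koch_category,
    roc_with_ci,
    ttest_per_feature,
)

from _oracles import brute_auc


def _frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame({k: np.asarray(v, dtype=np.float64) for k, v in cols.items()})


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        table = _frame({"f": [1, 2, 3] * 3})
        labels = np.repeat(["a", "b", "c"], 3)
        res = anova_per_feature(table, labels)
        assert res.loc[0, "F"] == pytest.approx(0.0)
        assert not res.loc[0, "significant"]

    def test_separated_groups_below_any_threshold(self):
        rng = np.random.default_rng(0)
        table = _frame({"f": np.concatenate([
            0 + rng.normal(scale=1e-3, size=4),
            10 + rng.normal(scale=1e-3, size=4),
            20 + rng.normal(scale=1e-3, size=4),
        ])})
        labels = np.repeat(["a", "b", "c"], 4)
        res = anova_per_feature(table, labels)
        assert res.loc[0, "p"] < 1e-12
        assert res.loc[0, "significant"]

    def test_one_row_per_feature(self, feature_table):
        res = anova_per_feature(feature_table, feature_table["class_label"],
                                feature_names=feature_table.columns[4:])
        assert len(res) == 47

    def test_ttest_identical_and_separated(self):
        table = _frame({"f": [1.0, 2.0, 1.0, 2.0]})
        res = ttest_per_feature(table, ["a", "a", "b", "b"])
        assert res.loc[0, "t"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

        table2 = _frame({"f": [0.0, 1.0, 10.0, 11.0]})
        res2 = ttest_per_feature(table2, ["a", "a", "b", "b"])
        # hand two-sample t: means 0.5 vs 10.5, pooled sd 1/sqrt(2) per group formula
        diff = 0.5 - 10.5
        se = np.sqrt(0.5 * (1 / 2 + 1 / 2))
        assert res2.loc[0, "t"] == pytest.approx(diff / se)
        assert res2.loc[0, "p"] < 0.01

    def test_ttest_antisymmetric_in_group_order(self):
        table = _frame({"f": [0.0, 1.0, 10.0, 11.0]})
        t_ab = ttest_per_feature(table, ["a", "a", "b", "b"]).loc[0, "t"]
        t_ba = ttest_per_feature(table, ["b", "b", "a", "a"]).loc[0, "t"]
        assert t_ab == pytest.approx(-t_ba)


class TestROC:
    def test_perfect_ordering(self):
        r = roc_with_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        r = roc_with_ci([0.5] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_pair_counting_examples(self):
        assert roc_with_ci([0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0]).auc == pytest.approx(1.0)
        assert roc_with_ci([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 51))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        r = roc_with_ci(scores, labels)
        assert r.auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        # AUC equals the trapezoidal integral of the ROC curve
        trap = np.trapezoid(r.sensitivity, r.one_minus_specificity)
        assert r.auc == pytest.approx(trap, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_with_ci([0.1, 0.9], [1, 1])

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        boots = []
        for _ in range(1000):
            idx_p = rng.integers(0, 40, 40)
            idx_n = 40 + rng.integers(0, 40, 40)
            idx = np.concatenate([idx_p, idx_n])
            boots.append(brute_auc_fast(scores[idx], labels[idx]))
        boot_var = np.var(boots, ddof=1)
        from abustex.stats import _auc_variance, _placements

        a10, a01, _ = _placements(scores, labels)
        assert _auc_variance(a10, a01) == pytest.approx(boot_var, rel=0.2)


def brute_auc_fast(scores, labels):
    from scipy.stats import rankdata

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array([0, 1, 0, 1, 1, 0])
        res = delong_compare(scores, scores, labels)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_placements_match_pair_enumeration_n4(self):
        scores_a = np.array([0.9, 0.6, 0.4, 0.1])
        scores_b = np.array([0.2, 0.8, 0.6, 0.4])
        labels = np.array([1, 0, 1, 0])
        res = delong_compare(scores_a, scores_b, labels)
        assert res.auc_a == pytest.approx(brute_auc(scores_a, labels))
        assert res.auc_b == pytest.approx(brute_auc(scores_b, labels))
        assert res.delta == pytest.approx(res.auc_a - res.auc_b)
        assert 0.0 <= res.p_value <= 1.0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        n = 60
        rejections = 0
        reps = 500
        for _ in range(reps):
            labels = np.array([1] * n + [0] * n)
            scores_a = rng.normal(size=2 * n)
            scores_b = rng.normal(size=2 * n)
            res = delong_compare(scores_a, scores_b, labels)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.08

    def test_degenerate_variance_with_real_difference_raises(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([1.0, 1.0, 0.0, 0.0])  # AUC 1, zero variance
        b = np.array([0.0, 0.0, 1.0, 1.0])  # AUC 0, zero variance
        with pytest.raises(DegenerateVarianceError):
            delong_compare(a, b, labels)


class TestICC:
    def test_identical_readers_perfect(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_two_reader(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "almost perfect"

    def test_landis_koch_boundaries(self):
        assert landis_koch_category(0.70) == "substantial"
        assert landis_koch_category(0.50) == "moderate"
        assert landis_koch_category(0.30) == "poor/fair"
        assert landis_koch_category(0.90) == "almost perfect"
        assert landis_koch_category(0.60) == "moderate"
        assert landis_koch_category(0.80) == "substantial"

    def test_offset_reader_matches_mean_squares_formula(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0])
        r2 = r1 + 1.0
        res = icc_two_reader(r1, r2)
        # hand ANOVA mean squares, n=4, k=2
        data = np.column_stack([r1, r2])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((data - data.mean(axis=1, keepdims=True)
                - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(expected)
        assert res.icc < 1.0

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        r1 = rng.normal(size=12)
        r2 = 0.8 * r1 + rng.normal(scale=0.4, size=12) + 0.2
        res = icc_two_reader(r1, r2)
        frame = pd.DataFrame({
            "targets": np.tile(np.arange(12), 2),
            "raters": np.repeat(["r1", "r2"], 12),
            "scores": np.concatenate([r1, r2]),
        })
        ref = pingouin.intraclass_corr(frame, targets="targets", raters="raters",
                                       ratings="scores")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=0.02)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=0.02)

    def test_degenerate_and_small_n(self):
        with pytest.raises(DegenerateVarianceError):
            icc_two_reader([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ParameterError):
            icc_two_reader([1.0, 2.0], [1.0, 2.0])


class TestConfusion:
    def test_perfect_prediction(self):
        r = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (r.accuracy, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_all_positive_prediction(self):
        r = confusion_metrics([1, 1, 1, 1], [1, 0, 1, 0])
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0

    def test_validation_counts_reproduce_reported_percentages(self):
        # counts TP 50 / FN 4 / FP 3 / TN 48 -> 93.3 / 92.6 / 94.1 percent
        predicted = [1] * 50 + [0] * 4 + [1] * 3 + [0] * 48
        actual = [1] * 54 + [0] * 51
        r = confusion_metrics(predicted, actual)
        assert (r.tp, r.fn, r.fp, r.tn) == (50, 4, 3, 48)
        assert round(100 * r.accuracy, 1) == 93.3
        assert round(100 * r.sensitivity, 1) == 92.6
        assert round(100 * r.specificity, 1) == 94.1

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics([], [])


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        table = _frame({"a": x, "b": x.copy(), "c": -x})
        corr = feature_correlation_matrix(table)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(5)
        table = _frame({f"f{i}": rng.normal(size=1000) for i in range(12)})
        corr = feature_correlation_matrix(table).to_numpy()
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.mean(np.abs(off) < 0.15) >= 0.95

    def test_constant_column_flagged_zeroed(self):
        rng = np.random.default_rng(6)
        table = _frame({"a": rng.normal(size=10), "b": np.ones(10)})
        corr = feature_correlation_matrix(table)
        assert corr.attrs["constant_columns"] == ["b"]
        assert corr.loc["a", "b"] == 0.0
        assert corr.loc["b", "b"] == 1.0
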