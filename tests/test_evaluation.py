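import numpy as np
import pytest
from scipy import stats

from imrf import (
    ExpressionMatrix,
    LabelVector,
    anova_pvalues,
    classification_metrics,
    count_pvalues_above,
    generate_planted_tabular,
    load_reference_pvalues,
    pvalue_ratio_report,
    svm_validate,
)


def matrix_from(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return ExpressionMatrix([f"s{i}" for i in range(values.shape[0])], names, values)


class TestAnova:
    def test_hand_computed_f_statistic(self):
        # groups A=[1,2,3], B=[2,3,4]: SSB=1.5, SSW=4 → F=1.5 on df (1, 4)
        X = matrix_from([[1], [2], [3], [2], [3], [4]])
        y = LabelVector.from_labels(["A"] * 3 + ["B"] * 3)
        p = anova_pvalues(X, y).pvalues["f0"]
        assert p == pytest.approx(stats.f.sf(1.5, 1, 4), abs=1e-12)

    def test_agrees_with_independent_oracle(self):
        """Vectorized sums-of-squares route vs scipy's f_oneway, 30 fixtures."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            counts = [int(rng.integers(3, 10)) for _ in range(k)]
            m = int(rng.integers(1, 6))
            values = rng.normal(size=(sum(counts), m))
            labels = LabelVector.from_labels(
                [f"c{i}" for i, n in enumerate(counts) for _ in range(n)]
            )
            table = anova_pvalues(matrix_from(values), labels)
            for j in range(m):
                groups = [values[labels.indices_of(f"c{i}"), j] for i in range(k)]
                expected = stats.f_oneway(*groups).pvalue
                assert table.pvalues[f"f{j}"] == pytest.approx(expected, abs=1e-9)

    def test_constant_feature_convention(self):
        X = matrix_from([[5.0], [5.0], [5.0], [5.0]])
        y = LabelVector.from_labels(["A", "A", "B", "B"])
        assert anova_pvalues(X, y).pvalues["f0"] == 1.0

    def test_perfect_separation_convention(self):
        X = matrix_from([[0.0], [0.0], [1.0], [1.0]])
        y = LabelVector.from_labels(["A", "A", "B", "B"])
        assert anova_pvalues(X, y).pvalues["f0"] == 0.0

    def test_single_class_is_error(self):
        X = matrix_from([[1.0], [2.0]])
        y = LabelVector.from_labels(["A", "A"])
        with pytest.raises(ValueError, match="2 classes"):
            anova_pvalues(X, y)

    def test_feature_subset(self):
        ds = generate_planted_tabular({"A": 10, "B": 10}, m=8, n_informative=2, seed=1)
        table = anova_pvalues(ds.matrix, ds.labels, features=["f3", "f1"])
        assert list(table.pvalues) == ["f3", "f1"]
        with pytest.raises(ValueError, match="unknown"):
            anova_pvalues(ds.matrix, ds.labels, features=["nope"])


class TestThresholdCounts:
    def test_strict_count_and_conservation(self):
        rng = np.random.default_rng(3)
        pvals = list(rng.uniform(size=50))
        above = count_pvalues_above(pvals, 0.05)
        below_or_equal = sum(1 for p in pvals if p <= 0.05)
        assert above + below_or_equal == 50

    def test_empty_list_counts_zero(self):
        assert count_pvalues_above([], 0.05) == 0

    def test_bad_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            count_pvalues_above([0.1], 1.5)

    def test_ratio_boundary_goes_up(self):
        assert pvalue_ratio_report([0.05], 0.05) == (1.0, 0.0)
        assert pvalue_ratio_report([0.5, 0.5], 0.05) == (1.0, 0.0)

    def test_ratio_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            pvalue_ratio_report([], 0.05)


class TestReferencePValues:
    """Threshold counting on the published signature p-values."""

    @pytest.mark.parametrize(
        "comparison,n_genes,n_above",
        [
            ("late_ad_vs_pure_late", 20, 4),
            ("late_ad_vs_pure_ad", 24, 6),
            ("pure_late_vs_pure_ad", 21, 7),
            ("late_ad_vs_control", 12, 1),
            ("pure_late_vs_control", 18, 3),
            ("pure_ad_vs_control", 14, 3),
        ],
    )
    def test_pairwise_counts(self, comparison, n_genes, n_above):
        entries = load_reference_pvalues(comparison)
        assert len(entries) == n_genes
        assert count_pvalues_above([p for _, p in entries], 0.05) == n_above

    def test_four_class_counts_and_ratio(self):
        entries = load_reference_pvalues("four_class")
        pvals = [p for _, p in entries]
        assert len(pvals) == 31
        assert count_pvalues_above(pvals, 0.05) == 7
        assert pvalue_ratio_report(pvals, 0.05) == (7 / 31, 24 / 31)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        r = classification_metrics(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        assert r.accuracy == 1.0
        assert all(v == 1.0 for v in r.f1.values())

    def test_constant_prediction(self):
        r = classification_metrics(["A", "B"], ["A", "A"], ["A", "B"])
        assert r.accuracy == 0.5
        assert r.f1["B"] == 0.0

    def test_three_class_hand_confusion(self):
        # confusion [[2,1,0],[0,2,0],[1,0,4]]
        y_true = ["a"] * 3 + ["b"] * 2 + ["c"] * 5
        y_pred = ["a", "a", "b", "b", "b", "a", "c", "c", "c", "c"]
        r = classification_metrics(y_true, y_pred, ["a", "b", "c"])
        assert np.array_equal(r.confusion, [[2, 1, 0], [0, 2, 0], [1, 0, 4]])
        assert r.precision["a"] == pytest.approx(2 / 3)
        assert r.recall["a"] == pytest.approx(2 / 3)
        assert r.precision["b"] == pytest.approx(2 / 3)
        assert r.recall["b"] == pytest.approx(1.0)
        assert r.f1["b"] == pytest.approx(2 * (2 / 3) / (1 + 2 / 3))
        assert r.recall["c"] == pytest.approx(4 / 5)
        assert r.accuracy == pytest.approx(8 / 10)
        assert r.n_test == {"a": 3, "b": 2, "c": 5}

    def test_unknown_label_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            classification_metrics(["A"], ["Z"], ["A", "B"])


class TestSvmValidate:
    def test_identity_subset_equals_all_features(self):
        ds = generate_planted_tabular({"A": 20, "B": 20}, m=10, n_informative=2,
                                      effect_size=2.0, seed=4)
        full = svm_validate(ds.matrix, ds.labels, per_class_test=4, seed=9)
        explicit = svm_validate(
            ds.matrix, ds.labels, feature_subset=list(ds.matrix.feature_names),
            per_class_test=4, seed=9,
        )
        assert full.accuracy == explicit.accuracy
        assert full.f1 == explicit.f1

    def test_separable_toy_is_perfect(self):
        # one decisive feature: classes linearly separable in that coordinate
        values = np.zeros((20, 3))
        values[:, 1:] = np.random.default_rng(0).normal(size=(20, 2))
        values[10:, 0] = 10.0
        X = matrix_from(values)
        y = LabelVector.from_labels(["A"] * 10 + ["B"] * 10)
        r = svm_validate(X, y, feature_subset=["f0"], per_class_test=3, seed=0)
        assert r.accuracy == 1.0

    def test_unknown_feature_is_error(self):
        ds = generate_planted_tabular({"A": 8, "B": 8}, m=5, n_informative=1, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            svm_validate(ds.matrix, ds.labels, feature_subset=["ghost"], per_class_test=2)

    def test_deterministic_under_seed(self):
        ds = generate_planted_tabular({"A": 20, "B": 10}, m=8, n_informative=2, seed=2)
        a = svm_validate(ds.matrix, ds.labels, per_class_test=3, seed=5)
        b = svm_validate(ds.matrix, ds.labels, per_class_test=3, seed=5)
        assert a.accuracy == b.accuracy and a.f1 == b.f1
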