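"""Metric formulas, aggregation conventions and the reference tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifmtl import (
    classification_report,
    compare_accuracy,
    f1,
    mse_image,
    plcc,
    roc_auc_ovr,
)
from ifmtl.metrics import MetricError
from ifmtl.reference_tables import (
    ALL_TABLES,
    CLASSIFIER_SHARP,
    COMMON_CASCADE,
    TEST_COUNTS,
    realize_predictions,
)
from ifmtl.utils import round_half_up


def brute_force_auc(labels, scores, positive) -> float:
    """Pairwise positive-vs-negative comparison count, ties worth 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPlcc:
    def test_perfect_correlation(self):
        assert plcc([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert plcc([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct covariance/sd arithmetic: x=(.1,.9,.2,.8), y=(0,1,0,1)
        x = np.array([0.1, 0.9, 0.2, 0.8])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).mean() / (
            np.sqrt((xc**2).mean()) * np.sqrt((yc**2).mean())
        )
        assert plcc(x, y) == pytest.approx(expected, abs=1e-12)
        assert plcc(x, y) == pytest.approx(0.98994949, abs=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(MetricError, match="variance"):
            plcc([1, 1, 1], [0, 1, 0])

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.integers(0, 2, size=12).astype(float)
        if y.std() == 0:
            y[0] = 1 - y[0]
        assert abs(plcc(a * x + b, y) - plcc(x, y)) < 1e-10


class TestMseImage:
    def test_identical_images(self, rng):
        img = rng.random((7, 8, 8))
        assert mse_image(img, img) == 0.0

    def test_unit_difference(self):
        assert mse_image(np.ones((4, 4)), np.zeros((4, 4))) == pytest.approx(1.0)

    def test_hand_sum(self):
        i = np.array([[0.0, 0.5], [1.0, 0.25]])
        k = np.zeros((2, 2))
        assert mse_image(i, k) == pytest.approx(0.328125)

    def test_shape_mismatch(self):
        with pytest.raises(MetricError):
            mse_image(np.zeros((2, 2)), np.zeros((3, 3)))


class TestF1:
    def test_harmonic_mean_identity(self):
        for r in (0.1, 0.5, 0.93):
            assert f1(r, r) == pytest.approx(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(MetricError):
            f1(1.2, 0.5)

    def test_zero_denominator_defined(self):
        assert f1(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("table_name,rows", list(ALL_TABLES.items()))
    def test_reference_rows_reproduce_printed_f1(self, table_name, rows):
        """All 16 per-class rows: f1(P, R) rounded half-up to 2 d.p. equals
        the printed F1 column."""
        for disease, _n, _acc, recall, precision, printed_f1, _auc in rows:
            assert round_half_up(f1(precision, recall), 2) == pytest.approx(
                printed_f1
            ), f"{table_name}/{disease}"

    @settings(max_examples=40, deadline=None)
    @given(p=st.floats(0.01, 1.0), r=st.floats(0.01, 1.0))
    def test_between_min_and_max(self, p, r):
        v = f1(p, r)
        assert min(p, r) - 1e-12 <= v <= max(p, r) + 1e-12


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = ["a", "a", "b", "b"]
        assert roc_auc_ovr(labels, [0.9, 0.8, 0.2, 0.1], "a") == 1.0

    def test_constant_scores_half(self):
        labels = ["a", "a", "b", "b"]
        assert roc_auc_ovr(labels, [0.5] * 4, "a") == 0.5

    def test_five_sample_toy(self):
        labels = ["p", "p", "n", "n", "n"]
        scores = [0.9, 0.6, 0.7, 0.3, 0.2]
        assert roc_auc_ovr(labels, scores, "p") == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc_ovr(["a", "a"], [0.1, 0.2], "a")

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(4, 50), seed=st.integers(0, 10_000))
    def test_equals_brute_force_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # discretized scores force ties through the tie-handling path
        scores = rng.integers(0, 5, size=n) / 4.0
        assert roc_auc_ovr(labels, scores, 1) == pytest.approx(
            brute_force_auc(labels, scores, 1), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        assert roc_auc_ovr(y, s, 1) == pytest.approx(roc_auc_score(y, s))


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = ["a"] * 3 + ["b"] * 2
        scores = np.array([[1, 0]] * 3 + [[0, 1]] * 2, dtype=float)
        rep = classification_report(y, y, scores=scores, classes=("a", "b"))
        assert rep.totals["micro_accuracy"] == 1.0
        for name in ("a", "b"):
            row = rep.per_class[name]
            assert row["recall"] == row["precision"] == row["f1"] == 1.0
            assert row["auc"] == 1.0

    def test_toy_confusion_against_hand_count(self):
        """6-sample 2-class toy with confusion [[2,1],[1,2]]."""
        true = ["a", "a", "a", "b", "b", "b"]
        pred = ["a", "a", "b", "b", "b", "a"]
        rep = classification_report(true, pred, classes=("a", "b"))
        np.testing.assert_array_equal(rep.confusion, [[2, 1], [1, 2]])
        assert rep.totals["micro_accuracy"] == pytest.approx(4 / 6)
        assert rep.per_class["a"]["recall"] == pytest.approx(2 / 3)
        assert rep.per_class["a"]["accuracy"] == rep.per_class["a"]["recall"]

    def test_reference_sharp_table_totals(self):
        """Per-class recalls (.98,.97,.95,.95) at sizes 132/67/39/81 give
        micro total 0.97 and macro recall 0.96 after table rounding."""
        recalls = {r[0]: r[3] for r in CLASSIFIER_SHARP}
        true, pred = realize_predictions(recalls, TEST_COUNTS)
        rep = classification_report(true, pred, classes=tuple(TEST_COUNTS))
        assert rep.n == 319
        assert round_half_up(rep.totals["micro_accuracy"], 2) == 0.97
        assert round_half_up(rep.totals["macro_recall"], 2) == 0.96

    def test_reference_cascade_table_total(self):
        """The plain-cascade table's recalls total to micro accuracy 0.93."""
        recalls = {r[0]: r[3] for r in COMMON_CASCADE}
        true, pred = realize_predictions(recalls, TEST_COUNTS)
        rep = classification_report(true, pred, classes=tuple(TEST_COUNTS))
        assert round_half_up(rep.totals["micro_accuracy"], 2) == 0.93

    def test_micro_accuracy_is_support_weighted_recall(self, rng):
        labels = rng.integers(0, 3, size=60)
        preds = rng.integers(0, 3, size=60)
        for v in range(3):  # ensure all classes appear as true labels
            labels[v] = v
        rep = classification_report(labels, preds, classes=(0, 1, 2))
        weighted = sum(
            rep.per_class[c]["recall"] * rep.per_class[c]["n"] for c in (0, 1, 2)
        ) / rep.n
        assert rep.totals["micro_accuracy"] == pytest.approx(weighted, abs=1e-12)

    def test_unseen_prediction_class_rejected(self):
        with pytest.raises(MetricError, match="unseen"):
            classification_report(["a", "b"], ["a", "z"], classes=("a", "b"))


class TestCompareAccuracy:
    def test_identical_vectors_p_one(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        with pytest.warns(UserWarning):
            res = compare_accuracy(a, a, paired=True)
        assert res["p_value"] == 1.0

    def test_unpaired_hand_computed_chi_square(self):
        """2x2 table (90,10 / 70,30): E = [[80,20],[80,20]] so that
        chi2 = 100/80 + 100/20 + 100/80 + 100/20 = 12.5."""
        a = np.array([True] * 90 + [False] * 10)
        b = np.array([True] * 70 + [False] * 30)
        res = compare_accuracy(a, b, paired=False)
        assert res["statistic"] == pytest.approx(12.5, abs=1e-9)
        assert res["df"] == 1.0
        assert res["p_value"] < 0.001

    def test_mcnemar_discordant_counts(self):
        a = np.array([1, 1, 1, 0, 0, 1, 1, 1], dtype=bool)
        b = np.array([1, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        res = compare_accuracy(a, b, paired=True)
        # discordant: a-only = 2, b-only = 1 -> (2-1)^2 / 3
        assert res["statistic"] == pytest.approx(1 / 3)
        assert res["n10"] == 2 and res["n01"] == 1

    def test_matched_accuracy_smoke_on_319(self):
        """Two models at 0.94 vs 0.93 on n=319 with maximal discordance:
        the paired test runs and reports a p-value (no value asserted)."""
        n = 319
        a = np.zeros(n, dtype=bool)
        b = np.zeros(n, dtype=bool)
        a[: int(0.94 * n)] = True
        b[n - int(0.93 * n) :] = True
        res = compare_accuracy(a, b, paired=True)
        assert 0.0 <= res["p_value"] <= 1.0
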