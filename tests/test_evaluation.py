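import numpy as np
import pytest

from relclass.evaluation import (
    FoldReport,
    MetricSet,
    StratificationError,
    aggregate_folds,
    compute_metrics,
    cross_validate,
    stratified_balanced_folds,
    undersample,
)
from relclass.records_io import LabelError, LabelScheme


def metrics_oracle(y_true, y_pred, classes, averaging="macro_equal"):
    """Brute-force confusion-matrix computation, independent of the package."""
    classes = list(classes)
    C = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((C, C))
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    P = np.zeros(C)
    R = np.zeros(C)
    F = np.zeros(C)
    for c in range(C):
        pred = M[:, c].sum()
        true = M[c, :].sum()
        P[c] = M[c, c] / pred if pred else 0.0
        R[c] = M[c, c] / true if true else 0.0
        F[c] = 2 * P[c] * R[c] / (P[c] + R[c]) if P[c] + R[c] else 0.0
    if averaging == "macro_equal":
        w = np.full(C, 1.0 / C)
    else:
        support = M.sum(axis=1)
        w = support / support.sum()
    acc = np.trace(M) / M.sum()
    return acc, float(P @ w), float(R @ w), float(F @ w)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = ["a", "b", "a", "b"]
        m = compute_metrics(y, y)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_fixed_three_class_matrix_hand_values(self):
        # confusion matrix [[5,1,0],[2,3,1],[0,0,8]] (rows true, cols pred),
        # hand-computed per-class P/R/F1 averaged equally
        y_true = ["a"] * 6 + ["b"] * 6 + ["c"] * 8
        y_pred = (
            ["a"] * 5 + ["b"]
            + ["a"] * 2 + ["b"] * 3 + ["c"]
            + ["c"] * 8
        )
        m = compute_metrics(y_true, y_pred, scheme=("a", "b", "c"))
        assert m.accuracy == pytest.approx(0.8, abs=1e-12)
        assert m.precision == pytest.approx(0.784391534392, abs=1e-9)
        assert m.recall == pytest.approx(0.777777777778, abs=1e-9)
        assert m.f1 == pytest.approx(0.770135746606, abs=1e-9)
        w = compute_metrics(
            y_true, y_pred, scheme=("a", "b", "c"), averaging="weighted_by_support"
        )
        assert w.precision == pytest.approx(0.794841269841, abs=1e-9)
        assert w.f1 == pytest.approx(0.787239819005, abs=1e-9)

    def test_constant_predictor_on_balanced_binary(self):
        y_true = ["a"] * 10 + ["b"] * 10
        y_pred = ["a"] * 20
        m = compute_metrics(y_true, y_pred, scheme=("a", "b"))
        assert m.accuracy == 0.5
        assert m.recall == 0.5  # per-class recall 1.0 and 0.0

    def test_random_labelings_match_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            C = int(rng.integers(2, 11))
            classes = [f"c{i}" for i in range(C)]
            n = int(rng.integers(C, 60))
            y_true = rng.choice(classes, size=n)
            y_pred = rng.choice(classes, size=n)
            for avg in ("macro_equal", "weighted_by_support"):
                m = compute_metrics(y_true, y_pred, scheme=classes, averaging=avg)
                acc, p, r, f = metrics_oracle(y_true, y_pred, classes, avg)
                assert m.accuracy == pytest.approx(acc, abs=1e-9)
                assert m.precision == pytest.approx(p, abs=1e-9)
                assert m.recall == pytest.approx(r, abs=1e-9)
                assert m.f1 == pytest.approx(f, abs=1e-9)

    def test_weighted_equals_macro_on_equal_supports(self):
        rng = np.random.default_rng(5)
        y_true = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        y_pred = rng.choice(["a", "b", "c"], size=90)
        m = compute_metrics(y_true, y_pred, scheme=("a", "b", "c"))
        w = compute_metrics(
            y_true, y_pred, scheme=("a", "b", "c"), averaging="weighted_by_support"
        )
        assert m.precision == pytest.approx(w.precision, abs=1e-12)
        assert m.recall == pytest.approx(w.recall, abs=1e-12)
        assert m.f1 == pytest.approx(w.f1, abs=1e-12)

    def test_label_outside_scheme_is_error(self):
        with pytest.raises(LabelError):
            compute_metrics(["a", "x"], ["a", "a"], scheme=LabelScheme.binary())


class TestFolds:
    def test_proportional_stratification(self):
        labels = np.array(["maj"] * 80 + ["min"] * 20)
        plan = stratified_balanced_folds(labels, k=5, seed=0)
        for fold in range(5):
            va = plan.val_indices(fold)
            assert (labels[va] == "maj").sum() == 16
            assert (labels[va] == "min").sum() == 4

    def test_partition_and_disjointness(self):
        labels = np.array(["a", "b"] * 50)
        plan = stratified_balanced_folds(labels, k=5, seed=1)
        all_idx = np.concatenate([plan.val_indices(f) for f in range(5)])
        assert sorted(all_idx) == list(range(100))

    def test_undersample_equalizes_classes(self):
        labels = np.array(["maj"] * 80 + ["min"] * 20)
        plan = stratified_balanced_folds(labels, k=5, policy="undersample", seed=0)
        tr = plan.train_indices(0)
        counts = {c: (labels[tr] == c).sum() for c in ("maj", "min")}
        assert counts["maj"] == counts["min"] == 16

    def test_undersample_without_replacement(self):
        idx = np.arange(30)
        labels = np.array(["a"] * 20 + ["b"] * 10)
        out = undersample(idx, labels, seed=0)
        assert len(out) == 20 and len(set(out)) == 20

    def test_same_seed_identical_assignments(self):
        labels = np.array(["a", "b"] * 30)
        a = stratified_balanced_folds(labels, seed=9)
        b = stratified_balanced_folds(labels, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_small_class_raises_naming_it(self):
        labels = np.array(["big"] * 20 + ["tiny"] * 4)
        with pytest.raises(StratificationError, match="tiny"):
            stratified_balanced_folds(labels, k=5)

    def test_plan_csv_export(self, tmp_path):
        labels = np.array(["a", "b"] * 10)
        plan = stratified_balanced_folds(labels, k=5, seed=0)
        lines = plan.to_csv(tmp_path / "plan.csv").read_text().strip().split("\n")
        assert lines[0] == "record_id,fold"
        assert len(lines) == 21


class TestAggregateFolds:
    def _sets(self, f1s):
        return [
            MetricSet(accuracy=f, precision=f, recall=f, f1=f) for f in f1s
        ]

    def test_max_ave_min_triple(self):
        report = aggregate_folds(self._sets([0.9, 0.8, 0.7, 0.85, 0.75]))
        assert report.aggregate["f1"] == pytest.approx((0.9, 0.8, 0.7), abs=1e-12)

    def test_single_fold_collapses(self):
        report = aggregate_folds(self._sets([0.6]))
        assert report.aggregate["accuracy"] == (0.6, 0.6, 0.6)

    def test_fold_order_invariance(self):
        vals = [0.9, 0.5, 0.7]
        a = aggregate_folds(self._sets(vals)).aggregate
        b = aggregate_folds(self._sets(vals[::-1])).aggregate
        for m in a:
            assert b[m] == pytest.approx(a[m], abs=1e-12)

    def test_min_le_ave_le_max(self):
        rng = np.random.default_rng(0)
        report = aggregate_folds(self._sets(rng.random(7)))
        for mx, av, mn in report.aggregate.values():
            assert mn <= av <= mx

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            aggregate_folds([])


def test_cross_validate_baseline_pipeline():
    from relclass.baselines import BaselineSpec, make_baseline
    from conftest import make_text_dataset

    texts, labels = make_text_dataset(n=100, signal=1.0, seed=4, group=1)
    report = cross_validate(
        make_baseline(BaselineSpec("naive_bayes")), texts, labels, k=5, seed=0
    )
    assert len(report.folds) == 5
    assert report.aggregate["f1"][1] > 0.9  # separable corpus
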