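"""Confusion-matrix construction, one-vs-rest collapse, F1 identities."""

import numpy as np
import pytest

from afdetect1d import (
    CLASSES,
    BinaryConfusion,
    ConfusionMatrix4,
    accuracy,
    average_f1,
    collapse,
    confusion4,
    cv_report,
    f1,
    metrics_report,
    precision,
    recall,
)


def random_truth_pred(rng, n):
    return (rng.choice(CLASSES, n).tolist(), rng.choice(CLASSES, n).tolist())


class TestConfusion4:
    def test_perfect_classifier_is_diagonal(self):
        labels = list(CLASSES) * 3
        cm = confusion4(labels, labels)
        assert np.trace(cm.counts) == 12
        assert cm.counts.sum() == 12

    def test_placement_convention_rows_predicted(self):
        cm = confusion4(truth=["AF"], predicted=["Other"])
        assert cm.counts[CLASSES.index("Other"), CLASSES.index("AF")] == 1

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        t, p = random_truth_pred(rng, 40)
        assert confusion4(t, p).total == 40

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion4(["AF"], ["Sinus"])


class TestCollapse:
    def test_diagonal_matrix_has_no_errors(self):
        cm = ConfusionMatrix4(np.diag([5, 6, 7, 8]))
        for c in CLASSES:
            bc = collapse(cm, c)
            assert bc.fp == 0 and bc.fn == 0

    def test_hand_tallied_fixture(self):
        counts = np.diag([8, 30, 28, 30])
        counts[CLASSES.index("Other"), CLASSES.index("AF")] = 2
        counts[CLASSES.index("AF"), CLASSES.index("Normal")] = 2
        bc = collapse(ConfusionMatrix4(counts), "AF")
        assert (bc.tp, bc.fp, bc.fn, bc.tn) == (8, 2, 2, 88)

    def test_conservation_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cm = ConfusionMatrix4(rng.integers(0, 50, (4, 4)))
            for c in CLASSES:
                assert collapse(cm, c).total == cm.total


class TestBinaryMetrics:
    def test_worked_example(self):
        bc = BinaryConfusion(tp=8, fp=2, fn=2, tn=88)
        assert precision(bc) == pytest.approx(80.0)
        assert recall(bc) == pytest.approx(80.0)
        assert accuracy(bc) == pytest.approx(96.0)

    def test_perfect_classifier(self):
        bc = BinaryConfusion(tp=10, fp=0, fn=0, tn=30)
        assert precision(bc) == recall(bc) == accuracy(bc) == 100.0

    def test_zero_denominator_convention(self, caplog):
        bc = BinaryConfusion(tp=0, fp=0, fn=3, tn=7)
        with caplog.at_level("WARNING"):
            assert precision(bc) == 0.0
        assert "zero denominator" in caplog.text


class TestF1:
    def test_equal_precision_recall(self):
        assert f1(80.0, 80.0) == pytest.approx(80.0)

    def test_harmonic_mean(self):
        assert f1(100.0, 50.0) == pytest.approx(66.67, abs=0.005)

    def test_annihilation_and_convention(self):
        assert f1(0.0, 100.0) == 0.0
        assert f1(0.0, 0.0) == 0.0

    def test_bounded_by_max(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p, r = rng.uniform(0, 100, 2)
            v = f1(p, r)
            assert 0.0 <= v <= max(p, r) + 1e-9


class TestAverages:
    def test_constant_classes(self):
        assert average_f1({c: 70.0 for c in CLASSES}) == pytest.approx(70.0)

    def test_published_per_class_values(self):
        vals = dict(zip(("AF", "Normal", "Noisy", "Other"), (79.1, 90.7, 65.3, 76.0)))
        assert average_f1(vals) == pytest.approx(77.775)
        assert round(average_f1(vals), 1) == 77.8

    def test_three_class_mean(self):
        # per-class F1 of the average-pooling network; Noisy excluded
        assert np.mean([80.8, 90.4, 75.3]) == pytest.approx(82.17, abs=0.005)

    def test_micro_accuracy_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, (4, 4))
        cm = ConfusionMatrix4(counts)
        perm = rng.permutation(4)
        cm_perm = ConfusionMatrix4(counts[np.ix_(perm, perm)])
        assert cm.micro_accuracy() == pytest.approx(cm_perm.micro_accuracy())


class TestCvReport:
    def _report_with_avg(self, value):
        cm = ConfusionMatrix4(np.diag([5, 5, 5, 5]))
        r = metrics_report(cm)
        r.average_f1 = value
        return r

    def test_identical_folds_have_zero_sigma(self):
        folds = [self._report_with_avg(70.0) for _ in range(5)]
        assert cv_report(folds).sigma == 0.0

    def test_population_sigma_convention(self):
        agg = cv_report([self._report_with_avg(70.0), self._report_with_avg(80.0)])
        assert agg.average_f1 == pytest.approx(75.0)
        assert agg.sigma == pytest.approx(5.0)

    def test_mean_equals_hand_computation(self):
        rng = np.random.default_rng(4)
        reports = []
        for _ in range(5):
            t, p = rng.choice(CLASSES, 60).tolist(), rng.choice(CLASSES, 60).tolist()
            reports.append(metrics_report(confusion4(t, p)))
        agg = cv_report(reports)
        assert agg.average_f1 == pytest.approx(np.mean([r.average_f1 for r in reports]))
        for c in CLASSES:
            assert agg.per_class[c]["f1"] == pytest.approx(
                np.mean([r.per_class[c]["f1"] for r in reports]))
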