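"""Confusion matrices and F1 scoring for the four rhythm classes.

The 4×4 confusion matrix (rows = predicted, columns = ground truth,
order [AF, Normal, Noisy, Other]) is collapsed one-vs-rest into a 2×2
matrix per target class, from which precision = TP/(TP+FP), recall =
TP/(TP+FN), binary accuracy = (TP+TN)/total and F1 (harmonic mean of
precision and recall) follow, all expressed in percent.  The headline
number is the unweighted average of the four per-class F1 scores; a
three-class average excluding Noisy is also reported.  Fold-level
reports aggregate to per-class means and the standard deviation of the
fold average-F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix4",
    "BinaryConfusion",
    "MetricsReport",
    "confusion4",
    "collapse",
    "precision",
    "recall",
    "accuracy",
    "f1",
    "average_f1",
    "metrics_report",
    "cv_report",
]


@dataclass
class ConfusionMatrix4:
    """4×4 counts; rows = predicted class, columns = ground-truth class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def micro_accuracy(self) -> float:
        """trace/total in percent (100 if empty)."""
        return 100.0 * float(np.trace(self.counts)) / self.total if self.total else 100.0


@dataclass(frozen=True)
class BinaryConfusion:
    """One-vs-rest collapse for a target class (counts)."""

    tp: int  # target predicted as target
    fp: int  # non-target predicted as target
    fn: int  # target predicted as non-target
    tn: int  # non-target predicted as non-target

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    per_class: dict  # class -> {"precision","recall","accuracy","f1"} in percent
    accuracy: float  # micro accuracy (percent)
    average_f1: float
    average_f1_three_class: float  # over AF, Normal, Other
    sigma: float = 0.0  # std of fold-level average F1 (CV aggregation only)
    per_class_sigma: dict = field(default_factory=dict)


def confusion4(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix4:
    """Tally predictions against ground truth."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    index = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix4(counts)


def collapse(cm: ConfusionMatrix4, target: str) -> BinaryConfusion:
    """One-vs-rest 2×2 collapse; the four cells conserve the 4×4 total."""
    if target not in CLASSES:
        raise ValueError(f"unknown class {target!r}")
    i = CLASSES.index(target)
    c = cm.counts
    tp = int(c[i, i])
    fp = int(c[i, :].sum() - c[i, i])
    fn = int(c[:, i].sum() - c[i, i])
    tn = int(c.sum() - tp - fp - fn)
    return BinaryConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return 100.0 * num / den


def precision(bc: BinaryConfusion) -> float:
    """TP/(TP+FP) in percent; 0 (with a warning) when no positive predictions."""
    return _ratio(bc.tp, bc.tp + bc.fp, "precision")


def recall(bc: BinaryConfusion) -> float:
    """TP/(TP+FN) in percent; 0 (with a warning) when the class is absent."""
    return _ratio(bc.tp, bc.tp + bc.fn, "recall")


def accuracy(bc: BinaryConfusion) -> float:
    """(TP+TN)/total in percent."""
    return _ratio(bc.tp + bc.tn, bc.total, "accuracy")


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct < 0 or recall_pct < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def average_f1(f1_by_class: dict) -> float:
    """Unweighted mean of the four per-class F1 values."""
    return float(np.mean([f1_by_class[c] for c in CLASSES]))


def metrics_report(cm: ConfusionMatrix4) -> MetricsReport:
    """Full per-class and averaged metrics from one confusion matrix."""
    per_class = {}
    for c in CLASSES:
        bc = collapse(cm, c)
        p, r = precision(bc), recall(bc)
        per_class[c] = {"precision": p, "recall": r, "accuracy": accuracy(bc),
                        "f1": f1(p, r)}
    f1s = {c: per_class[c]["f1"] for c in CLASSES}
    three = float(np.mean([f1s[c] for c in ("AF", "Normal", "Other")]))
    return MetricsReport(per_class=per_class, accuracy=cm.micro_accuracy(),
                         average_f1=average_f1(f1s), average_f1_three_class=three)


def cv_report(per_fold: Sequence[MetricsReport], ddof: int = 0) -> MetricsReport:
    """Aggregate fold reports: per-class/average means and fold-σ.

    ``sigma`` is the standard deviation of the fold-level average F1
    (population by default; ``ddof=1`` for the sample convention).
    """
    if len(per_fold) == 0:
        raise ValueError("need at least one fold")
    per_class = {}
    per_class_sigma = {}
    for c in CLASSES:
        per_class[c] = {m: float(np.mean([r.per_class[c][m] for r in per_fold]))
                        for m in ("precision", "recall", "accuracy", "f1")}
        per_class_sigma[c] = float(np.std([r.per_class[c]["f1"] for r in per_fold], ddof=ddof))
    avg = [r.average_f1 for r in per_fold]
    return MetricsReport(
        per_class=per_class,
        accuracy=float(np.mean([r.accuracy for r in per_fold])),
        average_f1=float(np.mean(avg)),
        average_f1_three_class=float(np.mean([r.average_f1_three_class for r in per_fold])),
        sigma=float(np.std(avg, ddof=ddof)),
        per_class_sigma=per_class_sigma,
    )
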