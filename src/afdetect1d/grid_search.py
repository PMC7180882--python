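"""Exhaustive hyperparameter grid search with stratified-CV scoring.

The search space is the cartesian product of layer depth N ∈ {8, 9, 10,
11}, kernel size Ks ∈ {3, 5, 7}, batch size Bs ∈ {30, 50, 70, 90, 110}
and learning rate Lr ∈ {0.00005, 0.0001, 0.0005, 0.001, 0.005} — 300
architectures.  Some corners are infeasible (11 layers with kernel > 3
run out of samples before the last convolution); those are listed as
N/A, not dropped.  Each feasible point is scored by stratified K-fold
cross-validation on the segment dataset, and the best point maximizes
the fold-mean average F1 (ties break toward fewer parameters, then the
lower learning rate).  Parameter counts per point always come from the
analytic calculator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .architecture import build_network, check_feasible, count_trainable, make_variant
from .evaluation import confusion4, cv_report, metrics_report, MetricsReport
from .length_norm import SegmentDataset
from .training import TrainConfig, fit, predict, stratified_kfold

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID_SETS",
    "GridPoint",
    "GridPointResult",
    "GridResult",
    "make_grid",
    "run_grid",
    "refine_batch_search",
]

DEFAULT_GRID_SETS = {
    "n_conv_layers": (8, 9, 10, 11),
    "kernel": (3, 5, 7),
    "batch_size": (30, 50, 70, 90, 110),
    "learning_rate": (0.00005, 0.0001, 0.0005, 0.001, 0.005),
}


@dataclass(frozen=True)
class GridPoint:
    n_conv_layers: int
    kernel: int
    batch_size: int
    learning_rate: float


@dataclass
class GridPointResult:
    point: GridPoint
    feasible: bool
    mean_f1: Optional[float] = None   # fold-mean average F1 (percent); None if N/A
    sigma: Optional[float] = None
    n_params: Optional[int] = None

    @property
    def is_na(self) -> bool:
        return not self.feasible


@dataclass
class GridResult:
    entries: list[GridPointResult]

    @property
    def best(self) -> GridPointResult:
        feasible = [e for e in self.entries if e.feasible and e.mean_f1 is not None]
        if not feasible:
            raise ValueError("no feasible evaluated grid points")
        # argmax mean F1; ties -> fewer parameters, then lower learning rate
        return max(feasible, key=lambda e: (e.mean_f1, -e.n_params,
                                            -e.point.learning_rate))

    def to_rows(self) -> list[dict]:
        rows = []
        for e in self.entries:
            rows.append({
                "layers": e.point.n_conv_layers, "kernel": e.point.kernel,
                "batch_size": e.point.batch_size, "learning_rate": e.point.learning_rate,
                "mean_f1": e.mean_f1 if e.feasible else "N/A",
                "sigma": e.sigma if e.feasible else "N/A",
                "n_params": e.n_params if e.feasible else "N/A",
                "feasible": e.feasible,
            })
        return rows


def make_grid(n_conv_layers: Sequence[int] = DEFAULT_GRID_SETS["n_conv_layers"],
              kernel: Sequence[int] = DEFAULT_GRID_SETS["kernel"],
              batch_size: Sequence[int] = DEFAULT_GRID_SETS["batch_size"],
              learning_rate: Sequence[float] = DEFAULT_GRID_SETS["learning_rate"],
              ) -> list[GridPoint]:
    """Cartesian product of the four hyperparameter sets, lexicographic order."""
    sets = (n_conv_layers, kernel, batch_size, learning_rate)
    if any(len(s) == 0 for s in sets):
        raise ValueError("all hyperparameter sets must be non-empty")
    return [GridPoint(*combo) for combo in itertools.product(*sets)]


def _evaluate_point(point: GridPoint, segments: SegmentDataset, k: int, seed: int,
                    epochs: int, variant: str) -> tuple[float, float, int]:
    """Stratified k-fold CV score of one grid point."""
    spec = make_variant(variant, kernel=point.kernel,
                        n_conv_layers=point.n_conv_layers,
                        input_len=segments.threshold_samples)
    n_params = count_trainable(spec)
    _, labels = segments.to_arrays()
    split = stratified_kfold(labels, k, seed=seed)
    reports: list[MetricsReport] = []
    for fold in range(k):
        train_idx, test_idx = split.train_test_indices(fold)
        train_ds = SegmentDataset([segments.segments[i] for i in train_idx],
                                  segments.threshold_samples)
        test_ds = SegmentDataset([segments.segments[i] for i in test_idx],
                                 segments.threshold_samples)
        model = build_network(spec, seed=seed + fold)
        if epochs > 0:
            cfg = TrainConfig(learning_rate=point.learning_rate,
                              batch_size=point.batch_size, epochs=epochs,
                              seed=seed + fold)
            fit(model, train_ds, cfg)
        _, pred = predict(model, test_ds)
        reports.append(metrics_report(confusion4(test_ds.to_arrays()[1], pred)))
    agg = cv_report(reports)
    return agg.average_f1, agg.sigma, n_params


def run_grid(grid: Sequence[GridPoint], segments: SegmentDataset, k: int = 5,
             seed: int = 0, epochs: int = 50, variant: str = "Proposed-2",
             epochs_per_point: Optional[dict] = None,
             subsample: Optional[int] = None) -> GridResult:
    """Evaluate every grid point; infeasible points are reported as N/A.

    ``epochs_per_point`` overrides the epoch budget for specific points;
    ``subsample`` caps the number of segments used (stratified-agnostic
    deterministic head), for smoke-testing large grids.
    """
    if subsample is not None and subsample < len(segments):
        segments = SegmentDataset(segments.segments[:subsample], segments.threshold_samples)
    entries: list[GridPointResult] = []
    for point in grid:
        if not check_feasible(point.n_conv_layers, point.kernel,
                              segments.threshold_samples):
            logger.info("grid point %s infeasible (N/A)", point)
            entries.append(GridPointResult(point, feasible=False))
            continue
        ep = epochs if epochs_per_point is None else epochs_per_point.get(point, epochs)
        mean_f1, sigma, n_params = _evaluate_point(point, segments, k, seed, ep, variant)
        logger.info("grid point %s: mean F1 %.1f (σ %.1f), %d params",
                    point, mean_f1, sigma, n_params)
        entries.append(GridPointResult(point, True, mean_f1, sigma, n_params))
    result = GridResult(entries)
    result.best  # raises if everything was infeasible
    return result


def refine_batch_search(result: GridResult, base: GridPoint,
                        extra_batch_sizes: Sequence[int], segments: SegmentDataset,
                        k: int = 5, seed: int = 0, epochs: int = 50,
                        variant: str = "Proposed-2") -> GridResult:
    """Re-evaluate a base configuration at extra batch sizes and merge.

    Batch sizes already present for the base configuration are skipped
    (set semantics); returns a new GridResult sharing prior entries.
    """
    seen = {e.point for e in result.entries}
    entries = list(result.entries)
    for bs in dict.fromkeys(extra_batch_sizes):  # dedupe, keep order
        point = replace(base, batch_size=bs)
        if point in seen:
            continue
        if not check_feasible(point.n_conv_layers, point.kernel,
                              segments.threshold_samples):
            entries.append(GridPointResult(point, feasible=False))
            continue
        mean_f1, sigma, n_params = _evaluate_point(point, segments, k, seed, epochs, variant)
        entries.append(GridPointResult(point, True, mean_f1, sigma, n_params))
        seen.add(point)
    return GridResult(entries)
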