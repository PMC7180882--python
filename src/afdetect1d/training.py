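"""Training: one-hot encoding, cross-entropy, Adam fitting, stratified K-fold CV.

The classifier is trained by minimizing categorical cross-entropy — the
per-sample sum of ``-x_i log y_i`` over the four classes, averaged over
the minibatch — with the Adam optimizer (bias-corrected moment
estimates, fixed learning rate).  Dropout is active only during
training; prediction is deterministic for a fixed trained model.

Cross-validation uses stratified folds so that each fold preserves the
heavily imbalanced class proportions of the corpus.  Folds are drawn at
segment level by default, matching how the reference corpus was
evaluated; a record-grouped mode keeps sibling segments of one source
recording in the same fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .io_formats import CLASSES
from .length_norm import SegmentDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainingHistory",
    "DivergenceError",
    "one_hot",
    "encode_labels",
    "cross_entropy",
    "stratified_kfold",
    "fit",
    "predict",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4   # best-model setting; Adam's base default is 1e-3
    batch_size: int = 30
    epochs: int = 50
    dropout_rate: float = 0.5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0
    early_stopping_patience: Optional[int] = None  # on validation loss, if val data given
    stop_at_train_accuracy: Optional[float] = None  # stop once training accuracy reaches this

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # per-segment fold index in [0, k)
    seed: int

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(len(self.assignments))
        test = idx[self.assignments == fold]
        return idx[self.assignments != fold], test


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


def one_hot(label: str) -> np.ndarray:
    """4-vector with a single 1 at the class position ([AF, Normal, Noisy, Other])."""
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    v = np.zeros(len(CLASSES), dtype=np.float32)
    v[CLASSES.index(label)] = 1.0
    return v


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """(n, 4) one-hot matrix for a label sequence."""
    return np.stack([one_hot(lab) for lab in labels]) if len(labels) else np.zeros((0, 4), np.float32)


def cross_entropy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean over the batch of ``-sum_i x_i log y_i`` (probabilities clipped at 1e-12)."""
    truth = np.atleast_2d(truth)
    predicted = np.atleast_2d(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {predicted.shape}")
    return float(-(truth * np.log(np.clip(predicted, 1e-12, None))).sum(axis=1).mean())


def stratified_kfold(labels: Sequence[str], k: int, seed: int = 0) -> FoldSplit:
    """Stratified fold assignment: every fold mirrors the class proportions.

    Fold sizes differ by at most 1 and per-class counts per fold are
    within 1 of exact proportionality; deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"classes {list(small)} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def _accuracy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())


def fit(model: nn.Network, train_segments: SegmentDataset, config: TrainConfig,
        val_segments: Optional[SegmentDataset] = None) -> TrainingHistory:
    """Train in place with Adam on shuffled minibatches; returns the history.

    Early stopping (optional) watches validation loss with the configured
    patience and restores nothing — the model keeps its last weights.
    """
    x, labels = train_segments.to_arrays()
    if x.shape[1] != model.input_len:
        raise ValueError(f"segment length {x.shape[1]} != model input {model.input_len}")
    y = encode_labels(labels)
    opt = nn.Adam(model, lr=config.learning_rate, beta1=config.adam_beta1,
                  beta2=config.adam_beta2, eps=config.adam_epsilon)
    rng = np.random.default_rng(config.seed)
    hist = TrainingHistory()
    best_val = np.inf
    stale = 0
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, accs, weights = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(_accuracy(probs, y[idx]))
            weights.append(len(idx))
        hist.loss.append(float(np.average(losses, weights=weights)))
        hist.accuracy.append(float(np.average(accs, weights=weights)))
        msg = f"epoch {epoch + 1}: loss={hist.loss[-1]:.4f} acc={hist.accuracy[-1]:.3f}"
        if val_segments is not None:
            probs, _ = predict(model, val_segments)
            yv = encode_labels(val_segments.to_arrays()[1])
            vl = cross_entropy(yv, probs)
            hist.val_loss.append(vl)
            hist.val_accuracy.append(_accuracy(probs, yv))
            msg += f" val_loss={vl:.4f} val_acc={hist.val_accuracy[-1]:.3f}"
            if config.early_stopping_patience is not None:
                if vl < best_val - 1e-6:
                    best_val, stale = vl, 0
                else:
                    stale += 1
                    if stale > config.early_stopping_patience:
                        logger.info("early stop at epoch %d", epoch + 1)
                        break
        logger.info(msg)
        if (config.stop_at_train_accuracy is not None
                and hist.accuracy[-1] >= config.stop_at_train_accuracy):
            logger.info("training accuracy target reached at epoch %d", epoch + 1)
            break
    return hist


def predict(model: nn.Network, segments: SegmentDataset,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment class probabilities and argmax labels (ties → lowest index)."""
    x, _ = segments.to_arrays()
    if x.shape[0] and x.shape[1] != model.input_len:
        raise ValueError(f"segment length {x.shape[1]} != model input {model.input_len}")
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        chunks.append(nn.softmax(logits))
    probs = np.concatenate(chunks) if chunks else np.zeros((0, len(CLASSES)))
    labels = np.array([CLASSES[i] for i in probs.argmax(axis=1)], dtype=object)
    return probs, labels
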