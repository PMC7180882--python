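"""Declarative 1D-CNN architecture specs and the analytic shape/parameter calculator.

The canonical atrial-fibrillation classifier is a stack of convolutional
blocks (valid conv, stride 1 + ReLU, optionally batch-normalized, followed
by size-2 pooling) whose filter count starts at 32 and doubles every two
blocks, topped by dense layers of 128 and 32 units and a 4-way softmax.
Two families are distinguished by pooling type: ``Proposed-1`` (max
pooling) and ``Proposed-2`` (average pooling), plus ablation variants that
move batch normalization or add a pooling layer before the flatten.

``compute_layer_summaries`` derives every layer's output shape and
parameter count analytically; ``build_network`` realizes the same spec as
a trainable :class:`~afdetect1d.nn.Network`, and the two parameter counts
must agree — the calculator is the oracle for the built model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np

from . import nn

__all__ = [
    "BlockSpec",
    "ArchitectureSpec",
    "LayerSummary",
    "FeasibilityError",
    "VARIANT_NAMES",
    "make_variant",
    "compute_layer_summaries",
    "count_trainable",
    "count_total",
    "check_feasible",
    "build_network",
    "describe",
]

PoolKind = Literal["max", "average", "none"]

VARIANT_NAMES = (
    "Proposed-1",
    "Proposed-2",
    "All-BN",
    "No-BN",
    "Maxpooling",
    "Max-Average",
    "Extra-Average",
)


class FeasibilityError(ValueError):
    """A layer would receive fewer samples than its kernel needs."""


@dataclass(frozen=True)
class BlockSpec:
    """One convolutional block: conv + ReLU, optional BN, optional pool, optional dropout."""

    filters: int
    kernel: int
    has_bn: bool = False
    pool: PoolKind = "max"
    dropout_after: Optional[float] = None

    def __post_init__(self) -> None:
        if self.filters <= 0:
            raise ValueError("filters must be positive")
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.dropout_after is not None and not 0.0 <= self.dropout_after < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    blocks: tuple[BlockSpec, ...]
    dense_units: tuple[int, ...] = (128, 32)
    n_classes: int = 4
    pre_flatten_pool: PoolKind = "none"
    input_len: int = 9000
    dense_dropout: Optional[float] = 0.5  # after the first dense layer
    name: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ArchitectureSpec":
        blocks = tuple(BlockSpec(**b) for b in d["blocks"])
        rest = {k: v for k, v in d.items() if k != "blocks"}
        for key in ("dense_units",):
            if key in rest:
                rest[key] = tuple(rest[key])
        return ArchitectureSpec(blocks=blocks, **rest)


@dataclass(frozen=True)
class LayerSummary:
    layer_kind: Literal["conv", "bn", "pool", "dropout", "flatten", "dense"]
    output_len: int
    channels: int
    params_total: int
    params_trainable: int


def _dropout_positions(n_blocks: int) -> set[int]:
    """1-based block indices after which dropout 0.5 is inserted.

    For the canonical 10-block stack these are blocks 6, 8 and 9; for
    other depths the same relative positions (n-4, n-2, n-1) are used.
    """
    return {n_blocks - 4, n_blocks - 2, n_blocks - 1} & set(range(1, n_blocks + 1))


def make_variant(name: str, kernel: int = 5, n_conv_layers: int = 10,
                 input_len: int = 9000) -> ArchitectureSpec:
    """Build the canonical spec for a named variant.

    Filter counts start at 32 and double every two blocks; every block but
    the last is pooled; batch normalization sits in block 1 only (All-BN:
    every block; No-BN: none); dropout 0.5 follows blocks 6, 8, 9 of the
    10-block stack and the first dense layer.
    """
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    if not 8 <= n_conv_layers <= 11:
        raise ValueError("n_conv_layers must be in 8..11")

    block_pool: PoolKind = "average" if name in ("Proposed-2", "Extra-Average") else "max"
    drop_at = _dropout_positions(n_conv_layers)
    blocks = []
    for i in range(1, n_conv_layers + 1):
        if name == "All-BN":
            has_bn = True
        elif name == "No-BN":
            has_bn = False
        else:
            has_bn = i == 1
        blocks.append(BlockSpec(
            filters=32 * 2 ** ((i - 1) // 2),
            kernel=kernel,
            has_bn=has_bn,
            pool=block_pool if i < n_conv_layers else "none",
            dropout_after=0.5 if i in drop_at else None,
        ))
    pre_flatten: PoolKind = {"Maxpooling": "max", "Max-Average": "average",
                             "Extra-Average": "average"}.get(name, "none")
    return ArchitectureSpec(blocks=tuple(blocks), pre_flatten_pool=pre_flatten,
                            input_len=input_len, name=name)


def compute_layer_summaries(spec: ArchitectureSpec) -> list[LayerSummary]:
    """Analytic per-layer output shapes and parameter counts.

    Valid convolution: ``out = in - kernel + 1``; pooling halves with
    floor; conv params ``k*c_in*f + f``; BN carries ``4c`` parameters of
    which the ``2c`` scale/shift are trainable; dense ``in*out + out``.
    """
    out: list[LayerSummary] = []
    length = spec.input_len
    channels = 1
    for i, blk in enumerate(spec.blocks, start=1):
        if length < blk.kernel:
            raise FeasibilityError(
                f"conv block {i}: input length {length} < kernel {blk.kernel}")
        new_len = length - blk.kernel + 1
        p = blk.kernel * channels * blk.filters + blk.filters
        out.append(LayerSummary("conv", new_len, blk.filters, p, p))
        length, channels = new_len, blk.filters
        if blk.has_bn:
            out.append(LayerSummary("bn", length, channels, 4 * channels, 2 * channels))
        if blk.pool != "none":
            length //= 2
            if length < 1:
                raise FeasibilityError(f"pool after block {i}: output length 0")
            out.append(LayerSummary("pool", length, channels, 0, 0))
        if blk.dropout_after is not None:
            out.append(LayerSummary("dropout", length, channels, 0, 0))
    if spec.pre_flatten_pool != "none":
        length //= 2
        if length < 1:
            raise FeasibilityError("pre-flatten pool: output length 0")
        out.append(LayerSummary("pool", length, channels, 0, 0))
    units = length * channels
    out.append(LayerSummary("flatten", units, 1, 0, 0))
    for j, du in enumerate(spec.dense_units):
        p = units * du + du
        out.append(LayerSummary("dense", du, 1, p, p))
        units = du
        if j == 0 and spec.dense_dropout is not None:
            out.append(LayerSummary("dropout", units, 1, 0, 0))
    p = units * spec.n_classes + spec.n_classes
    out.append(LayerSummary("dense", spec.n_classes, 1, p, p))
    return out


def count_trainable(spec: ArchitectureSpec) -> int:
    """Total trainable parameters (BN running statistics excluded)."""
    return sum(s.params_trainable for s in compute_layer_summaries(spec))


def count_total(spec: ArchitectureSpec) -> int:
    """Total parameters including the non-trainable BN statistics."""
    return sum(s.params_total for s in compute_layer_summaries(spec))


def check_feasible(n_conv_layers: int, kernel: int, input_len: int = 9000) -> bool:
    """True iff the canonical stack at this depth/kernel fits the input length."""
    if n_conv_layers <= 0 or kernel <= 0 or input_len <= 0:
        raise ValueError("arguments must be positive")
    try:
        spec = make_variant("Proposed-1", kernel=kernel,
                            n_conv_layers=n_conv_layers, input_len=input_len)
        compute_layer_summaries(spec)
    except FeasibilityError:
        return False
    return True


def build_network(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Realize a spec as a trainable network with seeded initialization.

    The final dense layer emits 4-class logits; probabilities come from
    the softmax applied by the loss/prediction routines.
    """
    compute_layer_summaries(spec)  # raises FeasibilityError early
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length = spec.input_len
    channels = 1
    for blk in spec.blocks:
        layers.append(nn.Conv1D(blk.kernel, channels, blk.filters, rng))
        layers.append(nn.ReLU())
        length = length - blk.kernel + 1
        channels = blk.filters
        if blk.has_bn:
            layers.append(nn.BatchNorm(channels))
        if blk.pool == "max":
            layers.append(nn.MaxPool())
            length //= 2
        elif blk.pool == "average":
            layers.append(nn.AvgPool())
            length //= 2
        if blk.dropout_after is not None:
            layers.append(nn.Dropout(blk.dropout_after, rng))
    if spec.pre_flatten_pool == "max":
        layers.append(nn.MaxPool())
        length //= 2
    elif spec.pre_flatten_pool == "average":
        layers.append(nn.AvgPool())
        length //= 2
    layers.append(nn.Flatten())
    units = length * channels
    for j, du in enumerate(spec.dense_units):
        layers.append(nn.Dense(units, du, rng))
        layers.append(nn.ReLU())
        units = du
        if j == 0 and spec.dense_dropout is not None:
            layers.append(nn.Dropout(spec.dense_dropout, rng))
    layers.append(nn.Dense(units, spec.n_classes, rng))
    return nn.Network(layers, spec.input_len)


def describe(spec: ArchitectureSpec) -> str:
    """Human-readable per-layer summary table with totals."""
    rows = compute_layer_summaries(spec)
    lines = [f"{'Layer':<10}{'Output shape':>16}{'Params':>12}{'Trainable':>12}"]
    for s in rows:
        shape = f"{s.output_len} x {s.channels}" if s.channels > 1 else f"{s.output_len}"
        lines.append(f"{s.layer_kind:<10}{shape:>16}{s.params_total:>12,}{s.params_trainable:>12,}")
    lines.append(f"Total parameters: {sum(s.params_total for s in rows):,}")
    lines.append(f"Trainable parameters: {sum(s.params_trainable for s in rows):,}")
    return "\n".join(lines)
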