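"""Shared fixtures: tiny separable signal sets and a small synthetic corpus."""

import numpy as np
import pytest

from afdetect1d import (
    CLASSES,
    ArchitectureSpec,
    BlockSpec,
    Segment,
    SegmentDataset,
    SyntheticConfig,
    gen_dataset,
)

# frequencies (Hz) that make the four classes trivially separable by a CNN
_CLASS_FREQ = {"AF": 2.0, "Normal": 5.0, "Noisy": 11.0, "Other": 23.0}


def make_sine_dataset(n_per_class: int, length: int = 300, fs: float = 300.0,
                      seed: int = 0) -> SegmentDataset:
    """Fixed-length segments of class-coded sinusoids plus light noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs
    segs = []
    i = 0
    for label in CLASSES:
        f = _CLASS_FREQ[label]
        for _ in range(n_per_class):
            i += 1
            x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x = x + rng.normal(0, 0.05, length)
            segs.append(Segment(x.astype(np.float32), label, f"T{i:04d}", 0))
    return SegmentDataset(segs, length)


def small_spec(input_len: int = 300) -> ArchitectureSpec:
    """A 2-block network small enough for second-scale training tests."""
    return ArchitectureSpec(
        blocks=(BlockSpec(8, 5, has_bn=True, pool="max"),
                BlockSpec(16, 5, pool="average")),
        dense_units=(16,), input_len=input_len, dense_dropout=None)


@pytest.fixture(scope="session")
def sine_dataset() -> SegmentDataset:
    return make_sine_dataset(n_per_class=13, seed=3)


@pytest.fixture(scope="session")
def small_corpus():
    """A 24-recording synthetic ECG corpus with mixed durations."""
    cfg = SyntheticConfig(n_per_class={c: 6 for c in CLASSES}, seed=11)
    return gen_dataset(cfg)
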