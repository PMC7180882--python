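"""Histogram-based length normalization of variable-length ECG recordings.

Recordings in the target corpus run from 9 to 61 s at 300 Hz, but the
classifier needs a fixed input size.  The threshold is chosen
automatically as the modal bin of the duration histogram (30 s → 9000
samples on the reference corpus).  Each recording is then normalized:

* longer than the threshold — chopped into threshold-sized windows with
  50% overlap, plus an end-anchored window whenever the stride grid
  leaves an uncovered tail (an 18,600-sample record yields 4 windows);
* exactly the threshold — preserved unchanged;
* shorter — periodically tiled (self-concatenated) and truncated to the
  threshold.

All segments inherit their source recording's label, so normalization
also augments the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import CLASSES, Recording

__all__ = [
    "LengthNormConfig",
    "Segment",
    "SegmentDataset",
    "TILED",
    "compute_length_threshold",
    "segment_long",
    "tile_short",
    "normalize_dataset",
]

#: start_index marker for segments produced by tiling a short recording
TILED = -1


@dataclass(frozen=True)
class LengthNormConfig:
    bin_width_s: float = 1.0
    overlap_fraction: float = 0.5
    threshold_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in (0, 1)")


@dataclass
class Segment:
    samples: np.ndarray
    label: str
    source_id: str
    start_index: int  # sample offset in source, or TILED


@dataclass
class SegmentDataset:
    segments: list[Segment]
    threshold_samples: int
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            counts = {c: 0 for c in CLASSES}
            for s in self.segments:
                counts[s.label] += 1
            self.class_counts = counts
        for s in self.segments:
            if len(s.samples) != self.threshold_samples:
                raise ValueError("all segments must have length threshold_samples")
        if sum(self.class_counts.values()) != len(self.segments):
            raise ValueError("class_counts must sum to the number of segments")

    def __len__(self) -> int:
        return len(self.segments)

    def to_arrays(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """(n, threshold) sample matrix and the parallel label array."""
        if not self.segments:
            return (np.zeros((0, self.threshold_samples), dtype=dtype),
                    np.zeros(0, dtype=object))
        x = np.stack([s.samples for s in self.segments]).astype(dtype)
        y = np.array([s.label for s in self.segments], dtype=object)
        return x, y


def compute_length_threshold(lengths: Sequence[int], fs: float,
                             config: LengthNormConfig = LengthNormConfig()) -> int:
    """Threshold in samples from the modal bin of the duration histogram.

    Durations are binned at ``bin_width_s`` resolution; the threshold is
    the left edge of the most populated bin converted to samples.  Ties
    break toward the smaller duration.
    """
    if len(lengths) == 0:
        raise ValueError("lengths must be non-empty")
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if config.threshold_samples is not None:
        return int(config.threshold_samples)
    bins = np.floor(lengths / fs / config.bin_width_s).astype(np.int64)
    idx, counts = np.unique(bins, return_counts=True)
    modal = idx[np.argmax(counts)]  # np.argmax takes the first max: smallest duration
    threshold = int(round(modal * config.bin_width_s * fs))
    if threshold < 1:
        raise ValueError("modal duration bin is below one sample; "
                         "use an explicit threshold_samples override")
    return threshold


def segment_long(samples: np.ndarray, threshold: int,
                 overlap_fraction: float = 0.5) -> list[np.ndarray]:
    """Chop a long recording into overlapping threshold-sized windows.

    Windows start on a stride grid of ``threshold * (1 - overlap)``; if
    the last grid window stops short of the end, one extra window
    anchored at ``len - threshold`` is appended so every sample is
    covered.  Returns the windows with their start offsets attached via
    ``window.start`` being implicit in order; use :func:`window_starts`
    for offsets.
    """
    starts = window_starts(len(samples), threshold, overlap_fraction)
    return [samples[s:s + threshold] for s in starts]


def window_starts(length: int, threshold: int, overlap_fraction: float = 0.5) -> list[int]:
    """Start offsets of the overlapping windows for a long recording."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not 0.0 < overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in (0, 1)")
    if length <= threshold:
        raise ValueError("segment_long requires length > threshold")
    # adjacent grid windows share exactly floor(threshold * overlap) samples
    stride = max(1, threshold - int(threshold * overlap_fraction))
    starts = list(range(0, length - threshold + 1, stride))
    if starts[-1] + threshold < length:
        starts.append(length - threshold)
    return starts


def tile_short(samples: np.ndarray, threshold: int) -> np.ndarray:
    """Periodically tile a short recording out to the threshold length.

    ``out[i] == samples[i % len(samples)]`` for every i < threshold.
    """
    n = len(samples)
    if n == 0:
        raise ValueError("samples must be non-empty")
    if not n < threshold:
        raise ValueError("tile_short requires length < threshold")
    reps = -(-threshold // n)  # ceil
    return np.tile(samples, reps)[:threshold]


def normalize_dataset(recordings: Sequence[Recording],
                      config: LengthNormConfig = LengthNormConfig()) -> SegmentDataset:
    """Apply threshold selection and the per-recording branch rule.

    Output order is deterministic: input order, then window order within
    a recording.
    """
    if len(recordings) == 0:
        raise ValueError("recordings must be non-empty")
    fs = recordings[0].fs
    for r in recordings:
        if r.fs != fs:
            raise ValueError("all recordings must share a sampling rate")
    threshold = compute_length_threshold([len(r.samples) for r in recordings], fs, config)
    segments: list[Segment] = []
    for r in recordings:
        n = len(r.samples)
        if n > threshold:
            for start in window_starts(n, threshold, config.overlap_fraction):
                segments.append(Segment(np.asarray(r.samples[start:start + threshold]),
                                        r.label, r.record_id, start))
        elif n == threshold:
            segments.append(Segment(np.asarray(r.samples), r.label, r.record_id, 0))
        else:
            segments.append(Segment(tile_short(np.asarray(r.samples), threshold),
                                    r.label, r.record_id, TILED))
    return SegmentDataset(segments, threshold)
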