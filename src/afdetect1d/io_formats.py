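"""Readers and writers for PhysioNet-2017-style ECG records and segment stores.

A record on disk is a MATLAB-v5 array file holding one integer sample
vector named ``val`` plus a two-line WFDB-style ``.hea`` header giving
the sampling rate, sample count and ADC gain (counts per millivolt).
Labels come from a two-column CSV mapping record IDs to the rhythm
symbols ``N`` (Normal), ``A`` (AF), ``O`` (Other) and ``~`` (Noisy).

Normalized segment datasets are persisted as a single HDF5 container:
one fixed-width sample matrix plus parallel label / provenance columns,
which round-trips losslessly and slices quickly for cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import scipy.io

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "SYMBOL_TO_CLASS",
    "CLASS_TO_SYMBOL",
    "Recording",
    "LabelTable",
    "read_label_table",
    "write_label_table",
    "read_recording",
    "read_header",
    "write_segment_store",
    "read_segment_store",
]

#: fixed class order used everywhere (one-hot, confusion matrices, reports)
CLASSES = ("AF", "Normal", "Noisy", "Other")

SYMBOL_TO_CLASS = {"N": "Normal", "A": "AF", "O": "Other", "~": "Noisy"}
CLASS_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CLASS.items()}

_CSV_HEADER = ("record_id", "symbol")


@dataclass
class Recording:
    """One variable-length single-lead ECG trace."""

    record_id: str
    samples: np.ndarray  # millivolts (or raw ADC counts if units="raw")
    fs: float
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class LabelTable:
    """Ordered record_id → class mapping."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for rid, label in self.entries.items():
            if label not in CLASSES:
                raise ValueError(f"invalid label {label!r} for record {rid}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, record_id: str) -> str:
        return self.entries[record_id]


def read_label_table(path: Union[str, Path]) -> LabelTable:
    """Parse a two-column ``record_id,symbol`` CSV into a LabelTable.

    A leading ``record_id,symbol`` header row is tolerated; unknown
    symbols raise with the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, header=None, names=["record_id", "symbol"],
                     dtype=str, skip_blank_lines=True)
    if len(df) and tuple(df.iloc[0]) == _CSV_HEADER:
        df = df.iloc[1:]
    entries: dict[str, str] = {}
    for i, row in df.iterrows():
        rid, sym = row["record_id"], row["symbol"]
        if sym not in SYMBOL_TO_CLASS:
            raise ValueError(f"unknown label symbol {sym!r} in row {i} ({rid})")
        if rid in entries:
            raise ValueError(f"duplicate record id {rid!r}")
        entries[rid] = SYMBOL_TO_CLASS[sym]
    return LabelTable(entries)


def write_label_table(table: LabelTable, path: Union[str, Path]) -> None:
    """Write the table back as a symbol CSV (with header row)."""
    with open(path, "w") as fh:
        fh.write(",".join(_CSV_HEADER) + "\n")
        for rid, label in table.entries.items():
            fh.write(f"{rid},{CLASS_TO_SYMBOL[label]}\n")


def read_header(header_path: Union[str, Path]) -> dict:
    """Parse the 2-line WFDB-style header: fs, sample count, gain, baseline.

    Line 1: ``name n_signals fs n_samples``; line 2 field 3 is the gain
    as ``gain(baseline)/mV`` with baseline optional (default 0).
    """
    lines = Path(header_path).read_text().strip().splitlines()
    rec = lines[0].split()
    n_samples = int(rec[3]) if len(rec) > 3 else None
    fs = float(rec[2])
    gain, baseline = 200.0, 0.0  # WFDB defaults
    if len(lines) > 1:
        gfield = lines[1].split()[2]
        gpart = gfield.split("/")[0]
        if "(" in gpart:
            gpart, bpart = gpart.split("(")
            baseline = float(bpart.rstrip(")"))
        gain = float(gpart)
    return {"fs": fs, "n_samples": n_samples, "gain": gain, "baseline": baseline}


def read_recording(data_path: Union[str, Path], header_path: Union[str, Path],
                   label: str, units: str = "mv", zscore: bool = False) -> Recording:
    """Read one record: MATLAB ``val`` vector + header gain → millivolts.

    ``units="raw"`` skips the gain conversion and returns ADC counts;
    ``zscore=True`` additionally standardizes the trace (off by default).
    """
    data_path, header_path = Path(data_path), Path(header_path)
    mat = scipy.io.loadmat(data_path)
    if "val" not in mat:
        raise ValueError(f"{data_path} has no 'val' array")
    raw = np.asarray(mat["val"]).squeeze()
    if raw.ndim != 1:
        raise ValueError(f"{data_path}: expected a single sample vector, got shape {raw.shape}")
    hdr = read_header(header_path)
    if hdr["n_samples"] is not None and hdr["n_samples"] != raw.size:
        raise ValueError(
            f"{data_path}: header declares {hdr['n_samples']} samples, file has {raw.size}")
    if units == "raw":
        samples = raw.astype(np.float64)
    elif units == "mv":
        samples = (raw.astype(np.float64) - hdr["baseline"]) / hdr["gain"]
    else:
        raise ValueError("units must be 'mv' or 'raw'")
    if zscore:
        sd = samples.std()
        samples = (samples - samples.mean()) / (sd if sd > 0 else 1.0)
    return Recording(record_id=data_path.stem, samples=samples, fs=hdr["fs"], label=label)


def write_segment_store(dataset, path: Union[str, Path]) -> None:
    """Persist a SegmentDataset to one HDF5 container (lossless)."""
    segs = dataset.segments
    lengths = {len(s.samples) for s in segs}
    if lengths and lengths != {dataset.threshold_samples}:
        raise ValueError("mixed segment lengths in dataset")
    with h5py.File(path, "w") as f:
        f.attrs["threshold_samples"] = dataset.threshold_samples
        if segs:
            x = np.stack([s.samples for s in segs])
        else:
            x = np.zeros((0, dataset.threshold_samples))
        f.create_dataset("samples", data=x)
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("labels", data=np.array([s.label for s in segs], dtype=object),
                         dtype=str_dt)
        f.create_dataset("source_ids", data=np.array([s.source_id for s in segs], dtype=object),
                         dtype=str_dt)
        f.create_dataset("start_indices", data=np.array([s.start_index for s in segs],
                                                        dtype=np.int64))


def read_segment_store(path: Union[str, Path]):
    """Load a SegmentDataset written by :func:`write_segment_store`."""
    from .length_norm import Segment, SegmentDataset

    with h5py.File(path, "r") as f:
        threshold = int(f.attrs["threshold_samples"])
        x = f["samples"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
        sources = [s.decode() if isinstance(s, bytes) else s for s in f["source_ids"][()]]
        starts = f["start_indices"][()]
    segments = [Segment(x[i], labels[i], sources[i], int(starts[i]))
                for i in range(x.shape[0])]
    return SegmentDataset(segments, threshold)
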