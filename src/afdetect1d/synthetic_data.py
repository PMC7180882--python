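"""Synthetic single-lead ECG generator for the four rhythm classes.

Produces labeled, variable-length, 300 Hz recordings carrying the
class-defining structure the detector relies on, so the whole pipeline is
testable without the reference corpus:

* **Normal** — regular R-R intervals (coefficient of variation ≈ 0.025),
  full P-QRS-T morphology;
* **AF** — gamma-distributed (highly irregular) R-R intervals, absent
  P waves, and an additive low-amplitude 4–8 Hz baseline oscillation;
* **Other** — regular but slower rhythm with widened QRS and inverted T;
* **Noisy** — attenuated beats buried in white noise plus drift at an
  SNR below 0 dB.

Each heartbeat is a sum of Gaussian bumps (P, Q, R, S, T) rather than a
biophysical model — enough to carry the discriminative structure, and
fast.  Durations follow the corpus shape: a point mass at 30 s (weight
``mode_weight``) mixed with uniform 9–61 s.  Everything is driven by a
single seed and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import scipy.io
import scipy.signal

from .io_formats import CLASSES, CLASS_TO_SYMBOL, LabelTable, Recording, _CSV_HEADER

__all__ = [
    "SyntheticConfig",
    "gen_recording",
    "gen_dataset",
    "write_fixture_tree",
    "rr_intervals",
    "rr_cv",
    "band_power",
]

# (offset s, width s, amplitude mV) of the Gaussian bumps of one beat
_P = (-0.16, 0.025, 0.15)
_Q = (-0.035, 0.012, -0.10)
_R = (0.0, 0.012, 1.00)
_S = (0.035, 0.015, -0.20)
_T = (0.22, 0.055, 0.30)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic corpus."""

    n_per_class: dict = field(default_factory=lambda: {c: 25 for c in CLASSES})
    fs: float = 300.0
    mode_weight: float = 0.7        # weight of the 30 s point mass
    mode_duration_s: float = 30.0
    duration_range_s: tuple = (9.0, 61.0)
    seed: int = 0
    # class morphology parameters
    normal_rr_s: float = 0.8
    normal_rr_jitter_s: float = 0.02
    af_rr_s: float = 0.7
    af_rr_gamma_shape: float = 9.0  # CV = 1/3, well above the 0.15 AF cut
    af_baseline_amp_mv: float = 0.08
    af_baseline_band_hz: tuple = (4.0, 8.0)
    other_rr_s: float = 1.05
    noise_mv: float = 0.01          # measurement noise on clean classes
    noisy_snr_factor: float = 1.5   # noise sd as multiple of signal RMS (SNR < 0 dB)

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if not (lo <= self.mode_duration_s <= hi):
            raise ValueError("mode duration must lie inside duration_range_s")
        if not 0.0 <= self.mode_weight <= 1.0:
            raise ValueError("mode_weight must be in [0, 1]")
        if any(v < 0 for v in self.n_per_class.values()):
            raise ValueError("class counts must be non-negative")


def _beats(t: np.ndarray, onsets: np.ndarray, bumps) -> np.ndarray:
    sig = np.zeros_like(t)
    for t0 in onsets:
        for off, width, amp in bumps:
            if amp == 0.0:
                continue
            sig += amp * np.exp(-0.5 * ((t - t0 - off) / width) ** 2)
    return sig


def _onsets(rng: np.random.Generator, duration: float, mean_rr: float,
            jitter: float = 0.0, gamma_shape: float = 0.0) -> np.ndarray:
    out = [rng.uniform(0.3, 0.3 + mean_rr)]
    while out[-1] < duration:
        if gamma_shape > 0:
            rr = rng.gamma(gamma_shape, mean_rr / gamma_shape)
        else:
            rr = mean_rr + rng.normal(0.0, jitter)
        out.append(out[-1] + max(0.25, rr))
    return np.array(out[:-1])


def gen_recording(label: str, duration: float, fs: float = 300.0,
                  seed: Union[int, np.random.Generator] = 0,
                  config: SyntheticConfig = SyntheticConfig(),
                  record_id: str = "S00000") -> Recording:
    """Generate one recording of the given class and duration (seconds)."""
    lo, hi = config.duration_range_s
    if not lo <= duration <= hi:
        raise ValueError(f"duration must be in [{lo}, {hi}] s")
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if label == "Normal":
        onsets = _onsets(rng, duration, config.normal_rr_s, jitter=config.normal_rr_jitter_s)
        sig = _beats(t, onsets, (_P, _Q, _R, _S, _T))
        sig += rng.normal(0.0, config.noise_mv, n)
    elif label == "AF":
        onsets = _onsets(rng, duration, config.af_rr_s, gamma_shape=config.af_rr_gamma_shape)
        sig = _beats(t, onsets, (_Q, _R, _S, _T))  # no P wave
        f_lo, f_hi = config.af_baseline_band_hz
        f = rng.uniform(f_lo, f_hi)
        sig += config.af_baseline_amp_mv * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        sig += rng.normal(0.0, config.noise_mv, n)
    elif label == "Other":
        onsets = _onsets(rng, duration, config.other_rr_s, jitter=config.normal_rr_jitter_s)
        wide_r = (_R[0], 0.030, 0.80)     # widened QRS
        inv_t = (_T[0], _T[1], -0.30)     # inverted T
        sig = _beats(t, onsets, (_P, _Q, wide_r, _S, inv_t))
        sig += rng.normal(0.0, config.noise_mv, n)
    else:  # Noisy
        onsets = _onsets(rng, duration, config.normal_rr_s, jitter=0.05)
        base = 0.5 * _beats(t, onsets, (_P, _Q, _R, _S, _T))
        rms = float(np.sqrt(np.mean(base ** 2)))
        sig = base + rng.normal(0.0, config.noisy_snr_factor * max(rms, 0.05), n)
        sig += 0.3 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))  # drift
    return Recording(record_id=record_id, samples=sig, fs=fs, label=label)


def gen_dataset(config: SyntheticConfig = SyntheticConfig()
                ) -> tuple[list[Recording], LabelTable]:
    """Generate a corpus honoring the per-class counts and duration mixture."""
    rng = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    entries: dict[str, str] = {}
    i = 0
    for label in CLASSES:
        for _ in range(int(config.n_per_class.get(label, 0))):
            i += 1
            rid = f"S{i:05d}"
            if rng.random() < config.mode_weight:
                duration = config.mode_duration_s
            else:
                duration = rng.uniform(*config.duration_range_s)
            rec = gen_recording(label, duration, config.fs, rng, config, record_id=rid)
            recordings.append(rec)
            entries[rid] = label
    return recordings, LabelTable(entries)


def write_fixture_tree(recordings: list[Recording], out_dir: Union[str, Path],
                       gain: float = 1000.0) -> Path:
    """Emit the on-disk layout the record reader ingests.

    Per record: a MATLAB-v5 file with an int16 ``val`` vector (quantized
    at ``gain`` counts/mV), a 2-line WFDB-style header, and a cumulative
    ``REFERENCE.csv`` label file (header row only when empty).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [",".join(_CSV_HEADER)]
    for rec in recordings:
        raw = np.clip(np.round(rec.samples * gain), -32768, 32767).astype(np.int16)
        scipy.io.savemat(out_dir / f"{rec.record_id}.mat", {"val": raw[None, :]})
        hea = (f"{rec.record_id} 1 {rec.fs:g} {raw.size}\n"
               f"{rec.record_id}.mat 16 {gain:g}/mV 16 0 {int(raw[0])} 0 0 ECG\n")
        (out_dir / f"{rec.record_id}.hea").write_text(hea)
        lines.append(f"{rec.record_id},{CLASS_TO_SYMBOL[rec.label]}")
    (out_dir / "REFERENCE.csv").write_text("\n".join(lines) + "\n")
    return out_dir / "REFERENCE.csv"


# ---------------------------------------------------------------------------
# simple hand-crafted features, used to verify class separability


def rr_intervals(samples: np.ndarray, fs: float) -> np.ndarray:
    """R-R intervals (seconds) from simple peak detection on the trace."""
    samples = np.asarray(samples, dtype=float)
    height = 0.5 * samples.max() if samples.max() > 0 else None
    peaks, _ = scipy.signal.find_peaks(samples, height=height, distance=int(0.25 * fs))
    return np.diff(peaks) / fs


def rr_cv(samples: np.ndarray, fs: float) -> float:
    """Coefficient of variation of the R-R intervals (0 if < 2 beats)."""
    rr = rr_intervals(samples, fs)
    if rr.size < 2 or rr.mean() == 0:
        return 0.0
    return float(rr.std() / rr.mean())


def band_power(samples: np.ndarray, fs: float, lo: float = 4.0, hi: float = 8.0) -> float:
    """Power in [lo, hi] Hz as a fraction of total power (Welch PSD)."""
    f, p = scipy.signal.welch(np.asarray(samples, dtype=float), fs=fs,
                              nperseg=min(len(samples), 2048))
    total = float(np.trapezoid(p, f))
    if total == 0:
        return 0.0
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[sel], f[sel]) / total)
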