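"""Length-threshold selection and the chop/preserve/tile branches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afdetect1d import (
    LengthNormConfig,
    Recording,
    compute_length_threshold,
    normalize_dataset,
    segment_long,
    tile_short,
    window_starts,
)
from afdetect1d.length_norm import TILED


class TestThreshold:
    def test_single_bin(self):
        assert compute_length_threshold([9000] * 5, fs=300) == 9000

    def test_modal_bin_of_mixed_durations(self):
        # 70% of records exactly 30 s, the rest spread uniformly over 9-61 s
        rng = np.random.default_rng(0)
        lengths = [9000] * 70 + [int(rng.uniform(9, 61) * 300) for _ in range(30)]
        assert compute_length_threshold(lengths, fs=300) == 9000

    def test_tie_breaks_to_smaller_duration(self):
        lengths = [3000, 3100, 9000, 9100]  # 10 s and 30 s bins, 2 records each
        assert compute_length_threshold(lengths, fs=300) == 3000

    def test_override_wins(self):
        cfg = LengthNormConfig(threshold_samples=1234)
        assert compute_length_threshold([9000] * 5, fs=300, config=cfg) == 1234

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_length_threshold([], fs=300)


class TestLongBranch:
    @pytest.mark.parametrize("length,expected_starts", [
        (18_600, [0, 4500, 9000, 9600]),  # the 61 s worked example: 4 windows
        (13_500, [0, 4500]),              # grid lands exactly on the end
        (9_001, [0, 1]),                  # 1-sample tail forces an end anchor
    ])
    def test_window_starts(self, length, expected_starts):
        assert window_starts(length, 9000, 0.5) == expected_starts

    def test_windows_have_threshold_length_and_cover_input(self):
        x = np.arange(18_600)
        wins = segment_long(x, 9000, 0.5)
        assert all(len(w) == 9000 for w in wins)
        covered = np.zeros(len(x), dtype=bool)
        for s, w in zip(window_starts(len(x), 9000), wins):
            np.testing.assert_array_equal(w, x[s:s + 9000])
            covered[s:s + 9000] = True
        assert covered.all()

    @given(st.integers(50, 400), st.integers(5, 49))
    @settings(max_examples=50, deadline=None)
    def test_coverage_and_overlap_property(self, length, threshold):
        starts = window_starts(length, threshold, 0.5)
        covered = np.zeros(length, dtype=bool)
        for s in starts:
            assert 0 <= s <= length - threshold
            covered[s:s + threshold] = True
        assert covered.all()
        # adjacent stride-grid windows share exactly floor(threshold/2) samples
        stride = threshold - threshold // 2
        grid = [s for i, s in enumerate(starts) if s == i * stride]
        for a, b in zip(grid, grid[1:]):
            assert a + threshold - b == threshold // 2
        assert len(starts) >= 1


class TestShortBranch:
    def test_exact_division_doubles(self):
        x = np.arange(4500)
        out = tile_short(x, 9000)
        np.testing.assert_array_equal(out, np.concatenate([x, x]))

    def test_truncated_copy(self):
        x = np.arange(4000)
        out = tile_short(x, 9000)
        np.testing.assert_array_equal(out, x[np.arange(9000) % 4000])

    @given(st.integers(1, 200), st.integers(2, 5))
    @settings(max_examples=50, deadline=None)
    def test_periodicity_property(self, n, factor):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        threshold = n * factor - rng.integers(0, n)
        if threshold <= n:
            threshold = n + 1
        out = tile_short(x, threshold)
        np.testing.assert_array_equal(out, x[np.arange(threshold) % n])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tile_short(np.array([]), 10)


class TestNormalizeDataset:
    def _rec(self, rid, n, label):
        rng = np.random.default_rng(hash(rid) % 2**31)
        return Recording(rid, rng.normal(size=n), 300.0, label)

    def test_exact_length_preserved(self):
        rec = self._rec("R1", 9000, "Normal")
        ds = normalize_dataset([rec], LengthNormConfig(threshold_samples=9000))
        assert len(ds) == 1
        np.testing.assert_array_equal(ds.segments[0].samples, rec.samples)
        assert ds.segments[0].start_index == 0

    def test_three_branch_fixture(self):
        recs = [self._rec("A", 18_600, "AF"),
                self._rec("B", 4000, "Normal"),
                self._rec("C", 9000, "Other")]
        ds = normalize_dataset(recs, LengthNormConfig(threshold_samples=9000))
        assert len(ds) == 6
        assert ds.class_counts == {"AF": 4, "Normal": 1, "Noisy": 0, "Other": 1}
        # label conservation and provenance
        for seg in ds.segments:
            src = next(r for r in recs if r.record_id == seg.source_id)
            assert seg.label == src.label
        assert [s.start_index for s in ds.segments if s.source_id == "B"] == [TILED]

    def test_deterministic_and_ordered(self):
        recs = [self._rec("A", 12_000, "AF"), self._rec("B", 9000, "Normal")]
        cfg = LengthNormConfig(threshold_samples=9000)
        d1, d2 = normalize_dataset(recs, cfg), normalize_dataset(recs, cfg)
        assert [s.source_id for s in d1.segments] == ["A", "A", "B"]
        for s1, s2 in zip(d1.segments, d2.segments):
            np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_mixed_sampling_rates_rejected(self):
        recs = [Recording("A", np.ones(100), 300.0, "AF"),
                Recording("B", np.ones(100), 250.0, "AF")]
        with pytest.raises(ValueError):
            normalize_dataset(recs)
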