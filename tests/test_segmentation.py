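"""Window enumeration, first-beat labeling, normalization, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecganoise.errors import ArgumentError, DegenerateInputError
from ecganoise.records import BeatAnnotation, ECGRecord
from ecganoise.segmentation import (WindowSpec, assign_label, minmax_normalize,
                                    slice_windows, split_halves,
                                    train_test_split)


def brute_force_starts(length, window, stride):
    return [s for s in range(0, length, stride) if s + window <= length]


class TestSliceWindows:
    def test_eleven_windows_example(self):
        rec = ECGRecord("r", 360.0, np.zeros(2884))
        specs = slice_windows(rec, 1024, 180)
        assert [s.start_index for s in specs] == list(range(0, 1801, 180))
        assert len(specs) == 11

    def test_boundary_exact_fit(self):
        rec = ECGRecord("r", 360.0, np.zeros(1024))
        assert len(slice_windows(rec, 1024, 180)) == 1

    def test_boundary_one_short(self):
        rec = ECGRecord("r", 360.0, np.zeros(1023))
        assert slice_windows(rec, 1024, 180) == []

    @settings(max_examples=200, deadline=None)
    @given(length=st.integers(min_value=0, max_value=5000),
           stride=st.sampled_from([1, 180, 512]))
    def test_count_matches_enumeration(self, length, stride):
        rec = ECGRecord("r", 360.0, np.zeros(length))
        specs = slice_windows(rec, 1024, stride) if length else []
        expected = brute_force_starts(length, 1024, stride)
        assert [s.start_index for s in specs] == expected

    def test_windows_over_leadoff_removed(self):
        mask = np.ones(2884, dtype=bool)
        mask[1000:1010] = False
        rec = ECGRecord("r", 360.0, np.zeros(2884), valid_mask=mask)
        specs = slice_windows(rec, 1024, 180)
        # a window [s, s+1024) survives iff it misses [1000, 1010)
        survivors = [s for s in range(0, 1801, 180)
                     if s + 1024 <= 1000 or s >= 1010]
        assert [s.start_index for s in specs] == survivors


class TestAssignLabel:
    @staticmethod
    def _anns(d):
        return [BeatAnnotation(i, c, c) for i, c in sorted(d.items())]

    def test_earliest_beat_wins(self):
        spec = WindowSpec("r", 0, 512)
        assert assign_label(spec, self._anns({100: "N", 300: "V"})) == "N"

    def test_empty_window_none(self):
        assert assign_label(WindowSpec("r", 0, 512), self._anns({600: "N"})) is None

    def test_half_open_boundary(self):
        spec = WindowSpec("r", 100, 512)
        assert assign_label(spec, self._anns({100 + 511: "V"})) == "V"
        assert assign_label(spec, self._anns({100 + 512: "V"})) is None
        assert assign_label(spec, self._anns({99: "V"})) is None
        assert assign_label(spec, self._anns({100: "A"})) == "A"

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_linear_scan_oracle(self, data):
        n_ann = data.draw(st.integers(0, 20))
        idx = sorted(data.draw(st.lists(st.integers(0, 4999),
                                        min_size=n_ann, max_size=n_ann)))
        classes = data.draw(st.lists(st.sampled_from("NBVAF"),
                                     min_size=n_ann, max_size=n_ann))
        anns = [BeatAnnotation(i, c, c) for i, c in zip(idx, classes)]
        start = data.draw(st.integers(0, 4500))
        spec = WindowSpec("r", start, 512)
        # oracle: first annotation by linear scan
        expected = None
        for a in anns:
            if start <= a.sample_index < start + 512:
                expected = a.mapped_class
                break
        assert assign_label(spec, anns) == expected


class TestMinmaxNormalize:
    def test_simple_case(self):
        pair = minmax_normalize(np.zeros(4), np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(pair.noisy, [0, 1 / 3, 2 / 3, 1])

    def test_inverse_recovers_original(self, rng):
        noisy = rng.normal(size=1024)
        clean = rng.normal(size=1024)
        pair = minmax_normalize(clean, noisy)
        np.testing.assert_allclose(pair.denormalize(pair.noisy), noisy, atol=1e-12)
        np.testing.assert_allclose(pair.denormalize(pair.clean), clean, atol=1e-12)

    def test_clean_may_exceed_unit_range(self):
        clean = np.array([0.0, 5.0, 0.0, 0.0])
        noisy = np.array([0.0, 1.0, 2.0, 3.0])
        pair = minmax_normalize(clean, noisy)
        assert pair.clean.max() > 1.0  # no clamping

    def test_constant_noisy_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_normalize(np.ones(8), np.ones(8))

    def test_order_preserving(self, rng):
        noisy = rng.normal(size=100)
        pair = minmax_normalize(noisy, noisy)
        assert np.all(np.argsort(pair.noisy) == np.argsort(noisy))


class TestSplitHalves:
    def test_both_halves_labeled(self, rng):
        anns = [BeatAnnotation(100, "N", "N"), BeatAnnotation(700, "V", "V")]
        segs = split_halves(rng.normal(size=1024), WindowSpec("r", 0, 1024), anns)
        assert [s.label for s in segs] == ["N", "V"]
        assert [s.spec.start_index for s in segs] == [0, 512]
        assert all(len(s.window) == 512 for s in segs)

    def test_beat_only_in_second_half(self, rng):
        anns = [BeatAnnotation(800, "A", "A")]
        segs = split_halves(rng.normal(size=1024), WindowSpec("r", 0, 1024), anns)
        assert len(segs) == 1
        assert segs[0].label == "A"
        assert segs[0].spec.start_index == 512

    def test_halves_label_independently(self, rng):
        # two different beats -> two different labels preserved
        anns = [BeatAnnotation(10, "B", "B"), BeatAnnotation(400, "N", "N"),
                BeatAnnotation(600, "F", "F")]
        segs = split_halves(rng.normal(size=1024), WindowSpec("r", 0, 1024), anns)
        assert [s.label for s in segs] == ["B", "F"]

    def test_record_offset_respected(self, rng):
        anns = [BeatAnnotation(5000 + 600, "V", "V")]
        segs = split_halves(rng.normal(size=1024), WindowSpec("r", 5000, 1024), anns)
        assert [s.label for s in segs] == ["V"]


class TestTrainTestSplit:
    def test_eight_two_ratio(self):
        items = list(range(10))
        train, test = train_test_split(items, ratio=0.8, seed=0, labels=[None] * 10)
        assert len(train) == 8 and len(test) == 2
        assert sorted(train + test) == items

    def test_deterministic_under_seed(self):
        items = list(range(100))
        a = train_test_split(items, seed=5, labels=[None] * 100)
        b = train_test_split(items, seed=5, labels=[None] * 100)
        assert a == b

    def test_stratified_by_label(self):
        labels = ["N"] * 80 + ["V"] * 20
        train, test = train_test_split(list(range(100)), ratio=0.8, seed=1, labels=labels)
        train_v = sum(1 for i in train if labels[i] == "V")
        assert train_v == 16  # exactly 80% of each class

    def test_record_mode_partitions_records(self, rng):
        from ecganoise.segmentation import LabeledSegment
        items = [LabeledSegment(window=np.zeros(512), label="N",
                                spec=WindowSpec(f"rec{i % 5}", j, 512))
                 for j, i in enumerate(range(50))]
        train, test = train_test_split(items, ratio=0.6, seed=2, mode="record")
        train_ids = {s.spec.record_id for s in train}
        test_ids = {s.spec.record_id for s in test}
        assert train_ids.isdisjoint(test_ids)
        assert len(train) + len(test) == 50

    def test_bad_ratio_rejected(self):
        with pytest.raises(ArgumentError):
            train_test_split([1, 2], ratio=1.5)
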