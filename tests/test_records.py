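"""WFDB round-trips, Fourier resampling, annotation mapping, segment store."""

import numpy as np
import pytest

from ecganoise.errors import (ArgumentError, ChannelNotFoundError,
                              FormatError)
from ecganoise.noise import NoiseRecipe
from ecganoise.records import (BeatAnnotation, ECGRecord, LabelMap,
                               map_annotations, read_segment_store,
                               read_wfdb_record, resample_record,
                               write_segment_store, write_wfdb_record)
from ecganoise.segmentation import SegmentPair, WindowSpec, split_halves


def _quantize(sig):
    # the 12-bit/200-gain grid the WFDB writer stores on
    return np.clip(np.rint(np.asarray(sig) * 200.0), -2048, 2047) / 200.0


class TestWfdbRoundTrip:
    def test_signal_and_annotations_roundtrip_bit_exact(self, tmp_path, rng):
        sig = _quantize(rng.normal(0, 1.0, size=5001))
        anns = [BeatAnnotation(10, "N"), BeatAnnotation(500, "L"),
                BeatAnnotation(2500, "V"), BeatAnnotation(5000, "A")]
        rec = ECGRecord("t01", 360.0, sig, "MLII", anns)
        write_wfdb_record(rec, tmp_path)
        back = read_wfdb_record(tmp_path / "t01", channel="MLII")
        np.testing.assert_array_equal(back.signal, sig)
        assert back.fs == 360.0
        assert [(a.sample_index, a.raw_symbol) for a in back.annotations] == \
               [(a.sample_index, a.raw_symbol) for a in anns]

    def test_long_annotation_gap_uses_skip_escape(self, tmp_path):
        sig = np.zeros(10_000)
        sig[::50] = 1.0
        anns = [BeatAnnotation(3, "N"), BeatAnnotation(9000, "V")]  # gap > 1023
        write_wfdb_record(ECGRecord("t02", 250.0, sig, "MLII", anns), tmp_path)
        back = read_wfdb_record(tmp_path / "t02")
        assert [(a.sample_index, a.raw_symbol) for a in back.annotations] == \
               [(3, "N"), (9000, "V")]

    def test_valid_mask_roundtrip(self, tmp_path):
        sig = np.ones(2000)
        mask = np.ones(2000, dtype=bool)
        mask[300:500] = False
        write_wfdb_record(ECGRecord("t03", 360.0, sig, "MLII", [], mask), tmp_path)
        back = read_wfdb_record(tmp_path / "t03")
        np.testing.assert_array_equal(back.valid_mask, mask)

    def test_missing_channel_error_names_available(self, tmp_path):
        write_wfdb_record(ECGRecord("t04", 360.0, np.ones(1200), "V5"), tmp_path)
        with pytest.raises(ChannelNotFoundError) as exc:
            read_wfdb_record(tmp_path / "t04", channel="MLII")
        assert "V5" in str(exc.value)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wfdb_record(tmp_path / "nope")

    def test_annotation_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            ECGRecord("bad", 360.0, np.zeros(3), annotations=[BeatAnnotation(5, "N")])

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(ArgumentError):
            ECGRecord("bad", 0.0, np.zeros(10))


class TestResample:
    def test_250hz_to_360hz_length(self):
        rec = ECGRecord("r", 250.0, np.sin(np.arange(2500) * 0.01))
        out = resample_record(rec, 360.0)
        assert len(out) == 3600
        assert out.fs == 360.0

    def test_identity_resampling(self, rng):
        sig = rng.normal(size=1000)
        rec = ECGRecord("r", 360.0, sig)
        out = resample_record(rec, 360.0)
        np.testing.assert_allclose(out.signal, sig, rtol=1e-9)

    def test_sinusoid_against_closed_form(self):
        # 5 Hz tone: resampled output must track the analytic waveform
        t_in = np.arange(2500) / 250.0
        rec = ECGRecord("r", 250.0, np.sin(2 * np.pi * 5 * t_in))
        out = resample_record(rec, 360.0)
        t_out = np.arange(3600) / 360.0
        expected = np.sin(2 * np.pi * 5 * t_out)
        r = np.corrcoef(out.signal, expected)[0, 1]
        assert r >= 0.999

    def test_annotation_indices_rescaled(self):
        rec = ECGRecord("r", 250.0, np.zeros(2500),
                        annotations=[BeatAnnotation(250, "N"), BeatAnnotation(1000, "V")])
        out = resample_record(rec, 360.0)
        assert [a.sample_index for a in out.annotations] == [360, 1440]

    def test_round_trip_rms_small_for_bandlimited(self, rng):
        # band-limited signal survives down-up round trip
        t = np.arange(3600) / 360.0
        sig = sum(np.sin(2 * np.pi * f * t + f) for f in (1.0, 7.0, 23.0))
        rec = ECGRecord("r", 360.0, sig)
        back = resample_record(resample_record(rec, 250.0), 360.0)
        interior = slice(100, -100)  # FFT resampling rings at the edges
        rms = np.sqrt(np.mean((back.signal[interior] - sig[interior]) ** 2))
        assert rms < 1e-6

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ArgumentError):
            resample_record(ECGRecord("r", 250.0, np.zeros(100)), -1.0)


class TestMapAnnotations:
    def test_six_symbols_map_to_five_classes_with_drop(self):
        anns = [BeatAnnotation(i * 10, s) for i, s in enumerate("NLRV/A")]
        rec = ECGRecord("r", 360.0, np.zeros(100), annotations=anns)
        out = map_annotations(rec)
        assert [a.mapped_class for a in out.annotations] == ["N", "B", "B", "V", "A"]
        assert len(out.annotations) == len(anns) - 1

    def test_empty_annotations(self):
        out = map_annotations(ECGRecord("r", 360.0, np.zeros(100)))
        assert out.annotations == []

    def test_all_fusion_beats_kept(self):
        anns = [BeatAnnotation(i * 10, "F") for i in range(5)]
        out = map_annotations(ECGRecord("r", 360.0, np.zeros(100), annotations=anns))
        assert all(a.mapped_class == "F" for a in out.annotations)
        assert len(out.annotations) == 5

    def test_mapping_never_increases_count_and_alphabet_is_closed(self, rng):
        symbols = list("NLRVAF/fxQj|")
        anns = sorted(
            (BeatAnnotation(int(i), rng.choice(symbols)) for i in
             rng.choice(1000, size=50, replace=False)),
            key=lambda a: a.sample_index)
        rec = ECGRecord("r", 360.0, np.zeros(1000), annotations=anns)
        out = map_annotations(rec)
        assert len(out.annotations) <= len(anns)
        assert {a.mapped_class for a in out.annotations} <= {"N", "B", "V", "A", "F"}

    def test_default_label_map_invariants(self):
        lm = LabelMap()
        assert len(lm.mapping) == 6
        assert set(lm.mapping.values()) == {"N", "B", "V", "A", "F"}
        assert lm.excluded_records == frozenset({"102", "104"})


class TestSegmentStore:
    @staticmethod
    def _pairs(rng, n=11):
        out = []
        for i in range(n):
            noisy = rng.normal(size=1024)
            clean = rng.normal(size=1024)
            out.append(SegmentPair(
                clean=clean, noisy=noisy, norm_min=float(i), norm_max=float(i + 2),
                spec=WindowSpec("recA", i * 180, 1024),
                recipe=NoiseRecipe.single("BW", 0.0)))
        return out

    def test_pairs_roundtrip_bit_exact(self, tmp_path, rng):
        pairs = self._pairs(rng)
        path = write_segment_store(pairs, tmp_path / "pairs.h5")
        back = read_segment_store(path)
        assert len(back) == 11
        for a, b in zip(pairs, back):
            np.testing.assert_array_equal(a.clean, b.clean)
            np.testing.assert_array_equal(a.noisy, b.noisy)
            assert (a.norm_min, a.norm_max) == (b.norm_min, b.norm_max)
            assert a.spec == b.spec
            assert a.recipe == b.recipe

    def test_labeled_roundtrip(self, tmp_path, rng):
        segs = split_halves(rng.normal(size=1024), WindowSpec("recB", 0, 1024),
                            [BeatAnnotation(100, "N", "N"), BeatAnnotation(700, "V", "V")])
        path = write_segment_store(segs, tmp_path / "segs.h5")
        back = read_segment_store(path)
        assert [s.label for s in back] == [s.label for s in segs]
        for a, b in zip(segs, back):
            np.testing.assert_array_equal(a.window, b.window)

    def test_empty_store(self, tmp_path):
        path = write_segment_store([], tmp_path / "empty.h5")
        assert read_segment_store(path) == []

    def test_corrupted_store_rejected(self, tmp_path):
        bad = tmp_path / "bad.h5"
        bad.write_bytes(b"not an hdf5 file")
        with pytest.raises(FormatError):
            read_segment_store(bad)

    def test_window_length_mismatch_rejected(self, tmp_path, rng):
        import h5py
        path = write_segment_store(self._pairs(rng, 3), tmp_path / "p.h5")
        with h5py.File(path, "a") as f:
            f.attrs["window_len"] = 999
        with pytest.raises(FormatError):
            read_segment_store(path)
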