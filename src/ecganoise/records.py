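"""Single-lead ECG records: WFDB I/O, resampling, annotation mapping.

A record is a single channel of amplitude samples in millivolts plus an
ordered list of beat annotations (sample index + symbol) and an optional
per-sample validity mask (``False`` marks lead-off intervals).

The WFDB reader/writer here covers the subset of the format this package
needs: text ``.hea`` headers, format-212 ``.dat`` signal files (12-bit
two's-complement samples packed two per three bytes) and MIT ``.atr``
annotation files (2-byte words, 10-bit time deltas, SKIP escapes for long
gaps).  Files written by :func:`write_wfdb_record` round-trip bit-exactly
through :func:`read_wfdb_record` at the stored 12-bit precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy.signal import resample as _fourier_resample

from .errors import ArgumentError, ChannelNotFoundError, FormatError

logger = logging.getLogger(__name__)

#: Beat classes retained for classification.
BEAT_CLASSES = ("N", "B", "V", "A", "F")

# MIT annotation code numbers for the symbols this package reads and writes.
SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "e": 14, "f": 38,
    "x": 37, "|": 31, "+": 28, "~": 22,
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}

_SKIP_CODE = 59
_NUM_CODE = 60  # annotation-num change, skipped on read
_AUX_CODE = 63  # aux string, skipped on read


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated beat: 0-based sample position plus its symbol.

    ``mapped_class`` is set only after :func:`map_annotations` and is one of
    ``BEAT_CLASSES`` (left/right bundle-branch block symbols L and R both map
    to the merged block class B).
    """

    sample_index: int
    raw_symbol: str
    mapped_class: Optional[str] = None


@dataclass(frozen=True)
class LabelMap:
    """Raw annotation symbol -> retained beat class, plus record exclusions.

    The default keeps the six symbols N, L, R, V, A, F, merging L and R into
    B, and excludes the two records whose primary channel is not MLII.
    """

    mapping: dict = field(
        default_factory=lambda: {
            "N": "N", "L": "B", "R": "B", "V": "V", "A": "A", "F": "F",
        }
    )
    excluded_records: frozenset = frozenset({"102", "104"})

    def __post_init__(self):
        classes = set(self.mapping.values())
        if not classes <= set(BEAT_CLASSES):
            raise ArgumentError(f"mapped classes {classes} not a subset of {BEAT_CLASSES}")


@dataclass
class ECGRecord:
    """Single-channel ECG signal with beat annotations.

    Attributes
    ----------
    record_id : str
        Record name (e.g. ``"100"``).
    fs : float
        Sampling rate in Hz, strictly positive.
    signal : ndarray
        Amplitude samples in mV.
    channel_name : str
        Lead name, e.g. ``"MLII"``.
    annotations : list of BeatAnnotation
        Sorted by sample index; every index in ``[0, len(signal))``.
    valid_mask : ndarray of bool, optional
        Per-sample validity; ``False`` marks lead-off samples.
    """

    record_id: str
    fs: float
    signal: np.ndarray
    channel_name: str = "MLII"
    annotations: list = field(default_factory=list)
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ArgumentError(f"fs must be positive, got {self.fs}")
        n = len(self.signal)
        idx = [a.sample_index for a in self.annotations]
        if any(i < 0 or i >= n for i in idx):
            raise ArgumentError("annotation sample_index out of range [0, record length)")
        if idx != sorted(idx):
            self.annotations = sorted(self.annotations, key=lambda a: a.sample_index)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if len(self.valid_mask) != n:
                raise ArgumentError("valid_mask length must equal signal length")

    def __len__(self) -> int:
        return len(self.signal)


# ---------------------------------------------------------------------------
# WFDB signal files (.hea + format-212 .dat)
# ---------------------------------------------------------------------------

_DEFAULT_GAIN = 200.0  # ADC units per mV, the MIT-BIH convention


def write_wfdb_record(rec: ECGRecord, directory) -> Path:
    """Write ``rec`` as a WFDB record (``.hea``, format-212 ``.dat``, ``.atr``).

    Samples are quantized at 200 ADC units/mV into the 12-bit range; the
    annotation file is written whenever the record has annotations.  A
    ``valid_mask``, when present, is stored as a sidecar ``.mask.json`` of
    lead-off intervals (not part of WFDB proper).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.record_id
    digital = np.clip(np.rint(rec.signal * _DEFAULT_GAIN), -2048, 2047).astype(np.int16)

    header = (
        f"{name} 1 {rec.fs:g} {len(digital)}\n"
        f"{name}.dat 212 {_DEFAULT_GAIN:g} 12 0 {int(digital[0]) if len(digital) else 0} "
        f"0 0 {rec.channel_name}\n"
    )
    (directory / f"{name}.hea").write_text(header)
    (directory / f"{name}.dat").write_bytes(_pack_212(digital))
    if rec.annotations:
        _write_atr(directory / f"{name}.atr", rec.annotations)
    if rec.valid_mask is not None:
        runs = _mask_to_invalid_runs(rec.valid_mask)
        (directory / f"{name}.mask.json").write_text(json.dumps(runs))
    return directory / f"{name}.hea"


def read_wfdb_record(path, channel: str = "MLII") -> ECGRecord:
    """Read a WFDB record, returning the requested channel in physical units.

    ``path`` is the header path or the record path without extension.
    Raises :class:`ChannelNotFoundError` (naming the available channels) if
    the requested lead is absent, and :class:`FormatError` on malformed files.
    """
    path = Path(path)
    if path.suffix == ".hea":
        path = path.with_suffix("")
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed header line in {hea}: {lines[0]!r}")
    name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    sig_lines = lines[1 : 1 + nsig]
    descs, gains, fmts, files = [], [], [], []
    for ln in sig_lines:
        parts = ln.split(None, 8)
        if len(parts) < 3:
            raise FormatError(f"malformed signal line in {hea}: {ln!r}")
        files.append(parts[0])
        fmts.append(parts[1].split("x")[0])
        gain_field = parts[2].split("/")[0]
        # gain may carry a (baseline) suffix, e.g. "200(0)"
        gains.append(float(gain_field.split("(")[0]))
        descs.append(parts[8] if len(parts) > 8 else f"ch{len(descs)}")
    if channel not in descs:
        raise ChannelNotFoundError(channel, descs)
    ch = descs.index(channel)
    if fmts[ch] != "212":
        raise FormatError(f"unsupported signal format {fmts[ch]} (only 212 supported)")
    raw = (path.parent / files[ch]).read_bytes()
    digital = _unpack_212(raw, nsamp * nsig)
    sig = digital.reshape(-1, nsig)[:nsamp, ch].astype(float) / gains[ch]

    annotations: list[BeatAnnotation] = []
    atr = path.with_suffix(".atr")
    if atr.exists():
        annotations = _read_atr(atr)

    mask = None
    mask_file = path.with_suffix(".mask.json")
    if mask_file.exists():
        mask = _invalid_runs_to_mask(json.loads(mask_file.read_text()), nsamp)

    return ECGRecord(record_id=name, fs=fs, signal=sig, channel_name=channel,
                     annotations=annotations, valid_mask=mask)


def _pack_212(digital: np.ndarray) -> bytes:
    d = digital.astype(np.int32)
    if len(d) % 2:
        d = np.concatenate([d, [0]])
    a, b = d[0::2] & 0xFFF, d[1::2] & 0xFFF
    out = np.empty(3 * len(a), dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[2::3] = b & 0xFF
    return out.tobytes()


def _unpack_212(raw: bytes, n_samples: int) -> np.ndarray:
    buf = np.frombuffer(raw, dtype=np.uint8)
    if len(buf) % 3:
        buf = buf[: len(buf) - len(buf) % 3]
    b0, b1, b2 = buf[0::3].astype(np.int32), buf[1::3].astype(np.int32), buf[2::3].astype(np.int32)
    a = ((b1 & 0x0F) << 8) | b0
    b = ((b1 >> 4) << 8) | b2
    out = np.empty(2 * len(a), dtype=np.int32)
    out[0::2], out[1::2] = a, b
    out = np.where(out > 2047, out - 4096, out)  # 12-bit two's complement
    if len(out) < n_samples:
        raise FormatError(f"signal file truncated: {len(out)} < {n_samples} samples")
    return out[:n_samples]


# ---------------------------------------------------------------------------
# MIT annotation files (.atr)
# ---------------------------------------------------------------------------

def _write_atr(path: Path, annotations: Sequence[BeatAnnotation]) -> None:
    words: list[int] = []
    prev = 0
    for ann in annotations:
        code = SYMBOL_TO_CODE.get(ann.raw_symbol)
        if code is None:
            raise ArgumentError(f"no MIT code for annotation symbol {ann.raw_symbol!r}")
        dt = ann.sample_index - prev
        if dt < 0:
            raise ArgumentError("annotations must be sorted by sample_index")
        if dt > 1023:
            # SKIP escape: code 59 with dt 0, then 32-bit interval, high word first
            words.append(_SKIP_CODE << 10)
            words.append((dt >> 16) & 0xFFFF)
            words.append(dt & 0xFFFF)
            dt = 0
        words.append((code << 10) | dt)
        prev = ann.sample_index
    words.append(0)  # EOF
    path.write_bytes(np.asarray(words, dtype="<u2").tobytes())


def _read_atr(path: Path) -> list[BeatAnnotation]:
    words = np.frombuffer(path.read_bytes(), dtype="<u2")
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code, dt = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and dt == 0:
            break
        if code == _SKIP_CODE and dt == 0:
            if i + 1 >= len(words):
                raise FormatError("truncated SKIP escape in annotation file")
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
            continue
        if code in (_NUM_CODE, _AUX_CODE):
            if code == _AUX_CODE:  # aux: dt bytes of string, padded to even
                i += (dt + 1) // 2
            continue
        t += dt
        symbol = CODE_TO_SYMBOL.get(code, "Q")
        anns.append(BeatAnnotation(sample_index=t, raw_symbol=symbol))
    return anns


def _mask_to_invalid_runs(mask: np.ndarray) -> list[list[int]]:
    invalid = ~np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], invalid.view(np.int8), [0]])))
    return [[int(s), int(e)] for s, e in zip(edges[0::2], edges[1::2])]


def _invalid_runs_to_mask(runs: list, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for s, e in runs:
        mask[s:e] = False
    return mask


# ---------------------------------------------------------------------------
# Resampling and annotation mapping
# ---------------------------------------------------------------------------

def resample_record(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample a record to ``target_fs`` with the Fourier (FFT) method.

    Output length is ``round(len * target_fs / fs)``; annotation indices are
    rescaled by the same ratio and rounded to the nearest sample (ties away
    from zero), then clipped into range.
    """
    if target_fs <= 0:
        raise ArgumentError(f"target_fs must be positive, got {target_fs}")
    if math.isclose(target_fs, rec.fs):
        return dataclasses.replace(rec)
    ratio = target_fs / rec.fs
    n_out = int(round(len(rec.signal) * ratio))
    sig = _fourier_resample(rec.signal, n_out)
    anns = [
        dataclasses.replace(a, sample_index=min(_round_half_away(a.sample_index * ratio), n_out - 1))
        for a in rec.annotations
    ]
    mask = None
    if rec.valid_mask is not None:
        # nearest-neighbour resample of the boolean mask
        src = np.minimum((np.arange(n_out) / ratio).astype(int), len(rec.valid_mask) - 1)
        mask = rec.valid_mask[src]
    return ECGRecord(rec.record_id, target_fs, sig, rec.channel_name, anns, mask)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def map_annotations(rec: ECGRecord, label_map: Optional[LabelMap] = None) -> ECGRecord:
    """Apply a :class:`LabelMap`: rewrite retained symbols, drop the rest.

    Dropped-symbol counts are logged at INFO level.  Never increases the
    annotation count; the post-mapping class alphabet is a subset of
    ``BEAT_CLASSES``.
    """
    label_map = label_map or LabelMap()
    kept, dropped = [], Counter()
    for ann in rec.annotations:
        cls = label_map.mapping.get(ann.raw_symbol)
        if cls is None:
            dropped[ann.raw_symbol] += 1
        else:
            kept.append(dataclasses.replace(ann, mapped_class=cls))
    if dropped:
        logger.info("record %s: dropped %d annotations: %s",
                    rec.record_id, sum(dropped.values()), dict(dropped))
    return dataclasses.replace(rec, annotations=kept)


# ---------------------------------------------------------------------------
# Segment store (HDF5 container)
# ---------------------------------------------------------------------------

_STORE_VERSION = 1


def write_segment_store(items, path) -> Path:
    """Write segment pairs or labeled segments to a single HDF5 container.

    The header records the schema version and window length so corrupted or
    mismatched stores are rejected on read.  Round-trips are bit-exact.
    """
    from .segmentation import LabeledSegment, SegmentPair  # local: avoid cycle

    items = list(items)
    path = Path(path)
    kind = "empty"
    if items and isinstance(items[0], SegmentPair):
        kind = "pairs"
    elif items and isinstance(items[0], LabeledSegment):
        kind = "labeled"
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _STORE_VERSION
        f.attrs["kind"] = kind
        f.attrs["n"] = len(items)
        if kind == "pairs":
            f.attrs["window_len"] = len(items[0].clean)
            f.create_dataset("clean", data=np.stack([p.clean for p in items]))
            f.create_dataset("noisy", data=np.stack([p.noisy for p in items]))
            f.create_dataset("norm_min", data=[p.norm_min for p in items])
            f.create_dataset("norm_max", data=[p.norm_max for p in items])
            f.create_dataset("record_id", data=[p.spec.record_id for p in items])
            f.create_dataset("start_index", data=[p.spec.start_index for p in items])
            f.create_dataset(
                "recipe",
                data=[json.dumps(_recipe_to_dict(p.recipe)) for p in items],
            )
        elif kind == "labeled":
            f.attrs["window_len"] = len(items[0].window)
            f.create_dataset("window", data=np.stack([s.window for s in items]))
            f.create_dataset("label", data=[s.label for s in items])
            f.create_dataset("record_id", data=[s.spec.record_id for s in items])
            f.create_dataset("start_index", data=[s.spec.start_index for s in items])
    return path


def read_segment_store(path):
    """Read a store written by :func:`write_segment_store`."""
    from .noise import NoiseRecipe
    from .segmentation import LabeledSegment, SegmentPair, WindowSpec

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"not a readable segment store: {path}") from exc
    with f:
        if f.attrs.get("schema_version") != _STORE_VERSION:
            raise FormatError(f"unsupported store schema version in {path}")
        kind = f.attrs["kind"]
        n = int(f.attrs["n"])
        if kind == "empty":
            return []
        window_len = int(f.attrs["window_len"])
        if kind == "pairs":
            clean, noisy = f["clean"][:], f["noisy"][:]
            if clean.shape[1] != window_len or noisy.shape[1] != window_len:
                raise FormatError("window length mismatch between header and data")
            out = []
            for i in range(n):
                spec = WindowSpec(
                    record_id=f["record_id"][i].decode(),
                    start_index=int(f["start_index"][i]),
                    length=window_len,
                )
                rd = json.loads(f["recipe"][i].decode())
                recipe = NoiseRecipe(**rd) if rd else None
                out.append(SegmentPair(
                    clean=clean[i], noisy=noisy[i],
                    norm_min=float(f["norm_min"][i]), norm_max=float(f["norm_max"][i]),
                    spec=spec, recipe=recipe,
                ))
            return out
        if kind == "labeled":
            win = f["window"][:]
            if win.shape[1] != window_len:
                raise FormatError("window length mismatch between header and data")
            return [
                LabeledSegment(
                    window=win[i],
                    label=f["label"][i].decode(),
                    spec=WindowSpec(
                        record_id=f["record_id"][i].decode(),
                        start_index=int(f["start_index"][i]),
                        length=window_len,
                    ),
                )
                for i in range(n)
            ]
        raise FormatError(f"unknown store kind {kind!r} in {path}")


def _recipe_to_dict(recipe):
    if recipe is None:
        return {}
    return {"components": [list(c) for c in recipe.components],
            "target_snr_db": recipe.target_snr_db}
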