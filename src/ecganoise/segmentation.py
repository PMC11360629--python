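"""Fixed-window segmentation, labeling, normalization and data splitting.

Records are sliced into overlapping 1024-sample denoising windows at a
180-sample stride (0.50 s at 360 Hz).  Each window is min-max normalized
using the *noisy* member's extrema (the clean signal is unknown at
inference), and split into two 512-sample halves for beat classification.
A half-window's label is the mapped class of the earliest annotation inside
it; halves with no annotation are discarded.  All indexing is 0-based with
half-open windows ``[start, start + length)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ArgumentError, DegenerateInputError
from .records import BeatAnnotation, ECGRecord
from .noise import NoiseRecipe

logger = logging.getLogger(__name__)

DENOISE_WINDOW = 1024
CLASSIFY_WINDOW = 512
DEFAULT_STRIDE = 180


@dataclass(frozen=True)
class WindowSpec:
    """Location of one window inside a record (half-open, 0-based)."""

    record_id: str
    start_index: int
    length: int

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length


@dataclass
class SegmentPair:
    """Aligned clean/noisy window pair on a shared normalized scale."""

    clean: np.ndarray
    noisy: np.ndarray
    norm_min: float
    norm_max: float
    spec: WindowSpec
    recipe: Optional[NoiseRecipe] = None

    def __post_init__(self):
        if self.norm_max <= self.norm_min:
            raise ArgumentError("norm_max must exceed norm_min")
        if len(self.clean) != len(self.noisy):
            raise ArgumentError("clean and noisy members must have equal length")

    def denormalize(self, values: np.ndarray) -> np.ndarray:
        """Map values from the normalized scale back to mV."""
        return np.asarray(values) * (self.norm_max - self.norm_min) + self.norm_min


@dataclass(frozen=True)
class LabeledSegment:
    """Normalized 512-sample window carrying one beat-class label."""

    window: np.ndarray
    label: str
    spec: WindowSpec


def slice_windows(
    rec: ECGRecord,
    window_len: int = DENOISE_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> List[WindowSpec]:
    """Enumerate window positions at a fixed stride, starting at sample 0.

    Yields ``floor((L - window_len)/stride) + 1`` windows for a record of
    length ``L >= window_len``; an empty list (with a warning) otherwise.
    Windows overlapping any invalid (lead-off) sample are removed.
    """
    if window_len <= 0 or stride <= 0:
        raise ArgumentError("window_len and stride must be positive")
    n = len(rec)
    if n < window_len:
        logger.warning("record %s shorter than window (%d < %d); no windows",
                       rec.record_id, n, window_len)
        return []
    starts = range(0, n - window_len + 1, stride)
    specs = [WindowSpec(rec.record_id, s, window_len) for s in starts]
    if rec.valid_mask is not None:
        invalid = ~rec.valid_mask
        cum = np.concatenate([[0], np.cumsum(invalid)])
        kept = [sp for sp in specs if cum[sp.stop_index] - cum[sp.start_index] == 0]
        if len(kept) != len(specs):
            logger.info("record %s: %d windows dropped over lead-off samples",
                        rec.record_id, len(specs) - len(kept))
        specs = kept
    return specs


def assign_label(spec: WindowSpec, annotations: Sequence[BeatAnnotation]) -> Optional[str]:
    """Mapped class of the earliest annotation inside the window, else None."""
    for ann in annotations:  # sorted by sample_index
        if ann.sample_index >= spec.stop_index:
            break
        if ann.sample_index >= spec.start_index:
            return ann.mapped_class
    return None


def minmax_normalize(
    clean: Sequence[float],
    noisy: Sequence[float],
    spec: Optional[WindowSpec] = None,
    recipe: Optional[NoiseRecipe] = None,
) -> SegmentPair:
    """Normalize a window pair by the noisy member's min and max.

    Both members are mapped by ``(x - min(noisy)) / (max(noisy) - min(noisy))``
    and the parameters are stored for inversion.  Clean values outside the
    noisy range legitimately fall outside [0, 1]; no clamping.
    """
    clean = np.asarray(clean, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    if clean.shape != noisy.shape:
        raise ArgumentError("clean and noisy windows must have equal length")
    lo, hi = float(np.min(noisy)), float(np.max(noisy))
    if hi == lo:
        raise DegenerateInputError("constant noisy window; min-max scale undefined")
    scale = hi - lo
    spec = spec or WindowSpec("", 0, len(clean))
    return SegmentPair(
        clean=(clean - lo) / scale,
        noisy=(noisy - lo) / scale,
        norm_min=lo,
        norm_max=hi,
        spec=spec,
        recipe=recipe,
    )


def split_halves(
    values: Sequence[float],
    spec: WindowSpec,
    annotations: Sequence[BeatAnnotation],
) -> List[LabeledSegment]:
    """Split a 1024-sample window into two labeled 512-sample halves.

    ``values`` is any signal on the window (clean, noisy or denoised);
    ``annotations`` are record-level.  Halves without an annotation are
    dropped; the two halves are labeled independently.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != spec.length:
        raise ArgumentError("values length must equal spec.length")
    if spec.length % 2:
        raise ArgumentError("window length must be even to split into halves")
    half = spec.length // 2
    out = []
    for offset in (0, half):
        half_spec = WindowSpec(spec.record_id, spec.start_index + offset, half)
        label = assign_label(half_spec, annotations)
        if label is not None:
            out.append(LabeledSegment(
                window=values[offset:offset + half], label=label, spec=half_spec))
    return out


def train_test_split(
    items: Sequence,
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "segment",
    labels: Optional[Sequence[str]] = None,
) -> Tuple[list, list]:
    """Deterministic 8:2-style split of segments or whole records.

    ``segment`` mode shuffles items (stratified by ``labels`` or by each
    item's ``label`` attribute when available); ``record`` mode partitions by
    each item's ``spec.record_id`` so no record contributes to both sides.
    """
    if not 0.0 < ratio < 1.0:
        raise ArgumentError(f"ratio must be in (0, 1), got {ratio}")
    if mode not in ("segment", "record"):
        raise ArgumentError(f"unknown split mode {mode!r}")
    items = list(items)
    rng = np.random.default_rng(seed)

    if mode == "record":
        rec_ids = sorted({it.spec.record_id for it in items})
        rng.shuffle(rec_ids)
        n_train = int(round(ratio * len(rec_ids)))
        train_ids = set(rec_ids[:n_train])
        train = [it for it in items if it.spec.record_id in train_ids]
        test = [it for it in items if it.spec.record_id not in train_ids]
        return train, test

    if labels is None:
        labels = [getattr(it, "label", None) for it in items]
    groups: Dict[object, list] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    train_idx, test_idx = [], []
    for lab in sorted(groups, key=str):
        idx = np.array(groups[lab])
        rng.shuffle(idx)
        n_train = int(round(ratio * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return [items[i] for i in sorted(train_idx)], [items[i] for i in sorted(test_idx)]


def data_volume_report(
    original_beats: int, segments: int
) -> Dict[str, float]:
    """Bookkeeping of segment-count amplification over raw beat labels."""
    return {
        "original_labels": original_beats,
        "segments": segments,
        "amplification": segments / original_beats if original_beats else float("nan"),
    }
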