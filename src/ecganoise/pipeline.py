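"""Corpus building and end-to-end evaluation helpers.

These functions connect the stages: record -> contaminated window pairs ->
labeled classification segments (original / noisy / denoised) -> metric
reports.  The offline stream simulator replays a record window-by-window in
arrival order and is guaranteed to agree with batch processing (inference
runs in evaluation mode, so per-window results are independent of batch
composition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .classifier import ClassifierResults
from .denoiser import DenoiserResults
from .errors import ArgumentError
from .metrics import denoise_metrics, mean_window_snr
from .noise import NoiseRecipe, synthesize_noisy
from .records import ECGRecord
from .segmentation import (DEFAULT_STRIDE, DENOISE_WINDOW, LabeledSegment,
                           SegmentPair, minmax_normalize, slice_windows,
                           split_halves)


def contaminate_record(
    rec: ECGRecord,
    recipe: NoiseRecipe,
    noise_bank,
    window_len: int = DENOISE_WINDOW,
    stride: int = DEFAULT_STRIDE,
    seed: int = 0,
) -> List[SegmentPair]:
    """Slice a record and contaminate every window at the recipe's target SNR.

    Each window is normalized by its noisy member's min-max; the noise
    weight is recomputed per window.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for spec in slice_windows(rec, window_len, stride):
        clean = rec.signal[spec.start_index:spec.stop_index]
        result = synthesize_noisy(clean, recipe, noise_bank, rng=rng)
        pairs.append(minmax_normalize(clean, result.noisy, spec, recipe))
    return pairs


def labeled_corpora(
    pairs: Sequence[SegmentPair],
    annotations,
    denoiser: Optional[DenoiserResults] = None,
) -> Dict[str, List[LabeledSegment]]:
    """Original/noisy(/denoised) labeled 512-sample corpora from window pairs."""
    corpora: Dict[str, List[LabeledSegment]] = {"original": [], "noisy": []}
    denoised_all = None
    if denoiser is not None:
        corpora["denoised"] = []
        denoised_all = denoiser.denoise(np.stack([p.noisy for p in pairs]))
    for i, pair in enumerate(pairs):
        corpora["original"].extend(split_halves(pair.clean, pair.spec, annotations))
        corpora["noisy"].extend(split_halves(pair.noisy, pair.spec, annotations))
        if denoised_all is not None:
            corpora["denoised"].extend(split_halves(denoised_all[i], pair.spec, annotations))
    return corpora


def denoising_summary(pairs: Sequence[SegmentPair], denoiser: DenoiserResults) -> Dict[str, float]:
    """Mean PRD/SNR/RMSE of the denoiser over window pairs, plus the noisy baseline."""
    noisy = np.stack([p.noisy for p in pairs])
    clean = np.stack([p.clean for p in pairs])
    denoised = denoiser.denoise(noisy)
    per = [denoise_metrics(c, d) for c, d in zip(clean, denoised)]
    return {
        "prd_percent": float(np.mean([m["prd_percent"] for m in per])),
        "snr_db": mean_window_snr(zip(clean, denoised)),
        "rmse": float(np.mean([m["rmse"] for m in per])),
        "noisy_snr_db": mean_window_snr(zip(clean, noisy)),
    }


def evaluate_corpora(
    corpora: Dict[str, List[LabeledSegment]],
    classifier: ClassifierResults,
) -> Dict[str, object]:
    """Classification report per corpus (noisy vs denoised vs original)."""
    return {
        name: classifier.report(segs)
        for name, segs in corpora.items() if segs
    }


@dataclass(frozen=True)
class StreamEvent:
    """One per-window result of the stream simulator."""

    start_index: int
    timestamp_s: float
    labels: tuple  # predicted class per 512-sample half
    skipped: bool = False
    reason: str = ""


def stream_simulate(
    rec: ECGRecord,
    denoiser: Optional[DenoiserResults],
    classifier: ClassifierResults,
    stride: int = DEFAULT_STRIDE,
    window_len: int = DENOISE_WINDOW,
) -> List[StreamEvent]:
    """Replay a record window-by-window: normalize, denoise, classify.

    Windows overlapping lead-off samples are skipped with a logged reason.
    Results are identical to :func:`batch_process` on the same record.
    """
    if classifier is None:
        raise ArgumentError("stream simulation requires a trained classifier")
    events: List[StreamEvent] = []
    n = len(rec)
    half = window_len // 2
    for start in range(0, n - window_len + 1, stride):
        ts = start / rec.fs
        if rec.valid_mask is not None and not rec.valid_mask[start:start + window_len].all():
            events.append(StreamEvent(start, ts, (), skipped=True, reason="lead-off gap"))
            continue
        window = rec.signal[start:start + window_len]
        lo, hi = float(window.min()), float(window.max())
        if hi == lo:
            events.append(StreamEvent(start, ts, (), skipped=True, reason="constant window"))
            continue
        norm = (window - lo) / (hi - lo)
        cleaned = denoiser.denoise(norm) if denoiser is not None else norm
        halves = np.stack([cleaned[:half], cleaned[half:]])
        labels = tuple(classifier.predict(halves))
        events.append(StreamEvent(start, ts, labels))
    return events


def batch_process(
    rec: ECGRecord,
    denoiser: Optional[DenoiserResults],
    classifier: ClassifierResults,
    stride: int = DEFAULT_STRIDE,
    window_len: int = DENOISE_WINDOW,
) -> List[StreamEvent]:
    """Process all windows at once; the reference for stream equivalence."""
    half = window_len // 2
    starts, norms, events_meta = [], [], []
    n = len(rec)
    for start in range(0, n - window_len + 1, stride):
        ts = start / rec.fs
        if rec.valid_mask is not None and not rec.valid_mask[start:start + window_len].all():
            events_meta.append(StreamEvent(start, ts, (), skipped=True, reason="lead-off gap"))
            continue
        window = rec.signal[start:start + window_len]
        lo, hi = float(window.min()), float(window.max())
        if hi == lo:
            events_meta.append(StreamEvent(start, ts, (), skipped=True, reason="constant window"))
            continue
        starts.append((start, ts))
        norms.append((window - lo) / (hi - lo))
    if norms:
        stack = np.stack(norms)
        cleaned = denoiser.denoise(stack) if denoiser is not None else stack
        halves = np.concatenate([cleaned[:, :half], cleaned[:, half:]], axis=0)
        labels = classifier.predict(halves)
        k = len(starts)
        for i, (start, ts) in enumerate(starts):
            events_meta.append(StreamEvent(start, ts, (labels[i], labels[k + i])))
    events_meta.sort(key=lambda e: e.start_index)
    return events_meta
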