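"""Denoising and classification metrics.

Denoising quality is measured between a reference window ``x`` and a
reconstruction ``x_hat``:

* ``PRD(%) = sqrt( sum((x - x_hat)^2) / sum(x^2) ) * 100``
* ``SNR(dB) = 10 * log10( sum(x^2) / sum((x_hat - x)^2) )``
* ``RMSE = sqrt( mean((x_hat - x)^2) )``

The three share one residual energy, so ``SNR = -20*log10(PRD/100)`` and
``RMSE = (PRD/100) * sqrt(sum(x^2)/N)`` hold identically; the helpers here
expose those identities for validation.  Classification quality is one-vs-
rest precision/recall/F1 per beat class, macro-averaged as the unweighted
mean over the declared class alphabet (a class absent from both truth and
prediction contributes zeros, it is not skipped).  Percentages are kept at
full precision internally and rounded half-even to two decimals only when
formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ArgumentError

#: Sentinel SNR for a perfect reconstruction (zero residual).
PERFECT_SNR_DB = math.inf


def _check_pair(x, x_hat):
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ArgumentError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return x, x_hat


def prd(x: Sequence[float], x_hat: Sequence[float]) -> float:
    """Percent root-mean-squared difference between ``x`` and ``x_hat``."""
    x, x_hat = _check_pair(x, x_hat)
    e_sig = float(np.sum(x**2))
    if e_sig == 0.0:
        raise ArgumentError("reference signal has zero energy; PRD undefined")
    return float(np.sqrt(np.sum((x - x_hat) ** 2) / e_sig) * 100.0)


def snr(x: Sequence[float], x_hat: Sequence[float]) -> float:
    """Signal-to-noise ratio of the reconstruction in dB (inf if exact)."""
    x, x_hat = _check_pair(x, x_hat)
    e_res = float(np.sum((x_hat - x) ** 2))
    if e_res == 0.0:
        return PERFECT_SNR_DB
    e_sig = float(np.sum(x**2))
    if e_sig == 0.0:
        raise ArgumentError("reference signal has zero energy; SNR undefined")
    return float(10.0 * np.log10(e_sig / e_res))


def rmse(x: Sequence[float], x_hat: Sequence[float]) -> float:
    """Root-mean-squared error between ``x`` and ``x_hat``."""
    x, x_hat = _check_pair(x, x_hat)
    return float(np.sqrt(np.mean((x_hat - x) ** 2)))


def snr_from_prd(prd_percent: float) -> float:
    """SNR implied by a PRD value: ``-20*log10(PRD/100)``."""
    if prd_percent <= 0:
        return PERFECT_SNR_DB
    return float(-20.0 * np.log10(prd_percent / 100.0))


def denoise_metrics(x, x_hat) -> Dict[str, float]:
    """PRD/SNR/RMSE of one window pair as a dict."""
    return {"prd_percent": prd(x, x_hat), "snr_db": snr(x, x_hat), "rmse": rmse(x, x_hat)}


@dataclass
class ClassificationReport:
    """Per-class and macro precision/recall/F1 with confusion counts.

    Values are percentages at full precision; use :meth:`to_text` or
    :meth:`rounded` for two-decimal presentation.
    """

    classes: tuple
    tp: Dict[str, int]
    fp: Dict[str, int]
    fn: Dict[str, int]
    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def rounded(self, ndigits: int = 2) -> "ClassificationReport":
        """Report with all percentages rounded half-even."""
        rnd = lambda d: {k: _round_half_even(v, ndigits) for k, v in d.items()}
        return ClassificationReport(
            classes=self.classes, tp=self.tp, fp=self.fp, fn=self.fn,
            precision=rnd(self.precision), recall=rnd(self.recall), f1=rnd(self.f1),
            macro_precision=_round_half_even(self.macro_precision, ndigits),
            macro_recall=_round_half_even(self.macro_recall, ndigits),
            macro_f1=_round_half_even(self.macro_f1, ndigits),
        )

    def to_text(self) -> str:
        """Aligned table: one row per class plus the macro-average row."""
        lines = [f"{'Class':<8}{'Precision (%)':>14}{'Recall (%)':>12}{'F1 (%)':>10}"]
        for c in self.classes:
            lines.append(f"{c:<8}{self.precision[c]:>14.2f}{self.recall[c]:>12.2f}"
                         f"{self.f1[c]:>10.2f}")
        lines.append(f"{'Average':<8}{self.macro_precision:>14.2f}"
                     f"{self.macro_recall:>12.2f}{self.macro_f1:>10.2f}")
        return "\n".join(lines)

    def to_csv(self) -> str:
        lines = ["class,precision_pct,recall_pct,f1_pct,tp,fp,fn"]
        for c in self.classes:
            lines.append(f"{c},{self.precision[c]:.2f},{self.recall[c]:.2f},"
                         f"{self.f1[c]:.2f},{self.tp[c]},{self.fp[c]},{self.fn[c]}")
        lines.append(f"Average,{self.macro_precision:.2f},{self.macro_recall:.2f},"
                     f"{self.macro_f1:.2f},,,")
        return "\n".join(lines) + "\n"


def _round_half_even(x: float, ndigits: int) -> float:
    return float(np.round(x, ndigits))


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def classification_report(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> ClassificationReport:
    """One-vs-rest precision/recall/F1 per class, macro-averaged.

    ``classes`` declares the alphabet (defaults to the sorted union of the
    observed labels); every declared class enters the macro average even
    when it never occurs.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ArgumentError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ArgumentError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = tuple(classes)

    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    for t, p in zip(y_true, y_pred):
        if t == p:
            if t in tp:
                tp[t] += 1
        else:
            if p in fp:
                fp[p] += 1
            if t in fn:
                fn[t] += 1

    precision, recall, f1 = {}, {}, {}
    for c in classes:
        denom_p = tp[c] + fp[c]
        denom_r = tp[c] + fn[c]
        precision[c] = 100.0 * tp[c] / denom_p if denom_p else 0.0
        recall[c] = 100.0 * tp[c] / denom_r if denom_r else 0.0
        f1[c] = f1_score(precision[c], recall[c])

    return ClassificationReport(
        classes=classes, tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(np.mean([precision[c] for c in classes])),
        macro_recall=float(np.mean([recall[c] for c in classes])),
        macro_f1=float(np.mean([f1[c] for c in classes])),
    )


def pooled_snr(pairs) -> float:
    """SNR of pooled residual energy across many (x, x_hat) pairs."""
    e_sig = sum(float(np.sum(np.asarray(x, dtype=float) ** 2)) for x, _ in pairs)
    e_res = sum(float(np.sum((np.asarray(xh, dtype=float) - np.asarray(x, dtype=float)) ** 2))
                for x, xh in pairs)
    if e_res == 0.0:
        return PERFECT_SNR_DB
    return float(10.0 * np.log10(e_sig / e_res))


def mean_window_snr(pairs) -> float:
    """Unweighted mean of per-window SNRs (the default aggregation)."""
    vals = [snr(x, xh) for x, xh in pairs]
    return float(np.mean(vals))
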