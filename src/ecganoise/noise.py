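"""SNR-controlled contamination of clean windows.

The contaminated signal is ``noisy = clean + alpha * noise`` where the noise
weight

    alpha = sqrt( sum(clean^2) / (10^(SNR_dB/10) * sum(noise^2)) )

makes the energy ratio between the clean signal and the injected noise hit
the requested SNR exactly.  Mixed recipes (e.g. ``0.3*BW + 0.7*MA``) are
formed as a pointwise weighted sum *before* alpha is computed, so the target
SNR governs the composite trace.  Alpha is recomputed per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ArgumentError, DegenerateInputError
from .fixtures import NoiseTrace


@dataclass(frozen=True)
class NoiseRecipe:
    """Noise components with mix weights, plus the target SNR in dB.

    Weights must be strictly positive and sum to one.
    """

    components: Tuple[Tuple[str, float], ...]
    target_snr_db: float

    def __post_init__(self):
        comps = tuple((str(k), float(w)) for k, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ArgumentError("recipe needs at least one noise component")
        weights = [w for _, w in comps]
        if any(w <= 0 for w in weights):
            raise ArgumentError(f"mix weights must be strictly positive, got {weights}")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ArgumentError(f"mix weights must sum to 1, got {sum(weights)}")

    @classmethod
    def single(cls, kind: str, target_snr_db: float) -> "NoiseRecipe":
        return cls(components=((kind, 1.0),), target_snr_db=target_snr_db)


@dataclass(frozen=True)
class NoiseSynthesisResult:
    """Contaminated window plus the weight and noise actually used."""

    noisy: np.ndarray
    alpha: float
    recipe: NoiseRecipe
    noise_used: NoiseTrace


def compute_alpha(clean: Sequence[float], noise: Sequence[float], target_snr_db: float) -> float:
    """Noise weight that achieves ``target_snr_db`` for ``clean + alpha*noise``."""
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ArgumentError(f"length mismatch: clean {clean.shape} vs noise {noise.shape}")
    e_noise = float(np.sum(noise**2))
    if e_noise == 0.0:
        raise DegenerateInputError("noise has zero energy; alpha undefined")
    e_clean = float(np.sum(clean**2))
    return float(np.sqrt(e_clean / (10.0 ** (target_snr_db / 10.0) * e_noise)))


def mix_noise_components(traces: Sequence[NoiseTrace], weights: Sequence[float]) -> NoiseTrace:
    """Pointwise weighted sum of equal-length traces; result kind is MIXED."""
    if len(traces) != len(weights):
        raise ArgumentError("one weight per trace required")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ArgumentError(f"trace length mismatch: {sorted(lengths)}")
    if any(w <= 0 for w in weights):
        raise ArgumentError("mix weights must be strictly positive")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ArgumentError("mix weights must sum to 1")
    samples = np.sum([w * t.samples for w, t in zip(weights, traces)], axis=0)
    kind = traces[0].kind if len(traces) == 1 else "MIXED"
    return NoiseTrace(kind=kind, samples=samples, fs=traces[0].fs)


def synthesize_noisy(
    clean: Sequence[float],
    recipe: NoiseRecipe,
    noise_bank: Dict[str, NoiseTrace],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NoiseSynthesisResult:
    """Contaminate one clean window at the recipe's exact target SNR.

    Each component is sliced from its bank trace at a random offset (seeded),
    the slices are mixed by recipe weight, and the composite is scaled by
    alpha so the achieved SNR equals the target to floating-point precision.
    """
    clean = np.asarray(clean, dtype=float)
    n = len(clean)
    if rng is None:
        rng = np.random.default_rng(seed)
    slices: List[NoiseTrace] = []
    for kind, _ in recipe.components:
        if kind not in noise_bank:
            raise ArgumentError(f"noise bank missing kind {kind!r}; has {sorted(noise_bank)}")
        trace = noise_bank[kind]
        if len(trace) < n:
            raise ArgumentError(
                f"bank trace for {kind!r} too short: {len(trace)} < window {n}")
        offset = int(rng.integers(0, len(trace) - n + 1))
        slices.append(NoiseTrace(kind=kind, samples=trace.samples[offset:offset + n],
                                 fs=trace.fs))
    mixed = mix_noise_components(slices, [w for _, w in recipe.components])
    alpha = compute_alpha(clean, mixed.samples, recipe.target_snr_db)
    noisy = clean + alpha * mixed.samples
    return NoiseSynthesisResult(noisy=noisy, alpha=alpha, recipe=recipe, noise_used=mixed)


#: The mixed-noise recipes studied at 0 dB, MA weighted highest.
STANDARD_MIXED_RECIPES = (
    NoiseRecipe(components=(("BW", 0.3), ("MA", 0.7)), target_snr_db=0.0),
    NoiseRecipe(components=(("EM", 0.3), ("MA", 0.7)), target_snr_db=0.0),
    NoiseRecipe(components=(("BW", 0.5), ("EM", 0.5)), target_snr_db=0.0),
    NoiseRecipe(components=(("BW", 0.25), ("EM", 0.25), ("MA", 0.5)), target_snr_db=0.0),
)
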