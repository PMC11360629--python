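"""Synthetic single-lead ECG and noise generation.

Every downstream stage — noise synthesis, segmentation, denoiser and
classifier training — can run on records produced here, with no external
download.  Beats are sums of Gaussian waves (P, Q, R, S, T); the five beat
classes differ by fixed, deterministic morphology presets chosen to be
separable rather than physiologically exact:

* ``N`` — canonical P-QRS-T complex;
* ``B`` — widened, notched QRS (merged bundle-branch block);
* ``V`` — wide, tall QRS, absent P wave, followed by a compensatory pause;
* ``A`` — premature beat (shortened preceding RR) with a shifted P wave;
* ``F`` — sample-wise average of the N and V templates.

Three noise archetypes mirror the stress-test noise kinds: baseline wander
(BW, sub-0.5 Hz sinusoids), muscle artifact (MA, burst-gated 5-50 Hz
Gaussian noise) and electrode motion (EM, sparse baseline steps plus spike
transients).  One integer seed drives a separate named substream per
component, so e.g. changing the noise seed path never shifts beat timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ArgumentError
from .records import BEAT_CLASSES, BeatAnnotation, ECGRecord

NOISE_KINDS = ("BW", "EM", "MA")

# Per-wave parameters: (amplitude mV, offset from R peak in s, width in s).
# One preset per beat class; F is derived from N and V below.
_BASE_WAVES = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.030, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.20, 0.030, 0.010),
    "T": (0.30, 0.25, 0.045),
}

MORPHOLOGY: Dict[str, Dict[str, tuple]] = {
    "N": dict(_BASE_WAVES),
    # widened, notched QRS: broad R split into two lobes
    "B": {
        "P": (0.12, -0.22, 0.028),
        "Q": (-0.12, -0.050, 0.018),
        "R": (0.75, -0.012, 0.022),
        "R2": (0.55, 0.028, 0.020),
        "S": (-0.25, 0.065, 0.020),
        "T": (0.25, 0.30, 0.055),
    },
    # ventricular: wide tall QRS, no P
    "V": {
        "Q": (-0.25, -0.055, 0.025),
        "R": (1.40, 0.0, 0.035),
        "S": (-0.45, 0.060, 0.030),
        "T": (-0.35, 0.28, 0.060),
    },
    # atrial premature: P shifted close to QRS
    "A": {
        "P": (0.18, -0.12, 0.020),
        "Q": (-0.10, -0.030, 0.010),
        "R": (0.95, 0.0, 0.012),
        "S": (-0.20, 0.030, 0.010),
        "T": (0.28, 0.24, 0.045),
    },
}


@dataclass
class SyntheticECGConfig:
    """Configuration of the synthetic ECG generator.

    ``class_mix`` gives per-class beat probabilities over N/B/V/A/F and must
    sum to one.  ``rr_jitter`` is the coefficient of variation of the RR
    interval.  The same seed always reproduces the same record.
    """

    fs: float = 360.0
    duration_s: float = 60.0
    mean_rr_s: float = 0.8
    rr_jitter: float = 0.05
    class_mix: Dict[str, float] = field(default_factory=lambda: {"N": 1.0})
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ArgumentError(f"class_mix must sum to 1, got {total}")
        unknown = set(self.class_mix) - set(BEAT_CLASSES)
        if unknown:
            raise ArgumentError(f"unknown beat classes in class_mix: {unknown}")
        if self.duration_s * self.fs < 1024:
            raise ArgumentError("record must be at least one 1024-sample window long")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream: independent of sibling streams under one seed."""
    key = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def beat_template(cls: str, fs: float, half_width_s: float = 0.45) -> np.ndarray:
    """Gaussian-sum waveform of one beat of class ``cls``, centred on the R peak."""
    t = np.arange(-half_width_s, half_width_s, 1.0 / fs)
    if cls == "F":  # fusion of ventricular and normal
        return 0.5 * (beat_template("N", fs, half_width_s) + beat_template("V", fs, half_width_s))
    waves = MORPHOLOGY[cls]
    out = np.zeros_like(t)
    for amp, mu, sigma in waves.values():
        out += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return out


def generate_clean_ecg(config: SyntheticECGConfig) -> ECGRecord:
    """Generate an annotated clean synthetic record.

    Beat classes are drawn i.i.d. from ``class_mix``; RR intervals are
    Gaussian around ``mean_rr_s`` (A beats arrive premature at 70% of the
    drawn interval, V beats are followed by a 1.35x compensatory pause).
    One annotation is placed at each R-peak sample, carrying the generating
    class as both raw symbol and mapped class.
    """
    rng_cls = _substream(config.seed, "beats")
    rng_rr = _substream(config.seed, "jitter")
    fs = config.fs
    n = int(round(config.duration_s * fs))
    sig = np.zeros(n)

    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    templates = {c: beat_template(c, fs) for c in set(classes)}

    anns = []
    t_r = config.mean_rr_s  # first R peak
    prev_was_v = False
    while True:
        cls = classes[rng_cls.choice(len(classes), p=probs)]
        rr = config.mean_rr_s * (1.0 + config.rr_jitter * rng_rr.standard_normal())
        rr = max(rr, 0.3)
        if cls == "A":
            t_r_this = t_r - 0.3 * rr  # premature arrival
        else:
            t_r_this = t_r
        if prev_was_v:
            t_r_this += 0.35 * rr  # compensatory pause after a V beat
        idx = int(round(t_r_this * fs))
        if idx >= n - 1:
            break
        tpl = templates[cls]
        half = len(tpl) // 2
        lo, hi = idx - half, idx - half + len(tpl)
        s_lo, s_hi = max(lo, 0), min(hi, n)
        sig[s_lo:s_hi] += tpl[s_lo - lo : len(tpl) - (hi - s_hi)]
        if idx >= 0:
            anns.append(BeatAnnotation(sample_index=idx, raw_symbol=cls, mapped_class=cls))
        prev_was_v = cls == "V"
        t_r = t_r_this + rr

    anns.sort(key=lambda a: a.sample_index)
    return ECGRecord(
        record_id=f"synth{config.seed}",
        fs=fs,
        signal=sig,
        channel_name="MLII",
        annotations=anns,
    )


@dataclass(frozen=True)
class NoiseTrace:
    """A generated noise trace of one kind (or MIXED after weighting)."""

    kind: str
    samples: np.ndarray
    fs: float
    seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if len(self.samples) == 0:
            raise ArgumentError("noise trace must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ArgumentError("noise trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.samples)


def generate_noise(kind: str, n_samples: int, fs: float = 360.0, seed: int = 0) -> NoiseTrace:
    """Generate one of the three noise archetypes.

    BW: sum of eight sinusoids with frequencies below 0.5 Hz and random
    phases.  MA: 5-50 Hz band-limited Gaussian noise gated by smooth random
    bursts.  EM: a sparse random step process plus occasional spike
    transients.  Deterministic under ``seed``; traces are scaled to unit RMS.
    """
    if n_samples <= 0:
        raise ArgumentError(f"n_samples must be positive, got {n_samples}")
    if kind not in NOISE_KINDS:
        raise ArgumentError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    rng = _substream(seed, f"noise-{kind}")
    t = np.arange(n_samples) / fs

    if kind == "BW":
        freqs = rng.uniform(0.05, 0.45, size=8)
        phases = rng.uniform(0, 2 * np.pi, size=8)
        amps = rng.uniform(0.5, 1.0, size=8)
        x = np.sum([a * np.sin(2 * np.pi * f * t + p)
                    for a, f, p in zip(amps, freqs, phases)], axis=0)
    elif kind == "MA":
        white = rng.standard_normal(n_samples)
        nyq = fs / 2
        sos = butter(4, [5 / nyq, min(50 / nyq, 0.99)], btype="band", output="sos")
        band = sosfiltfilt(sos, white) if n_samples > 30 else white
        # smooth on/off burst gate, ~50% duty cycle
        gate_rate = 0.5  # bursts per second
        n_knots = max(int(gate_rate * n_samples / fs) + 2, 4)
        knots = rng.uniform(size=n_knots) > 0.5
        gate = np.interp(np.linspace(0, 1, n_samples),
                         np.linspace(0, 1, n_knots), knots.astype(float))
        x = band * (0.2 + 0.8 * gate)
    else:  # EM
        step_prob = 0.5 / fs  # ~0.5 steps per second
        impulses = rng.standard_normal(n_samples) * (rng.uniform(size=n_samples) < step_prob)
        steps = np.cumsum(impulses)
        steps -= steps.mean()
        spike_prob = 0.3 / fs
        spikes = (rng.uniform(size=n_samples) < spike_prob) * rng.standard_normal(n_samples) * 5.0
        x = steps + spikes

    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms
    return NoiseTrace(kind=kind, samples=x, fs=fs, seed=seed)


def default_noise_bank(n_samples: int, fs: float = 360.0, seed: int = 0) -> Dict[str, NoiseTrace]:
    """One trace of each kind, long enough to contaminate ``n_samples`` windows."""
    return {k: generate_noise(k, n_samples, fs, seed) for k in NOISE_KINDS}
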