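# ecganoise

Single-lead ECG denoising and beat classification for noisy, continuously
recorded signals — the kind produced by wearable patches, where baseline
wander (BW), electrode motion (EM) and muscle artifact (MA) routinely bury
the waveform that a rhythm classifier needs.

The package implements the full offline pipeline:

* **SNR-controlled noise synthesis** — a clean window `S(t)` is contaminated
  as `N(t) = S(t) + α·n(t)` with the noise weight
  `α = sqrt(ΣS² / (10^(SNR/10)·Σn²))`, so the achieved SNR equals the
  target *exactly*, for single or mixed noise (e.g. `0.3·BW + 0.7·MA`).
* **LSGAN denoising** — a 1D U-Net generator built from residual blocks
  (with a global identity shortcut) against a convolutional least-squares
  discriminator. The generator loss augments the adversarial term with
  distance information: `L_G = ½E[(D(G(z))−1)²] + 0.7·L_dist +
  0.3·L_dist-max`, where `L_dist` is the summed squared sample difference
  to the clean window and `L_dist-max` its maximum absolute deviation.
* **Fixed-window segmentation** — 1024-sample windows at a 180-sample
  stride, min–max normalized from the noisy member, split into two
  512-sample halves labeled by the earliest beat annotation (classes N, B,
  V, A, F; half-open windows, first-beat rule).
* **1D ResNet beat classification** with transfer learning (layer freezing,
  output-head remapping when a class is absent).
* **Metrics** — PRD, SNR, RMSE with their mutual identities
  (`SNR = −20·log10(PRD/100)`), and per-class / unweighted-macro
  precision, recall and F1.
* **Synthetic fixtures** — annotated Gaussian-wave ECG and all three noise
  archetypes, so everything above runs and is tested without downloading
  anything. Real WFDB records (`.hea`/`.dat` format 212 + `.atr`) are read
  and written natively.

Model training follows a fit/results convention: `DenoisingGAN(pairs).fit()`
returns a `DenoiserResults` (loss history, `denoise()`, `summary()`,
checkpoint I/O) and `BeatClassifier(segments).fit()` returns a
`ClassifierResults` (`predict`, `predict_proba`, `report`, `summary`).
The neural networks run on a compact numpy autodiff engine shipped in
`ecganoise.nn`, gradient-checked against finite differences.

## Worked example

```python
import numpy as np
from ecganoise import (SyntheticECGConfig, generate_clean_ecg,
                       default_noise_bank, NoiseRecipe, contaminate_record,
                       DenoisingGAN, GeneratorSpec, DiscriminatorSpec,
                       snr)
from ecganoise.denoiser import TrainingConfig

mix = {"N": 0.6, "B": 0.1, "V": 0.15, "A": 0.1, "F": 0.05}
rec = generate_clean_ecg(SyntheticECGConfig(duration_s=520.0, class_mix=mix, seed=11))
bank = default_noise_bank(200_000, seed=12)
pairs = contaminate_record(rec, NoiseRecipe.single("BW", 0.0), bank, seed=13)

train, test = pairs[:800], pairs[800:]
res = DenoisingGAN(train,
                   GeneratorSpec(depth=4, filters_per_level=(8, 16, 24, 32), kernel_size=9),
                   DiscriminatorSpec(layers=((8, 9, 2), (16, 9, 2))),
                   train_cfg=TrainingConfig(batch_size=32)).fit(epochs=3, seed=0)

clean = np.stack([p.clean for p in test])
noisy = np.stack([p.noisy for p in test])
denoised = res.denoise(noisy)
before = np.mean([snr(c, n) for c, n in zip(clean, noisy)])
after = np.mean([snr(c, d) for c, d in zip(clean, denoised)])
print(f"mean window SNR: {before:.2f} dB noisy -> {after:.2f} dB denoised")
```

```
mean window SNR: 8.14 dB noisy -> 16.89 dB denoised
```

Every window was contaminated at exactly 0 dB against the raw clean signal;
the printed baseline is higher because SNR is measured on the min–max
normalized scale, whose offset adds signal energy without adding residual.
Three epochs of the tiny desk-scale model recover roughly +9 to +10 dB
depending on the beat mix and seed; the method at full scale on the real
arrhythmia/noise-stress databases is reported well above 30 dB.

A command-line interface covers the same pipeline stage by stage
(`ecganoise fixtures | synth | segment | train-denoiser | train-classifier
| transfer | predict | evaluate | stream-sim`); `stream-sim` replays a
record window-by-window, emitting per-window denoised output and beat
predictions identical to batch processing.

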