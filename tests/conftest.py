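import numpy as np
import pytest

from ecganoise.fixtures import (SyntheticECGConfig, default_noise_bank,
                                generate_clean_ecg)


@pytest.fixture(scope="session")
def clean_record():
    """Two minutes of all-normal synthetic ECG at 360 Hz."""
    return generate_clean_ecg(SyntheticECGConfig(duration_s=120.0, seed=7))


@pytest.fixture(scope="session")
def mixed_record():
    """Synthetic record containing all five beat classes."""
    cfg = SyntheticECGConfig(
        duration_s=240.0,
        class_mix={"N": 0.6, "B": 0.1, "V": 0.15, "A": 0.1, "F": 0.05},
        seed=21,
    )
    return generate_clean_ecg(cfg)


@pytest.fixture(scope="session")
def noise_bank():
    return default_noise_bank(120_000, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
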