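import numpy as np
import pytest

from sscnn import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def tiny_clean_dataset():
    """3x12 noise-free images: separable by construction."""
    cfg = SyntheticConfig(n_per_class=12, image_size=32, noise_sd=0.0, seed=42)
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """3x30 images at mild noise for loop-level tests."""
    cfg = SyntheticConfig(n_per_class=30, image_size=32, noise_sd=0.05, seed=7)
    return generate_synthetic_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
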