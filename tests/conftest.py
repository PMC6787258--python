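import numpy as np
import pytest

from bucklesense import BuckleProfile, GeneratorConfig


@pytest.fixture(scope="session")
def profile() -> BuckleProfile:
    """Reference buckle: 10% compression, one period of 37.8 nm arc length."""
    return BuckleProfile.from_gamma(0.1, 37.8)


@pytest.fixture(scope="session")
def clean_cfg() -> GeneratorConfig:
    """Noiseless generator configuration for exact round-trip checks."""
    return GeneratorConfig(noise_sigma=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
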