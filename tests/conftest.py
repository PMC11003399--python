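import numpy as np
import pytest

from aoholo.field_model import OpticalConfig, default_config


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    """Default study geometry: N=1024, D=256 samples, 0.125 um pitch."""
    return default_config()


@pytest.fixture(scope="session")
def small_optics() -> OpticalConfig:
    """Scaled-down geometry for 2D-heavy tests (same pitch and D/N ratio)."""
    return OpticalConfig.from_target_pitch(0.125, grid_size=256, aperture_samples=64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
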