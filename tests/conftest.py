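import numpy as np
import pytest

from leafwater import SimConfig, simulate_sample_table
from leafwater.grid import default_grid


@pytest.fixture
def small_config():
    """80-band config spanning the full NIR range (covers the NISDI anchors)."""
    return SimConfig(n_bands=80)


@pytest.fixture
def quiet_config():
    """Noiseless, scatter-free config: the deterministic spectral model."""
    return SimConfig(n_bands=80).without_noise()


@pytest.fixture
def small_table(small_config):
    return simulate_sample_table(60, small_config, seed=11)


@pytest.fixture
def grid80():
    return default_grid(80, 900.0, 1700.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
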