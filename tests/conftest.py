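import numpy as np
import pytest

from paca import SimulationConfig, simulate_dataset
from paca.algorithm import center_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_centered_pair(rng):
    """Well-conditioned centered matrices in the tall (m > n) regime."""
    Xc = center_columns(rng.standard_normal((200, 30)))
    Yc = center_columns(rng.standard_normal((200, 30)))
    return Xc, Yc


@pytest.fixture(scope="session")
def signal_dataset():
    """Default signal regime: 3 dominant shared axes, one subtle case axis."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_signal_dataset():
    """Smaller signal-regime dataset for cheap end-to-end tests."""
    return simulate_dataset(SimulationConfig(
        m=300, n1=60, n0=60, k0=2, k1=1,
        shared_scales=50.0, case_scales=8.0, sigma=1.0, seed=7,
    ))
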