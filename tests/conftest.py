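import numpy as np
import pytest

from phenofuse.calibration import LandscapeConfig
from phenofuse.synthetic import simulate


@pytest.fixture(scope="session")
def small_landscape():
    """A compact landscape with all three sensor stacks (40x40 target cells)."""
    return simulate(LandscapeConfig(size_cells=40), rng_seed=1)


@pytest.fixture(scope="session")
def noiseless_landscape():
    """Noise-, bias- and cloud-free landscape for closed-loop checks."""
    return simulate(LandscapeConfig(size_cells=30).noiseless(), rng_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
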