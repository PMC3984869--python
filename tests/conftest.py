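import numpy as np
import pytest

from ttclust.cbf import CbfConfig, generate_cbf
from ttclust.cbf import generate_blocks


@pytest.fixture(scope="session")
def small_cbf():
    """90-series CBF dataset shared by the slower integration tests."""
    return generate_cbf(CbfConfig(counts=(30, 30, 30), seed=7))


@pytest.fixture(scope="session")
def easy_blocks():
    """Well-separated 3-group fixture where every method should be exact."""
    return generate_blocks(3, 5, separation=10.0, noise_sd=0.1, length=16, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
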