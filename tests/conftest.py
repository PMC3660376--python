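import numpy as np
import pytest

from amitosim import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small, fast configuration for engine-level tests."""
    return SimParams(pop_size=100, n_iter=300, seed=7)
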