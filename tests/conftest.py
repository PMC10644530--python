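import numpy as np
import pytest

from genebirth import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small, fast configuration for mechanism tests."""
    return SimConfig(N=50, T=40, regime="high", d=0.0)
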