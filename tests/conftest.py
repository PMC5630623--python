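import numpy as np
import pytest

from bnnpt import BNNPTConfig, PairedSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sample(rng):
    """A generic dependent sample with distinct x values."""
    x = np.sort(rng.uniform(-1, 1, 30))
    y = np.sin(np.pi * x) + rng.normal(0, 0.5, 30)
    return PairedSample(x=x, y=y)


@pytest.fixture
def default_config():
    return BNNPTConfig(seed=99)
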