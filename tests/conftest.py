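import numpy as np
import pytest

from nlmdct import add_rician, brain_phantom, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_t1_128():
    """Deterministic 128x128 T1-like phantom (t = 150) used by the heavier tests."""
    return make_phantom(brain_phantom("T1", 128, 128))


@pytest.fixture(scope="session")
def phantom_t1_default():
    """Full-size (181x217) T1-like phantom."""
    return make_phantom(brain_phantom("T1"))


def make_noisy(clean, level_percent, t, seed):
    return add_rician(clean, level_percent / 100.0 * t, seed)
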