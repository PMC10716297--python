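import numpy as np
import pytest
from hypothesis import settings

import hopmem as hm

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# Reference pairwise Hamming distances of the bundled A-J character set
# (rows/cols in label order A..J).
CHARSET_HD = np.array([
    [0, 44, 36, 36, 56, 57, 24, 46, 68, 56],
    [44, 0, 34, 10, 20, 27, 32, 24, 58, 50],
    [36, 34, 0, 28, 42, 45, 16, 54, 48, 46],
    [36, 10, 28, 0, 26, 33, 30, 34, 60, 56],
    [56, 20, 42, 26, 0, 13, 46, 24, 50, 48],
    [57, 27, 45, 33, 13, 0, 53, 27, 49, 43],
    [24, 32, 16, 30, 46, 53, 0, 48, 56, 50],
    [46, 24, 54, 34, 24, 27, 48, 0, 66, 52],
    [68, 58, 48, 60, 50, 49, 56, 66, 0, 28],
    [56, 50, 46, 56, 48, 43, 50, 52, 28, 0],
])


@pytest.fixture(scope="session")
def charset():
    return hm.builtin_charset()


@pytest.fixture(scope="session")
def noise_testset(charset):
    """Shared default-size corrupted test set (8,000 items)."""
    return hm.make_noise_testset(charset, rng=np.random.default_rng(20240517))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
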