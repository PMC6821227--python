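import numpy as np
import pytest

from gtascan.synthetic import block_distance_matrix, sample_training_set


@pytest.fixture(scope="session")
def skewed_training_set():
    """60+60 GTA/virus records from Ala/Gly-skewed profiles (seed 1)."""
    return sample_training_set(0.5, 60, rng=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_block_matrix():
    """Two tight blocks of 5 (intra 0.01) far apart (inter 1.0)."""
    return block_distance_matrix([5, 5], intra=0.01, inter=1.0, rng=0)
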