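import numpy as np
import pytest

from gengrad import default_config, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """12 subjects x 10 stimuli from the reference generator."""
    cfg = default_config(n_subjects=12, seed=3)
    return simulate_dataset(cfg, rng)


@pytest.fixture
def medium_dataset():
    """40 subjects x 10 stimuli with a real cross-level interaction."""
    cfg = default_config(n_subjects=40, gamma11=0.10, seed=17)
    return simulate_dataset(cfg, np.random.default_rng(17))
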