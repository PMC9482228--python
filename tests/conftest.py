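import numpy as np
import pytest

from volnorm import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_known():
    return syn.toy_known_params()


@pytest.fixture(scope="session")
def small_noisy_v1():
    """One modest v1 replicate shared by fitting tests."""
    return syn.simulate_v1(n_metabolites=10, n_timepoints=20, seed=2024)
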