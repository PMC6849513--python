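import numpy as np
import pytest

from multicue import Hyperparameters, build_lexicon


@pytest.fixture(scope="session")
def lexicon100():
    return build_lexicon(100, seed=12345)


@pytest.fixture(scope="session")
def lexicon10():
    return build_lexicon(10, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_hp():
    """5-input / 3-hidden / 2-output net for gradient-oracle tests."""
    return Hyperparameters(n_input=5, n_hidden=3, n_semantic=2, learning_rate=0.1)


@pytest.fixture
def small_hp():
    """10-word-scale net that trains in seconds."""
    return Hyperparameters(n_input=82, n_hidden=20, n_semantic=10, learning_rate=0.1)
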