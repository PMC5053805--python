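import numpy as np
import pytest

from seqdecode import make_preset_session


@pytest.fixture(scope="session")
def early_session():
    """Medium early-encoding session shared across test modules."""
    return make_preset_session("early_encoding", seed=7, n_units=12, n_trials=300)


@pytest.fixture(scope="session")
def seq_session():
    return make_preset_session("sequences_only", seed=11, n_units=10, n_trials=200)


@pytest.fixture(scope="session")
def null_session():
    return make_preset_session("null", seed=5, n_units=6, n_trials=80)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
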