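import numpy as np
import pytest

from burstdecode import pipeline as pl
from burstdecode import simulate as sim


@pytest.fixture(scope="session")
def small_session():
    """A short decodable session shared by the integration-style tests."""
    return sim.simulate_session(n_lists=4, n_channels=2, seed=123,
                                hg_effect=(3.0, 1.0), recall_p=0.4)


@pytest.fixture(scope="session")
def small_datasets(small_session):
    return pl.session_to_datasets(small_session, tensor_fs=20.0, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
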