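import numpy as np
import pytest

from porekin.hmm import HmmModel
from porekin.synthetic import SyntheticConfig, default_models


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wt_model():
    return default_models()[0]


@pytest.fixture(scope="session")
def mut_model():
    return default_models()[1]


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig()


def random_model(rng, K, spread=0.6):
    """Random valid K-state model with distinct, sorted emission means."""
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    q = np.sort(rng.uniform(0, spread, K))
    q += np.arange(K) * 1e-3          # guarantee strict ordering
    b = rng.uniform(0.02, 0.15, K)
    return HmmModel(pi=pi, A=A, q=q, b=b).validate()
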