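import numpy as np
import pytest

from bbqrisk import default_config
from bbqrisk.synthetic import GroundTruth


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def population_small(cfg):
    """A modest fixed population reused by risk-engine tests."""
    from bbqrisk.exposure import simulate_population

    return simulate_population(800, cfg, seed=11)
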