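import numpy as np
import pytest

from phyloquartet.models import empirical_synthetic_model, poisson_model


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def poisson_gamma():
    return poisson_model(gamma_shape=0.8)


@pytest.fixture(scope="session")
def empirical():
    return empirical_synthetic_model()


@pytest.fixture(scope="session")
def empirical_gamma():
    return empirical_synthetic_model(gamma_shape=0.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
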