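import numpy as np
import pytest

from myelopt.model import (
    cancerous_equilibrium,
    default_parameters,
    null_n_parameters,
)


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def null_params():
    return null_n_parameters()


@pytest.fixture(scope="session")
def cancer_eq(default_params):
    return cancerous_equilibrium(default_params)


@pytest.fixture(scope="session")
def null_cancer_eq(null_params):
    return cancerous_equilibrium(null_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240811)
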