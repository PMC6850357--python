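import numpy as np
import pytest

from zipne.data_model import ParameterSet
from zipne.fixtures import micro_datasets, micro_params
from zipne.quadrature import gh_rule


@pytest.fixture(scope="session")
def rule101():
    return gh_rule(101)


@pytest.fixture(scope="session")
def micro():
    """Named micro datasets with matching interior parameter sets."""
    out = {}
    for name, data in micro_datasets().items():
        out[name] = (data, ParameterSet(**micro_params(data.T)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20251002)
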