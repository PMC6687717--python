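import numpy as np
import pytest

from pubtcr.io import SampleMeta
from pubtcr.simulate import simulate_germline


@pytest.fixture(scope="session")
def germline():
    """Small simulated germline shared across tests."""
    return simulate_germline(1, n_v=5, n_j=3)


@pytest.fixture
def blister_meta():
    return SampleMeta(
        sample_id="S1", cohort="case", phenotype="SJS/TEN",
        drug="CBZ", tissue="blister", hla_flag=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
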