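import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from splicebench import consensus_acceptor_model, consensus_donor_model, generate_gene

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def donor_model():
    return consensus_donor_model()


@pytest.fixture(scope="session")
def acceptor_model():
    return consensus_acceptor_model()


@pytest.fixture(scope="session")
def small_gene():
    """A fixed synthetic 5-exon gene with its transcript model."""
    sequence, transcript = generate_gene(11)
    return sequence, transcript


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
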