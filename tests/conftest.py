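import numpy as np
import pytest
from hypothesis import settings

from fracsir.model import SIRParameters
from fracsir.wavelets import HybridBasis, build_basis, make_filter

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db4():
    return make_filter(4)


@pytest.fixture(scope="session")
def basis_unit(db4):
    """Periodized db4 basis at level 4 on [0, 1]."""
    return build_basis(db4, 1.0, 4)


@pytest.fixture(scope="session")
def hybrid_unit(basis_unit):
    return HybridBasis(basis_unit)


@pytest.fixture(scope="session")
def base_params():
    return SIRParameters(beta=5e-4, gamma=0.1, delta=0.05, alpha=0.9,
                         tau=2.0, N=700.0, T=10.0)


@pytest.fixture(scope="session")
def midpoint_nodes():
    def make(n, T=10.0):
        return (np.arange(n) + 0.5) * T / n
    return make
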