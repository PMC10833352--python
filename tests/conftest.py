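import numpy as np
import pytest

from jointxn.fixtures import make_toy_structure, simulate_data
from jointxn.model_core import build_exchange_sites


@pytest.fixture(scope="session")
def peptide5():
    """Five-residue fixture (one of each residue type), hydrogenated."""
    return make_toy_structure(5, seed=11, n_waters=3)


@pytest.fixture(scope="session")
def exchanged5(peptide5):
    """Same fixture with H/D exchange sites at labile positions."""
    return build_exchange_sites(peptide5, "all-labile")


@pytest.fixture(scope="session")
def neutron_data5(exchanged5):
    """Noise-free complete 2.5 A neutron amplitudes from the fixture."""
    return simulate_data(exchanged5, "neutron", d_min=2.5, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
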