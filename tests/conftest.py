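import numpy as np
import pytest

from openps.search import SearchConfig, build_index
from openps.synthetic_data import SimConfig, make_library, simulate_run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_small():
    return SimConfig(
        seed=7, n_proteins=20, n_absent_proteins=8,
        protein_length=(80, 300), n_spectra=250, n_blank_spectra=60,
    )


@pytest.fixture(scope="session")
def library_small(sim_small):
    return make_library(sim_small)


@pytest.fixture(scope="session")
def index_small(library_small):
    return build_index(library_small, SearchConfig())


@pytest.fixture(scope="session")
def run_small(library_small, sim_small):
    return simulate_run(library_small, sim_small)


def random_peptide(rng, length):
    from openps.constants import VALID_RESIDUES

    return "".join(rng.choice(sorted(VALID_RESIDUES), size=length))
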