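import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from moietherm import build_incidence, parse_compound
from moietherm.fixtures import (
    ENANTIOMER_PAIR,
    EPI_ISOZIZAENE_SMILES,
    fixture_pseudoisomer_specs,
    generate_corpus,
)


@pytest.fixture(scope="session")
def epi_isozizaene():
    return parse_compound("EPI", EPI_ISOZIZAENE_SMILES)


@pytest.fixture(scope="session")
def enantiomer_records():
    r, s = ENANTIOMER_PAIR
    return parse_compound("BUTR", r), parse_compound("BUTS", s)


@pytest.fixture(scope="session")
def small_corpus():
    """40 molecules, 200 reactions, 1 kJ/mol noise."""
    return generate_corpus(n_molecules=40, n_reactions=200, noise_sd=1.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_corpus():
    return generate_corpus(n_molecules=40, n_reactions=200, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def incidence_r1(small_corpus):
    return small_corpus.incidence


@pytest.fixture(scope="session")
def pseudo_specs():
    return fixture_pseudoisomer_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
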