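import numpy as np
import pytest

from tkicombo import datasets


@pytest.fixture(scope="session")
def pk_table():
    return datasets.load_pk_table()


@pytest.fixture(scope="session")
def mutant_table():
    return datasets.load_mutant_table()


@pytest.fixture(scope="session")
def wildtype_potencies():
    return datasets.load_wildtype_potencies()


@pytest.fixture(scope="session")
def norm_potencies(pk_table):
    return datasets.normalised_potencies(pk_table)


@pytest.fixture(scope="session")
def t315i(mutant_table):
    return datasets.mutant_profile("T315I", mutant_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
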