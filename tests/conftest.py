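import pytest

from commflux import community_builder as cb
from commflux import synthetic_data as syn


@pytest.fixture(scope="session")
def toy_chain():
    return syn.toy_chain()


@pytest.fixture(scope="session")
def toy_azo():
    return syn.toy_azo()


@pytest.fixture(scope="session")
def toy_glycolysis():
    return syn.toy_glycolysis()


@pytest.fixture(scope="session")
def toy_futile():
    return syn.toy_futile()


@pytest.fixture(scope="session")
def levo_pair():
    return syn.toy_levo_pair()


@pytest.fixture(scope="session")
def drugs():
    return syn.standard_drug_modules()


@pytest.fixture(scope="session")
def western_diet():
    return syn.western_diet()


@pytest.fixture(scope="session")
def azo_community(toy_azo):
    return cb.assemble_community({"Azoreducens toy": toy_azo},
                                 {"Azoreducens toy": 1.0})


@pytest.fixture(scope="session")
def levo_community(levo_pair):
    a, b = levo_pair
    return cb.assemble_community(
        {"Levoa prima": a, "Levob secunda": b},
        {"Levoa prima": 0.2, "Levob secunda": 0.8})
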