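import pytest

from selnet.fixtures import make_mkmn_pair, make_toy_stoich

CHAIN_RULES = "input a = 1\nb = a\nt = b\n"


@pytest.fixture(scope="session")
def mkmn_pair():
    return make_mkmn_pair()


@pytest.fixture(scope="session")
def chain_model():
    return make_toy_stoich("chain")


@pytest.fixture(scope="session")
def parallel_model():
    return make_toy_stoich("parallel")


@pytest.fixture(scope="session")
def cycle_model():
    return make_toy_stoich("cycle")
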