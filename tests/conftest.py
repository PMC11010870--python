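import pytest

from mtmap.boolnet import parse_bnet
from mtmap.fixtures import make_conflict_network, make_exemplar_network, make_toggle


@pytest.fixture(scope="session")
def toggle():
    return make_toggle()


@pytest.fixture(scope="session")
def conflict():
    return make_conflict_network()


@pytest.fixture(scope="session")
def exemplar():
    return make_exemplar_network()


@pytest.fixture(scope="session")
def oscillator():
    return parse_bnet("A, !C\nB, A\nC, B")
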