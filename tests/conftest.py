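import pytest

from nsilink import Graph, erdos_renyi


@pytest.fixture
def path4():
    """Path 1–2–3–4."""
    return Graph(edges=[("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture
def path3():
    """Path 1–2–3."""
    return Graph(edges=[("1", "2"), ("2", "3")])


@pytest.fixture
def triangle():
    return Graph(edges=[("1", "2"), ("2", "3"), ("1", "3")])


@pytest.fixture
def star4():
    """Star: center c with leaves 1..4."""
    return Graph(edges=[("c", str(i)) for i in range(1, 5)])


@pytest.fixture
def cycle4():
    return Graph(edges=[("1", "2"), ("2", "3"), ("3", "4"), ("1", "4")])


@pytest.fixture(scope="session")
def er30():
    return erdos_renyi(30, 0.2, 8)
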