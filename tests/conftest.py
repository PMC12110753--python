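import pytest

from causalspace import Dag, enumerate_dags, partition_by_equivalence
from causalspace.dag import independence_statements


@pytest.fixture
def chain():
    return Dag("ABC", [("A", "B"), ("B", "C")])


@pytest.fixture
def fork():
    return Dag("ABC", [("B", "A"), ("B", "C")])


@pytest.fixture
def collider():
    return Dag("ABC", [("A", "B"), ("C", "B")])


@pytest.fixture(scope="session")
def dags3():
    return enumerate_dags("ABC")


@pytest.fixture(scope="session")
def partition3(dags3):
    return partition_by_equivalence(dags3)


@pytest.fixture(scope="session")
def dags4():
    return enumerate_dags("ABCD")


@pytest.fixture(scope="session")
def indep4(dags4):
    """Cached independence sets for every 4-node DAG (shared across the
    exhaustive tests)."""
    return {g: independence_statements(g) for g in dags4}
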