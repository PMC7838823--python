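import pytest

from cosmos.graph import CausalPKN, SignedEdge
from cosmos.synthetic import generate_preset_study, generate_random_instance

# shared by the solver tests and the acceptance suite
random_instance = generate_random_instance


@pytest.fixture(scope="session")
def tiny_study():
    return generate_preset_study("tiny", seed=7)


@pytest.fixture(scope="session")
def small_study():
    return generate_preset_study("small", seed=11)


@pytest.fixture
def chain_pkn():
    """Directed +1 chain of 10 nodes n0 -> n1 -> ... -> n9."""
    edges = [SignedEdge(f"n{i}", 1, f"n{i+1}") for i in range(9)]
    return CausalPKN(edges)
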