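import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def graph_from_edges(edges) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


K4_EDGES = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]


@pytest.fixture
def k4_plus_full_fifth() -> nx.Graph:
    """A 4-clique abcd with a fifth node e adjacent to all four (a 5-clique)."""
    return graph_from_edges(
        K4_EDGES + [("e", "a"), ("e", "b"), ("e", "c"), ("e", "d")]
    )


@pytest.fixture
def dense_core_with_sparse_residue(k4_plus_full_fifth) -> nx.Graph:
    """A complex graph with a dense 5-clique core and a sparse 4-cycle residue.

    The residue f-g-h-i is internally connected (a 4-cycle, so triangle-free
    and without any 4-clique) but carries no edge into the dense part, so the
    extension of the core stops at 5 nodes and the residue must be abandoned.
    """
    g = k4_plus_full_fifth
    g.add_edges_from([("f", "g"), ("g", "h"), ("h", "i"), ("f", "i")])
    return g
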