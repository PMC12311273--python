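import numpy as np
import pytest

from pathprop import (GeneScoreVector, Pathway, PathwayCollection, PPINetwork,
                      normalize_symmetric)


@pytest.fixture
def two_node_net():
    """Single edge A-B with unit weight."""
    return PPINetwork.from_edges(["A", "B"], [("A", "B", 1.0)])


@pytest.fixture
def path_net():
    """Path A-B-C with unit weights (degrees 1, 2, 1)."""
    return PPINetwork.from_edges(["A", "B", "C"],
                                 [("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def isolated_net():
    """Edge A-B plus an isolated node Z."""
    return PPINetwork.from_edges(["A", "B", "Z"], [("A", "B", 1.0)])


def random_network(n: int, p: float, seed: int) -> PPINetwork:
    """Erdos-Renyi unit-weight network helper for property tests."""
    import networkx as nx

    g = nx.gnp_random_graph(n, p, seed=seed)
    names = [f"N{i}" for i in range(n)]
    return PPINetwork.from_edges(
        names, [(names[a], names[b], 1.0) for a, b in g.edges]
    )


def random_absolute_scores(net: PPINetwork, seed: int) -> GeneScoreVector:
    rng = np.random.default_rng(seed)
    return GeneScoreVector(list(net.nodes), rng.uniform(0, 5, net.n_nodes),
                           "absolute")


def propagated_vector(values, prefix: str = "G") -> GeneScoreVector:
    """Convenience wrapper: a propagated-provenance vector over G0, G1, ..."""
    values = np.asarray(values, dtype=float)
    return GeneScoreVector([f"{prefix}{i}" for i in range(values.size)],
                           values, "propagated")


def collection_of(*member_lists, prefix: str = "PW") -> PathwayCollection:
    return PathwayCollection([
        Pathway(f"{prefix}{i}", "", frozenset(m))
        for i, m in enumerate(member_lists)
    ])
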