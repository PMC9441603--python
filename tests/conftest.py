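import numpy as np
import pytest

from mirlink import AssociationTable, DiseaseDAG, SyntheticSpec, simulate_dataset


@pytest.fixture
def chain_dags():
    """Two chain descriptor DAGs sharing ancestors A <- B (<- C)."""
    d_i = DiseaseDAG("d_i", "C", frozenset("ABC"), frozenset({("A", "B"), ("B", "C")}))
    d_j = DiseaseDAG("d_j", "B", frozenset("AB"), frozenset({("A", "B")}))
    return d_i, d_j


@pytest.fixture
def tiny_corpus():
    """Three-disease corpus over terms {R, X, Y, Z}."""
    return [
        DiseaseDAG("X", "X", frozenset({"R", "X"}), frozenset({("R", "X")})),
        DiseaseDAG("Y", "Y", frozenset({"R", "Y"}), frozenset({("R", "Y")})),
        DiseaseDAG(
            "Z", "Z", frozenset({"R", "X", "Z"}), frozenset({("R", "X"), ("X", "Z")})
        ),
    ]


@pytest.fixture
def toy_assoc():
    return AssociationTable(("d1", "d2"), ("m1", "m2"), np.eye(2))


@pytest.fixture(scope="session")
def small_dataset():
    """20 x 30 planted dataset reused by the heavier evaluation tests."""
    return simulate_dataset(SyntheticSpec(n_diseases=20, n_mirnas=30, seed=3))


def random_dag(rng: np.random.Generator, n_terms: int, disease_id: str = None) -> DiseaseDAG:
    """Random acyclic descriptor DAG on at most n_terms terms.

    Terms are ordered; each non-root term gets one or two parents among
    lower-ordered terms, and the disease term is the last term, so every
    term is one of its ancestors (reachable down to it is not guaranteed
    for every term, hence the closure step below).
    """
    import networkx as nx

    names = [f"t{i}" for i in range(n_terms)]
    g = nx.DiGraph()
    g.add_node(names[0])
    for i in range(1, n_terms):
        parents = rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False)
        for p in parents:
            g.add_edge(names[p], names[i])
    leaf = names[-1]
    terms = nx.ancestors(g, leaf) | {leaf}
    edges = {(p, c) for p, c in g.edges if p in terms and c in terms}
    return DiseaseDAG(
        disease_id=disease_id or f"dis-{leaf}",
        disease_term=leaf,
        terms=frozenset(terms),
        edges=frozenset(edges),
    )
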