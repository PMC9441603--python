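"""Disease and miRNA similarity measures.

Three families of similarity feed the heterogeneous network:

* **Semantic similarity** between diseases, computed from each disease's
  MeSH-style descriptor DAG. Two measures are combined: Wang's measure,
  which credits shared ancestor terms with a contribution that decays by
  a factor theta per level, and Xuan's measure, which weights shared
  terms by their information content across the whole descriptor corpus
  (rarer terms count more). The combined score is their plain average.

* **Gaussian interaction profile kernel (GIPK)** similarity, an RBF
  kernel between binary association profiles, with a bandwidth
  normalized by the mean squared profile norm. It is defined for every
  disease and miRNA because it only needs the association matrix.

* **Integration**: the semantic (or functional) similarity is used where
  it is available; where it is structurally missing (exact zero — e.g. a
  disease with no descriptor), the GIPK value substitutes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AssociationTable, SimilarityMatrix

__all__ = [
    "DiseaseDAG",
    "SemanticProfile",
    "ICTable",
    "semantic_profile",
    "wang_similarity",
    "information_content",
    "xuan_similarity",
    "combined_semantic_similarity",
    "semantic_similarity_matrix",
    "gipk_disease",
    "gipk_mirna",
    "integrate_similarity",
]

DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's descriptor DAG: its own term plus all ancestors.

    ``edges`` are ordered (parent, child) pairs; parents are the more
    general terms. Every term other than the disease's own term must lie
    on a directed path down to the disease term, and the graph must be
    acyclic.
    """

    disease_id: str
    disease_term: str
    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if self.disease_term not in self.terms:
            raise ValueError(
                f"{self.disease_id}: disease term {self.disease_term!r} not in term set"
            )
        for parent, child in self.edges:
            if parent not in self.terms or child not in self.terms:
                raise ValueError(f"{self.disease_id}: edge ({parent}, {child}) leaves the term set")
        graph = self.graph()
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError(f"{self.disease_id}: descriptor graph contains a cycle")
        reachable = nx.ancestors(graph, self.disease_term) | {self.disease_term}
        unreachable = self.terms - reachable
        if unreachable:
            raise ValueError(
                f"{self.disease_id}: terms not on a path to the disease term: "
                f"{sorted(unreachable)}"
            )

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph over the DAG's terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SemanticProfile:
    """Per-term semantic contributions of one disease and their sum.

    The disease's own term contributes exactly 1; every ancestor
    contributes ``theta`` times the largest contribution among its
    children inside the DAG.
    """

    disease_id: str
    contributions: Mapping[str, float]
    semantic_value: float
    theta: float


@dataclass(frozen=True)
class ICTable:
    """Information content of descriptor terms over a DAG corpus.

    IC(t) = -log(fraction of DAGs whose term set contains t). Terms that
    appear in every DAG have IC 0; terms absent from the corpus are
    absent from the table. The logarithm base is recorded for
    reproducibility of the raw IC values; ratio-based similarity
    measures are base-invariant.
    """

    values: Mapping[str, float]
    corpus_size: int
    log_base: float = math.e


def semantic_profile(dag: DiseaseDAG, theta: float = DEFAULT_THETA) -> SemanticProfile:
    """Decayed semantic contribution of every term in a disease's DAG.

    Contributions are evaluated children-first (reverse topological
    order from the disease term): C(disease term) = 1, and for every
    ancestor t, C(t) = theta * max over children of t inside the DAG.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    graph = dag.graph()
    children: dict[str, list[str]] = {t: list(graph.successors(t)) for t in dag.terms}
    contributions: dict[str, float] = {}
    # Parents precede children in topological order; reverse it so every
    # child is evaluated before any of its parents.
    for term in reversed(list(nx.topological_sort(graph))):
        if term == dag.disease_term:
            contributions[term] = 1.0
        else:
            contributions[term] = theta * max(contributions[c] for c in children[term])
    return SemanticProfile(
        disease_id=dag.disease_id,
        contributions=contributions,
        semantic_value=float(sum(contributions.values())),
        theta=theta,
    )


def wang_similarity(p_i: SemanticProfile, p_j: SemanticProfile) -> float:
    """Wang's semantic similarity between two diseases (SS1).

    Sum of both diseases' contributions over shared terms, divided by
    the sum of the two semantic values. Disjoint term sets give 0;
    identical DAGs give 1.
    """
    if p_i.theta != p_j.theta:
        raise ValueError("profiles were built with different theta values")
    shared = p_i.contributions.keys() & p_j.contributions.keys()
    numerator = sum(p_i.contributions[t] + p_j.contributions[t] for t in shared)
    return numerator / (p_i.semantic_value + p_j.semantic_value)


def information_content(
    corpus: Sequence[DiseaseDAG], log_base: float = math.e
) -> ICTable:
    """Corpus-level information content of every descriptor term."""
    if not corpus:
        raise ValueError("corpus must be nonempty")
    counts: dict[str, int] = {}
    for dag in corpus:
        for term in dag.terms:
            counts[term] = counts.get(term, 0) + 1
    n = len(corpus)
    scale = math.log(log_base)
    # "+ 0.0" normalizes the -0.0 produced for ubiquitous terms.
    values = {t: -math.log(c / n) / scale + 0.0 for t, c in counts.items()}
    return ICTable(values=values, corpus_size=n, log_base=log_base)


def xuan_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG, ic: ICTable) -> float:
    """Xuan's IC-weighted semantic similarity between two diseases (SS2).

    Twice the summed IC of shared terms over the summed IC of both term
    sets. If every term of both diseases is ubiquitous (all ICs zero)
    the measure is undefined; 0 is returned with a warning.
    """
    missing = (dag_i.terms | dag_j.terms) - ic.values.keys()
    if missing:
        raise ValueError(f"terms absent from the IC table: {sorted(missing)}")
    denom = sum(ic.values[t] for t in dag_i.terms) + sum(
        ic.values[t] for t in dag_j.terms
    )
    if denom == 0.0:
        warnings.warn(
            f"all terms of {dag_i.disease_id} and {dag_j.disease_id} are ubiquitous; "
            "IC similarity undefined, returning 0",
            stacklevel=2,
        )
        return 0.0
    shared = dag_i.terms & dag_j.terms
    return 2.0 * sum(ic.values[t] for t in shared) / denom


def combined_semantic_similarity(
    diseases: Sequence[DiseaseDAG], theta: float = DEFAULT_THETA
) -> SimilarityMatrix:
    """Average of Wang's and Xuan's measures over all disease pairs (SS)."""
    if not diseases:
        raise ValueError("disease list must be nonempty")
    labels = tuple(d.disease_id for d in diseases)
    profiles = [semantic_profile(d, theta) for d in diseases]
    ic = information_content(diseases)
    n = len(diseases)
    values = np.zeros((n, n))
    with warnings.catch_warnings():
        # A corpus of near-identical DAGs can make SS2 undefined for
        # many pairs at once; one warning per matrix is enough.
        warnings.simplefilter("once")
        for i in range(n):
            for j in range(i, n):
                ss1 = wang_similarity(profiles[i], profiles[j])
                ss2 = xuan_similarity(diseases[i], diseases[j], ic)
                values[i, j] = values[j, i] = (ss1 + ss2) / 2.0
    return SimilarityMatrix(labels, values)


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    labels: Iterable[str],
    theta: float = DEFAULT_THETA,
) -> SimilarityMatrix:
    """Combined semantic similarity embedded over a full label set.

    Diseases without a descriptor DAG get all-zero rows and columns, the
    structural-missingness signal that :func:`integrate_similarity`
    replaces with GIPK similarity.
    """
    labels = tuple(labels)
    present = [label for label in labels if label in dags]
    n = len(labels)
    values = np.zeros((n, n))
    if present:
        sub = combined_semantic_similarity([dags[label] for label in present], theta)
        pos = {label: k for k, label in enumerate(labels)}
        idx = np.array([pos[label] for label in present])
        values[np.ix_(idx, idx)] = sub.values
    return SimilarityMatrix(labels, values)


def _gipk(profiles: np.ndarray, labels: tuple[str, ...], kind: str) -> SimilarityMatrix:
    total = float((profiles**2).sum())
    if total == 0.0:
        raise ValueError(
            f"cannot compute {kind} GIPK similarity: the association matrix is all-zero "
            "(kernel bandwidth undefined)"
        )
    rho = profiles.shape[0] / total
    sq_dist = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-rho * sq_dist)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels, values)


def gipk_disease(assoc: AssociationTable) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity between diseases (GKSD).

    GKSD(d_i, d_j) = exp(-rho_d ||K(d_i) - K(d_j)||^2) with the
    bandwidth rho_d = n_d / sum_i ||K(d_i)||^2, profiles being rows of
    the association matrix.
    """
    return _gipk(assoc.values, assoc.disease_labels, "disease")


def gipk_mirna(assoc: AssociationTable) -> SimilarityMatrix:
    """GIPK similarity between miRNAs (GKSM); profiles are the columns."""
    return _gipk(assoc.values.T.copy(), assoc.mirna_labels, "miRNA")


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Entrywise substitution of the fallback where the primary is zero.

    Produces the integrated disease similarity A_DD (semantic with GIPK
    fallback) and the integrated miRNA similarity A_MM (functional with
    GIPK fallback). The comparison against zero is exact: only
    structurally missing similarity triggers the fallback. The diagonal
    is forced to 1.
    """
    if primary.labels != fallback.labels:
        raise ValueError("primary and fallback similarity labels differ")
    values = np.where(primary.values != 0.0, primary.values, fallback.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(primary.labels, values)
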