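"""Synthetic inputs: descriptor DAG corpora, planted low-rank
associations, and noisy similarity matrices.

The generator emulates the shape of the real inputs — a curated binary
disease x miRNA association matrix, per-disease descriptor DAGs drawn
from a shared term hierarchy, and a precomputed miRNA functional-
similarity matrix — at a scale where every stage of the pipeline runs
in seconds. Associations are planted from nonnegative low-rank factors
so that recovery and ranking quality can be measured against a known
continuous ground truth; functional similarity is derived from the same
miRNA factors (functionally similar miRNAs associate with similar
diseases), with mild jitter; a seeded fraction of diseases is left
without a descriptor and of miRNAs without functional similarity, to
exercise the Gaussian-kernel fallback.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np

from .containers import AssociationTable, SimilarityMatrix
from .similarity import DiseaseDAG, semantic_similarity_matrix

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "simulate_dag_corpus",
    "simulate_associations",
    "simulate_functional_similarity",
    "simulate_missing_similarity",
    "simulate_dataset",
    "write_dataset",
]

# Distinct per-operation seed streams derived from the user seed, so
# that e.g. the DAG corpus is identical whether or not associations
# were also generated.
_STREAM_DAG = 1
_STREAM_ASSOC = 2
_STREAM_MISSING = 3
_STREAM_FS = 4
_STREAM_NOISE = 5

# Probability that a hierarchy term gets a second parent, so generated
# descriptor graphs are genuine DAGs rather than trees.
_SECOND_PARENT_PROB = 0.2
# Jitter applied to the factor-derived functional similarity.
_FS_NOISE_SCALE = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a 30-disease x 40-miRNA corpus with rank-2
    planted structure at 10% association density — large enough for
    cross-validated ranking to be meaningful, small enough that a full
    leave-one-out sweep takes seconds.
    """

    n_diseases: int = 30
    n_mirnas: int = 40
    latent_rank: int = 2
    association_density: float = 0.1
    noise_rate: float = 0.0
    dag_depth: int = 3
    dag_branching: int = 4
    missing_similarity_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_mirnas < 1:
            raise ValueError("entity counts must be positive")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be at least 1")
        if not 0.0 < self.association_density < 1.0:
            raise ValueError("association_density must be in (0, 1)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag_depth and dag_branching must be positive")
        if not 0.0 <= self.missing_similarity_fraction <= 1.0:
            raise ValueError("missing_similarity_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    """A full bundle of pipeline inputs plus the planted ground truth."""

    spec: SyntheticSpec
    assoc: AssociationTable
    planted: np.ndarray
    dag_corpus: dict[str, DiseaseDAG]
    disease_semantic: SimilarityMatrix
    mirna_functional: SimilarityMatrix
    missing_diseases: tuple[str, ...]
    missing_mirnas: tuple[str, ...]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _disease_labels(spec: SyntheticSpec) -> list[str]:
    return [f"disease-{i:03d}" for i in range(spec.n_diseases)]


def _mirna_labels(spec: SyntheticSpec) -> list[str]:
    return [f"mirna-{j:03d}" for j in range(spec.n_mirnas)]


def simulate_dag_corpus(spec: SyntheticSpec) -> list[DiseaseDAG]:
    """Random shared term hierarchy; one leaf term per disease.

    A single root sits at level 0; internal levels widen by the
    branching factor; each disease owns one term at the deepest level.
    Every non-root term draws its parent uniformly from the level above
    and occasionally a second parent, so the ancestor closures are true
    DAGs. Each disease's DAG is the ancestor closure of its own term.
    """
    if spec.dag_branching**spec.dag_depth < spec.n_diseases:
        raise ValueError(
            f"hierarchy of depth {spec.dag_depth} and branching {spec.dag_branching} "
            f"has at most {spec.dag_branching ** spec.dag_depth} leaves, "
            f"fewer than {spec.n_diseases} diseases"
        )
    rng = _rng(spec, _STREAM_DAG)
    levels: list[list[str]] = [["term-root"]]
    graph = nx.DiGraph()
    graph.add_node("term-root")
    for level in range(1, spec.dag_depth + 1):
        if level == spec.dag_depth:
            width = spec.n_diseases
        else:
            # Enough terms to host the leaves below, capped by branching.
            needed = math.ceil(spec.n_diseases / spec.dag_branching ** (spec.dag_depth - level))
            width = max(1, min(spec.dag_branching**level, needed * 2))
        names = [f"term-{level}-{i:03d}" for i in range(width)]
        for name in names:
            parent = levels[level - 1][rng.integers(len(levels[level - 1]))]
            graph.add_edge(parent, name)
            if len(levels[level - 1]) > 1 and rng.random() < _SECOND_PARENT_PROB:
                second = levels[level - 1][rng.integers(len(levels[level - 1]))]
                if second != parent:
                    graph.add_edge(second, name)
        levels.append(names)
    corpus = []
    for disease, leaf in zip(_disease_labels(spec), levels[-1]):
        terms = nx.ancestors(graph, leaf) | {leaf}
        edges = {(p, c) for p, c in graph.edges if p in terms and c in terms}
        corpus.append(
            DiseaseDAG(disease_id=disease, disease_term=leaf, terms=frozenset(terms), edges=frozenset(edges))
        )
    return corpus


def _latent_factors(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(spec, _STREAM_ASSOC)
    U = rng.uniform(0.0, 1.0, size=(spec.n_diseases, spec.latent_rank))
    V = rng.uniform(0.0, 1.0, size=(spec.n_mirnas, spec.latent_rank))
    return U, V


def simulate_associations(spec: SyntheticSpec) -> tuple[AssociationTable, np.ndarray]:
    """Planted low-rank associations and their continuous ground truth.

    Scores are a nonnegative rank-r product U V^T rescaled into [0, 1];
    the top density-quantile of scores becomes the verified set, and a
    ``noise_rate`` fraction of entries is then flipped (symmetric label
    noise). Both the binary table and the continuous truth are
    returned.
    """
    U, V = _latent_factors(spec)
    rng = _rng(spec, _STREAM_NOISE)
    scores = U @ V.T
    span = scores.max() - scores.min()
    planted = (scores - scores.min()) / (span if span > 0 else 1.0)
    n_cells = spec.n_diseases * spec.n_mirnas
    n_pos = int(round(spec.association_density * n_cells))
    if n_pos == 0:
        raise ValueError("association_density yields zero positive associations")
    order = np.argsort(planted, axis=None)[::-1]
    values = np.zeros(n_cells)
    values[order[:n_pos]] = 1.0
    n_flip = int(round(spec.noise_rate * n_cells))
    if n_flip:
        flip = rng.choice(n_cells, size=n_flip, replace=False)
        values[flip] = 1.0 - values[flip]
    values = values.reshape(spec.n_diseases, spec.n_mirnas)
    if values.sum() == 0:
        raise ValueError("label noise removed every positive association")
    table = AssociationTable(_disease_labels(spec), _mirna_labels(spec), values)
    return table, planted


def simulate_functional_similarity(spec: SyntheticSpec) -> SimilarityMatrix:
    """miRNA functional similarity derived from the planted factors.

    Cosine similarity between the nonnegative miRNA factor rows (so
    functionally similar miRNAs share disease associations, the premise
    of functional-similarity scores), with mild seeded jitter.
    """
    _, V = _latent_factors(spec)
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    unit = V / np.where(norms > 0, norms, 1.0)
    cos = unit @ unit.T
    rng = _rng(spec, _STREAM_FS)
    jitter = rng.normal(0.0, _FS_NOISE_SCALE, size=cos.shape)
    values = np.clip(cos + (jitter + jitter.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(tuple(_mirna_labels(spec)), values)


def simulate_missing_similarity(
    spec: SyntheticSpec, sim: SimilarityMatrix
) -> SimilarityMatrix:
    """Zero whole rows/columns for a seeded subset of entities.

    Emulates entities with no descriptor or no functional-similarity
    entry; the integration step replaces exactly these rows with the
    Gaussian-kernel similarity.
    """
    missing, _ = _missing_indices(spec, sim.n)
    values = sim.values.copy()
    values[missing, :] = 0.0
    values[:, missing] = 0.0
    return SimilarityMatrix(sim.labels, values)


def _missing_indices(spec: SyntheticSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(spec, _STREAM_MISSING)
    k = int(round(spec.missing_similarity_fraction * n))
    missing = np.sort(rng.choice(n, size=k, replace=False))
    present = np.setdiff1d(np.arange(n), missing)
    return missing, present


def simulate_dataset(spec: SyntheticSpec, theta: float = 0.5) -> SyntheticDataset:
    """Generate the full input bundle one pipeline run consumes."""
    corpus = simulate_dag_corpus(spec)
    assoc, planted = simulate_associations(spec)
    missing_d, _ = _missing_indices(spec, spec.n_diseases)
    missing_d_set = {assoc.disease_labels[i] for i in missing_d}
    dag_corpus = {
        dag.disease_id: dag for dag in corpus if dag.disease_id not in missing_d_set
    }
    disease_semantic = semantic_similarity_matrix(
        dag_corpus, assoc.disease_labels, theta
    )
    fs = simulate_functional_similarity(spec)
    fs = simulate_missing_similarity(spec, fs)
    missing_m, _ = _missing_indices(spec, spec.n_mirnas)
    return SyntheticDataset(
        spec=spec,
        assoc=assoc,
        planted=planted,
        dag_corpus=dag_corpus,
        disease_semantic=disease_semantic,
        mirna_functional=fs,
        missing_diseases=tuple(sorted(missing_d_set)),
        missing_mirnas=tuple(assoc.mirna_labels[j] for j in missing_m),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the external TSV formats the readers accept.

    Emits associations.tsv (edge list), dag.tsv (term, parent pairs;
    the root has an empty parent), disease_terms.tsv (disease -> term
    mapping, omitting descriptor-less diseases), mirna_fs.tsv
    (functional similarity matrix) and truth.tsv (planted continuous
    scores).
    """
    from . import io as mio  # local import: io depends on containers only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "dag": outdir / "dag.tsv",
        "disease_terms": outdir / "disease_terms.tsv",
        "mirna_fs": outdir / "mirna_fs.tsv",
        "truth": outdir / "truth.tsv",
    }
    mio.write_associations(dataset.assoc, paths["associations"], form="edges")
    edges = sorted(
        {edge for dag in dataset.dag_corpus.values() for edge in dag.edges}
    )
    children = {c for _, c in edges}
    roots = sorted({p for p, _ in edges} - children)
    with open(paths["dag"], "w") as fh:
        fh.write("term_id\tparent_id\n")
        for root in roots:
            fh.write(f"{root}\t\n")
        for parent, child in edges:
            fh.write(f"{child}\t{parent}\n")
    with open(paths["disease_terms"], "w") as fh:
        fh.write("disease_id\tterm_id\n")
        for disease in dataset.assoc.disease_labels:
            if disease in dataset.dag_corpus:
                fh.write(f"{disease}\t{dataset.dag_corpus[disease].disease_term}\n")
    mio.write_similarity(dataset.mirna_functional, paths["mirna_fs"], full_precision=True)
    mio.write_matrix(
        dataset.planted,
        dataset.assoc.disease_labels,
        dataset.assoc.mirna_labels,
        paths["truth"],
    )
    return paths
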