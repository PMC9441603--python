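"""TSV readers and writers for every external format.

All external I/O is by label, never by position, and all formats are
tab-separated (disease names routinely contain commas). Associations
may arrive as a two-column edge list or as a labelled 0/1 matrix
(auto-detected from the header width); similarity matrices carry their
labels in the first row and first column; descriptor hierarchies are
(term, parent) pairs with an empty parent marking a root, plus a
disease -> term mapping from which the reader computes each disease's
ancestor closure.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AssociationTable, SimilarityMatrix
from .heteronet import ScoredAssociations
from .similarity import DiseaseDAG

__all__ = [
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "read_dag_corpus",
    "write_matrix",
    "write_predictions",
]

# Readers symmetrize (with a warning) up to this asymmetry and reject beyond.
_SYM_WARN_TOL = 1e-6
# Entries overshooting [0, 1] by at most this much are clipped silently.
_CLIP_TOL = 1e-9


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)
    if frame.empty and frame.columns.empty:
        raise ValueError(f"{path}: empty file")
    return frame


def read_associations(path: str | Path) -> AssociationTable:
    """Read associations from an edge list or a labelled binary matrix.

    A two-column file is an edge list (disease_id, mirna_id); anything
    wider is a matrix whose first column holds disease labels and whose
    header holds miRNA labels. Duplicate edges collapse to a single 1
    with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValueError(f"{path}: empty file")
    if len(header.split("\t")) == 2:
        frame = _read_tsv(path)
        diseases = list(dict.fromkeys(frame.iloc[:, 0]))
        mirnas = list(dict.fromkeys(frame.iloc[:, 1]))
        if frame.duplicated().any():
            warnings.warn(
                f"{path}: {int(frame.duplicated().sum())} duplicate association "
                "edge(s) collapsed",
                stacklevel=2,
            )
        values = np.zeros((len(diseases), len(mirnas)))
        d_pos = {d: i for i, d in enumerate(diseases)}
        m_pos = {m: j for j, m in enumerate(mirnas)}
        for d, m in frame.itertuples(index=False):
            values[d_pos[d], m_pos[m]] = 1.0
        return AssociationTable(tuple(diseases), tuple(mirnas), values)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = frame.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError(f"{path}: association matrix entries must be 0 or 1")
    return AssociationTable(
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
        values,
    )


def write_associations(
    table: AssociationTable, path: str | Path, form: str = "matrix"
) -> None:
    """Write associations as a labelled matrix or an edge list."""
    path = Path(path)
    if form == "matrix":
        table.to_frame().to_csv(path, sep="\t", index_label="disease_id")
    elif form == "edges":
        rows = np.argwhere(table.values == 1.0)
        with open(path, "w") as fh:
            fh.write("disease_id\tmirna_id\n")
            for i, j in rows:
                fh.write(f"{table.disease_labels[i]}\t{table.mirna_labels[j]}\n")
    else:
        raise ValueError(f"unknown association format {form!r}")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    """Read a labelled square similarity matrix.

    Row and column labels must agree; asymmetry up to 1e-6 is averaged
    away with a warning and anything worse is rejected; entries
    overshooting [0, 1] by at most 1e-9 are clipped, larger violations
    are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(str(i) for i in frame.index)
    if labels != tuple(str(c) for c in frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    values = frame.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYM_WARN_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance (|S-S^T| = {asym:g})")
    if asym > 1e-12:
        warnings.warn(f"{path}: symmetrized (max asymmetry {asym:g})", stacklevel=2)
    values = (values + values.T) / 2.0
    lo, hi = values.min(initial=0.0), values.max(initial=0.0)
    if lo < -_CLIP_TOL or hi > 1.0 + _CLIP_TOL:
        raise ValueError(f"{path}: entries outside [0, 1] (min {lo:g}, max {hi:g})")
    return SimilarityMatrix(labels, np.clip(values, 0.0, 1.0))


def write_similarity(
    sim: SimilarityMatrix, path: str | Path, full_precision: bool = False
) -> None:
    """Write a similarity matrix; 6 significant digits by default."""
    fmt = "%.17g" if full_precision else "%.6g"
    sim.to_frame().to_csv(path, sep="\t", index_label="", float_format=fmt)


def write_matrix(
    values: np.ndarray,
    row_labels: Iterable[str],
    col_labels: Iterable[str],
    path: str | Path,
) -> None:
    """Write an arbitrary labelled numeric matrix (full precision)."""
    pd.DataFrame(values, index=list(row_labels), columns=list(col_labels)).to_csv(
        path, sep="\t", index_label="", float_format="%.17g"
    )


def read_dag_corpus(
    dag_path: str | Path, mapping_path: str | Path
) -> dict[str, DiseaseDAG]:
    """Build each disease's descriptor DAG from the hierarchy tables.

    ``dag_path`` lists (term_id, parent_id) pairs — one row per parent,
    an empty parent marking a root. ``mapping_path`` maps each disease
    to its own term (one term per disease); the reader computes the
    ancestor closure.
    """
    hierarchy = _read_tsv(dag_path)
    if hierarchy.shape[1] != 2:
        raise ValueError(f"{dag_path}: expected two columns (term_id, parent_id)")
    graph = nx.DiGraph()
    for term, parent in hierarchy.itertuples(index=False):
        graph.add_node(term)
        if parent:
            graph.add_edge(parent, term)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{dag_path}: term hierarchy contains a cycle")
    mapping = _read_tsv(mapping_path)
    if mapping.shape[1] != 2:
        raise ValueError(f"{mapping_path}: expected two columns (disease_id, term_id)")
    if mapping.iloc[:, 0].duplicated().any():
        raise ValueError(f"{mapping_path}: a disease maps to more than one term")
    corpus: dict[str, DiseaseDAG] = {}
    for disease, term in mapping.itertuples(index=False):
        if term not in graph:
            raise ValueError(f"{mapping_path}: term {term!r} absent from the hierarchy")
        terms = nx.ancestors(graph, term) | {term}
        edges = {(p, c) for p, c in graph.edges if p in terms and c in terms}
        corpus[disease] = DiseaseDAG(
            disease_id=disease,
            disease_term=term,
            terms=frozenset(terms),
            edges=frozenset(edges),
        )
    return corpus


def write_predictions(scored: ScoredAssociations, path: str | Path) -> None:
    """Ranked prediction TSV: disease_id, mirna_id, score, rank, known_flag."""
    scored.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
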