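"""Labelled matrix containers shared across the pipeline.

Two containers carry almost all data in this package: a binary
disease x miRNA association table and a square symmetric similarity
matrix with entries in [0, 1]. Both are label-indexed; positional
indices are an internal detail and never part of the file formats.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Constructors symmetrize exactly once symmetry holds to this tolerance;
# anything worse is a data error, not numerical noise.
_SYMMETRY_TOL = 1e-8
# Floating-point excursions beyond [0, 1] smaller than this are clipped.
_RANGE_TOL = 1e-9


def _check_unique(labels: tuple[str, ...], axis: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {axis} labels")


@dataclass(frozen=True)
class AssociationTable:
    """Binary disease x miRNA association matrix with row/column labels.

    Rows are disease interaction profiles K(d_i), columns are miRNA
    interaction profiles K(m_j).
    """

    disease_labels: tuple[str, ...]
    mirna_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_labels", tuple(self.disease_labels))
        object.__setattr__(self, "mirna_labels", tuple(self.mirna_labels))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.disease_labels), len(self.mirna_labels)):
            raise ValueError(
                f"association matrix shape {values.shape} does not match "
                f"{len(self.disease_labels)} diseases x {len(self.mirna_labels)} miRNAs"
            )
        _check_unique(self.disease_labels, "disease")
        _check_unique(self.mirna_labels, "miRNA")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_known(self) -> int:
        """Number of known (verified) associations."""
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "AssociationTable":
        """A copy of this table with the same labels and new entries."""
        return AssociationTable(self.disease_labels, self.mirna_labels, values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=list(self.disease_labels),
            columns=list(self.mirna_labels),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AssociationTable":
        return cls(
            tuple(str(c) for c in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1].

    Used for every similarity flavour in the pipeline: the semantic
    measures (SS1, SS2, SS), miRNA functional similarity (FS), the
    Gaussian interaction profile kernels (GKSD, GKSM), and the
    integrated matrices A_DD and A_MM. The constructor symmetrizes
    exactly (average with the transpose) and clips sub-tolerance
    floating-point excursions outside [0, 1].
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {values.shape} != ({n}, {n})")
        _check_unique(self.labels, "similarity")
        if not np.isfinite(values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        asym = np.abs(values - values.T).max() if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric (max |S - S^T| = {asym:g})")
        values = (values + values.T) / 2.0
        lo, hi = values.min(initial=0.0), values.max(initial=0.0)
        if lo < -_RANGE_TOL or hi > 1.0 + _RANGE_TOL:
            raise ValueError(
                f"similarity entries outside [0, 1] (min {lo:g}, max {hi:g})"
            )
        values = np.clip(values, 0.0, 1.0)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimilarityMatrix":
        return cls(tuple(str(c) for c in frame.index), frame.to_numpy(dtype=float))

    @classmethod
    def zeros(cls, labels: tuple[str, ...]) -> "SimilarityMatrix":
        """All-zero similarity (no information; forces the GIPK fallback)."""
        return cls(tuple(labels), np.zeros((len(labels), len(labels))))

    def reindex(self, labels: tuple[str, ...]) -> "SimilarityMatrix":
        """Reorder/subset to the given labels, which must all be present."""
        labels = tuple(labels)
        missing = set(labels) - set(self.labels)
        if missing:
            raise ValueError(f"labels absent from similarity matrix: {sorted(missing)}")
        pos = {label: i for i, label in enumerate(self.labels)}
        idx = np.array([pos[label] for label in labels])
        return SimilarityMatrix(labels, self.values[np.ix_(idx, idx)].copy())
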