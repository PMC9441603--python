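"""Heterogeneous disease-miRNA network assembly.

The integrated disease similarity A_DD, the association matrix A_DM and
the integrated miRNA similarity A_MM are stacked into one symmetric
(n_d + n_m) x (n_d + n_m) block matrix

    M = [[A_DD,    A_DM],
         [A_DM^T,  A_MM]]

together with a known-entry mask Omega: every similarity entry (the two
diagonal blocks) is known, and an off-diagonal entry is known exactly
where the association is verified (A_DM = 1). Unknown entries carry the
value 0 and are what the completion fills in.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AssociationTable, SimilarityMatrix

__all__ = ["HeterogeneousNetwork", "ScoredAssociations", "assemble", "extract_prediction_block"]


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Block matrix M, its known-entry mask and the label -> index maps."""

    matrix: np.ndarray
    mask: np.ndarray
    disease_labels: tuple[str, ...]
    mirna_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for arr in (self.matrix, self.mask):
            arr.setflags(write=False)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    @property
    def disease_index(self) -> dict[str, int]:
        return {label: i for i, label in enumerate(self.disease_labels)}

    @property
    def mirna_index(self) -> dict[str, int]:
        n_d = self.n_diseases
        return {label: n_d + j for j, label in enumerate(self.mirna_labels)}

    def blocks(self) -> tuple[SimilarityMatrix, AssociationTable, SimilarityMatrix]:
        """The three input blocks (A_DD, A_DM, A_MM) recovered from M."""
        n_d = self.n_diseases
        add = SimilarityMatrix(self.disease_labels, self.matrix[:n_d, :n_d].copy())
        adm = AssociationTable(
            self.disease_labels, self.mirna_labels, self.matrix[:n_d, n_d:].copy()
        )
        amm = SimilarityMatrix(self.mirna_labels, self.matrix[n_d:, n_d:].copy())
        return add, adm, amm


def assemble(
    add: SimilarityMatrix, adm: AssociationTable, amm: SimilarityMatrix
) -> HeterogeneousNetwork:
    """Stack similarity and association blocks into the network matrix M.

    The mask marks both diagonal blocks entirely and the off-diagonal
    blocks at verified associations only, so the mask carries
    n_d^2 + n_m^2 + 2 * nnz(A_DM) ones.
    """
    if add.labels != adm.disease_labels:
        raise ValueError("disease similarity labels do not match the association table")
    if amm.labels != adm.mirna_labels:
        raise ValueError("miRNA similarity labels do not match the association table")
    a = adm.values
    matrix = np.block([[add.values, a], [a.T, amm.values]])
    mask = np.block(
        [
            [np.ones_like(add.values), a],
            [a.T, np.ones_like(amm.values)],
        ]
    )
    return HeterogeneousNetwork(
        matrix=matrix,
        mask=mask,
        disease_labels=adm.disease_labels,
        mirna_labels=adm.mirna_labels,
    )


@dataclass(frozen=True)
class ScoredAssociations:
    """Prediction scores for every disease-miRNA pair.

    ``known`` flags pairs that were verified in the input associations;
    they keep their completed score but are excluded from candidate
    ranking.
    """

    disease_labels: tuple[str, ...]
    mirna_labels: tuple[str, ...]
    scores: np.ndarray
    known: np.ndarray

    def __post_init__(self) -> None:
        self.scores.setflags(write=False)
        self.known.setflags(write=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format ranking, best candidates first.

        Candidate (unknown) pairs are ranked 1..K by descending score;
        known pairs appear with rank 0 and known_flag 1.
        """
        n_d, n_m = self.scores.shape
        di, mi = np.meshgrid(np.arange(n_d), np.arange(n_m), indexing="ij")
        frame = pd.DataFrame(
            {
                "disease_id": np.asarray(self.disease_labels)[di.ravel()],
                "mirna_id": np.asarray(self.mirna_labels)[mi.ravel()],
                "score": self.scores.ravel(),
                "known_flag": self.known.ravel().astype(int),
            }
        )
        frame = frame.sort_values(
            ["score", "disease_id", "mirna_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        frame["rank"] = 0
        candidates = frame["known_flag"] == 0
        frame.loc[candidates, "rank"] = np.arange(1, int(candidates.sum()) + 1)
        return frame[["disease_id", "mirna_id", "score", "rank", "known_flag"]]


def extract_prediction_block(
    completed: np.ndarray, net: HeterogeneousNetwork, symmetrize: bool = False
) -> ScoredAssociations:
    """Pull the disease x miRNA score block out of a completed matrix.

    By default the top-right block is returned as-is; with
    ``symmetrize`` it is averaged with the transpose of the bottom-left
    block (the solver's output need not be exactly symmetric).
    """
    completed = np.asarray(completed, dtype=float)
    if completed.shape != net.matrix.shape:
        raise ValueError(
            f"completed matrix shape {completed.shape} != network shape {net.matrix.shape}"
        )
    n_d = net.n_diseases
    scores = completed[:n_d, n_d:]
    if symmetrize:
        scores = (scores + completed[n_d:, :n_d].T) / 2.0
    known = net.mask[:n_d, n_d:] == 1.0
    return ScoredAssociations(
        disease_labels=net.disease_labels,
        mirna_labels=net.mirna_labels,
        scores=scores.copy(),
        known=known.copy(),
    )
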