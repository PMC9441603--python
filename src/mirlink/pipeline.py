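"""End-to-end scoring: similarities -> network -> completion -> scores.

This module wires the three stages together: compute GIPK similarities
from the association matrix, integrate them with semantic / functional
similarity where available, assemble the heterogeneous block matrix,
complete it under the bounded nuclear-norm model, and extract the
disease x miRNA score block.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .containers import AssociationTable, SimilarityMatrix
from .heteronet import HeterogeneousNetwork, ScoredAssociations, assemble, extract_prediction_block
from .similarity import gipk_disease, gipk_mirna, integrate_similarity
from .solver import SolverConfig, SolverResult, bnnr_solve

__all__ = ["PipelineResult", "build_network", "predict"]


@dataclass(frozen=True)
class PipelineResult:
    scores: ScoredAssociations
    solver: SolverResult
    network: HeterogeneousNetwork


def build_network(
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix] = None,
    mirna_functional: Optional[SimilarityMatrix] = None,
) -> HeterogeneousNetwork:
    """Integrate similarities and assemble the block matrix M.

    ``disease_semantic`` and ``mirna_functional`` may be None (or carry
    all-zero rows for entities without a descriptor / functional-
    similarity entry); GIPK similarity, computed from the association
    profiles, substitutes wherever the primary similarity is zero.
    """
    if disease_semantic is None:
        disease_semantic = SimilarityMatrix.zeros(assoc.disease_labels)
    if mirna_functional is None:
        mirna_functional = SimilarityMatrix.zeros(assoc.mirna_labels)
    add = integrate_similarity(disease_semantic, gipk_disease(assoc))
    amm = integrate_similarity(mirna_functional, gipk_mirna(assoc))
    return assemble(add, assoc, amm)


def predict(
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix] = None,
    mirna_functional: Optional[SimilarityMatrix] = None,
    cfg: SolverConfig = SolverConfig(),
    *,
    symmetrize: bool = False,
) -> PipelineResult:
    """Score every disease-miRNA pair by heterogeneous matrix completion."""
    net = build_network(assoc, disease_semantic, mirna_functional)
    result = bnnr_solve(net, cfg)
    scores = extract_prediction_block(result.H_star, net, symmetrize=symmetrize)
    return PipelineResult(scores=scores, solver=result, network=net)
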