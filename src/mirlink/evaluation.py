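"""Cross-validation protocols and ROC/AUC for association scoring.

Two protocols mirror standard practice for link prediction on a known
association matrix:

* **Global leave-one-out**: each verified association is removed in
  turn, the scoring pipeline is re-run on the remaining associations,
  and the held-out pair is ranked against every candidate pair (pairs
  that are 0 in the *full* association matrix).

* **k-fold**: the verified associations are shuffled (seeded) into k
  near-equal parts; each part is removed in turn and its pairs are
  scored against the candidates.

The headline number is the pooled AUC over all (test, candidate) score
comparisons; per-fold AUCs are reported alongside for k-fold. By
default the Gaussian-kernel similarities, which are functions of the
association matrix, are recomputed from the training matrix in every
round so that held-out associations never leak into the features; a
``fixed_similarity`` option reproduces the cheaper convention of
computing them once from the full matrix.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import AssociationTable, SimilarityMatrix
from .heteronet import assemble
from .pipeline import build_network
from .similarity import gipk_disease, gipk_mirna, integrate_similarity
from .solver import SolverConfig, bnnr_solve

__all__ = ["CVResult", "roc_auc", "bnnr_score_fn", "global_loocv", "kfold_cv", "grid_search"]

# A score function maps a training association table to a full
# n_d x n_m score matrix. The default is the bounded nuclear-norm
# pipeline; tests inject trivial scorers to validate the harness.
ScoreFn = Callable[[AssociationTable], np.ndarray]


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation run."""

    auc: float
    per_fold_auc: Optional[list[float]]
    test_ranks: list[tuple[str, str, float, int]]
    config_echo: dict
    seed: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, exact under ties.

    Computed as the Mann-Whitney statistic P(s+ > s-) + 0.5 P(s+ = s-)
    via midranks, which equals trapezoidal integration of the ROC curve
    swept over all distinct score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative label")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bnnr_score_fn(
    disease_semantic: Optional[SimilarityMatrix],
    mirna_functional: Optional[SimilarityMatrix],
    cfg: SolverConfig,
    *,
    fixed_similarity: bool = False,
    full_assoc: Optional[AssociationTable] = None,
) -> ScoreFn:
    """Build the default scorer: the full completion pipeline.

    With ``fixed_similarity`` the integrated similarity blocks are
    computed once from ``full_assoc`` (the full association matrix) and
    reused across training rounds; otherwise they are rebuilt from each
    training matrix.
    """
    if fixed_similarity:
        if full_assoc is None:
            raise ValueError("fixed_similarity requires the full association table")
        add = integrate_similarity(
            disease_semantic
            if disease_semantic is not None
            else SimilarityMatrix.zeros(full_assoc.disease_labels),
            gipk_disease(full_assoc),
        )
        amm = integrate_similarity(
            mirna_functional
            if mirna_functional is not None
            else SimilarityMatrix.zeros(full_assoc.mirna_labels),
            gipk_mirna(full_assoc),
        )

        def score(train: AssociationTable) -> np.ndarray:
            net = assemble(add, train, amm)
            result = bnnr_solve(net, cfg)
            n_d = train.n_diseases
            return result.H_star[:n_d, n_d:]

    else:

        def score(train: AssociationTable) -> np.ndarray:
            net = build_network(train, disease_semantic, mirna_functional)
            result = bnnr_solve(net, cfg)
            n_d = train.n_diseases
            return result.H_star[:n_d, n_d:]

    return score


def _resolve_score_fn(
    score_fn: Optional[ScoreFn],
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix],
    mirna_functional: Optional[SimilarityMatrix],
    cfg: SolverConfig,
    fixed_similarity: bool,
) -> ScoreFn:
    if score_fn is not None:
        return score_fn
    return bnnr_score_fn(
        disease_semantic,
        mirna_functional,
        cfg,
        fixed_similarity=fixed_similarity,
        full_assoc=assoc,
    )


def _rank_among(candidates: np.ndarray, value: float) -> float:
    """Average-rank position of ``value`` within the candidate scores
    (1 = best). Ties get the midrank."""
    higher = int((candidates > value).sum())
    equal = int((candidates == value).sum())
    return 1.0 + higher + 0.5 * equal


def _evaluate_folds(
    assoc: AssociationTable,
    folds: list[np.ndarray],
    score_fn: ScoreFn,
) -> tuple[list[float], list[float], Optional[list[float]], list]:
    """Zero out each fold of positives, score, and pool test/candidate scores."""
    full = assoc.values
    candidate_mask = full == 0.0
    pos_index = np.argwhere(full == 1.0)
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    per_fold: list[float] = []
    ranks: list = []
    for fold in folds:
        train = full.copy()
        held = pos_index[fold]
        train[held[:, 0], held[:, 1]] = 0.0
        scores = score_fn(assoc.with_values(train))
        cand_scores = scores[candidate_mask]
        test_scores = scores[held[:, 0], held[:, 1]]
        pooled_scores.extend(test_scores)
        pooled_scores.extend(cand_scores)
        pooled_labels.extend([1] * test_scores.size)
        pooled_labels.extend([0] * cand_scores.size)
        per_fold.append(
            roc_auc(
                np.concatenate([test_scores, cand_scores]),
                np.concatenate([np.ones(test_scores.size), np.zeros(cand_scores.size)]),
            )
        )
        for (i, j), s in zip(held, test_scores):
            ranks.append(
                (
                    assoc.disease_labels[i],
                    assoc.mirna_labels[j],
                    _rank_among(cand_scores, s),
                    int(cand_scores.size),
                )
            )
    pooled = roc_auc(pooled_scores, pooled_labels)
    return [pooled], per_fold, None, ranks


def global_loocv(
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix] = None,
    mirna_functional: Optional[SimilarityMatrix] = None,
    cfg: SolverConfig = SolverConfig(),
    *,
    score_fn: Optional[ScoreFn] = None,
    fixed_similarity: bool = False,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> CVResult:
    """Global leave-one-out cross-validation.

    Each verified association is zeroed in turn (together with its
    mirrored mask entry, since the network mask is rebuilt from the
    training matrix) and ranked against all candidate pairs. With
    ``subsample``, a seeded subset of that many held-out positives is
    evaluated instead of all of them (a cost control; the full protocol
    is the default).
    """
    n_pos = assoc.n_known
    if n_pos < 2:
        raise ValueError("leave-one-out requires at least 2 known associations")
    fn = _resolve_score_fn(
        score_fn, assoc, disease_semantic, mirna_functional, cfg, fixed_similarity
    )
    indices = np.arange(n_pos)
    if subsample is not None and subsample < n_pos:
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(n_pos, size=subsample, replace=False))
    folds = [np.array([i]) for i in indices]
    (pooled,), _, _, ranks = _evaluate_folds(assoc, folds, fn)
    return CVResult(
        auc=pooled,
        per_fold_auc=None,
        test_ranks=ranks,
        config_echo={
            "mode": "loocv",
            "alpha": cfg.alpha,
            "beta": cfg.beta,
            "tol": cfg.tol,
            "max_iter": cfg.max_iter,
            "fixed_similarity": fixed_similarity,
            "subsample": subsample,
            "n_positives_evaluated": len(indices),
        },
        seed=seed,
    )


def kfold_cv(
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix] = None,
    mirna_functional: Optional[SimilarityMatrix] = None,
    cfg: SolverConfig = SolverConfig(),
    *,
    k: int = 5,
    seed: int = 0,
    score_fn: Optional[ScoreFn] = None,
    fixed_similarity: bool = False,
) -> CVResult:
    """k-fold cross-validation over the verified associations."""
    if k < 2:
        raise ValueError("k must be at least 2")
    n_pos = assoc.n_known
    if n_pos < k:
        raise ValueError(f"need at least k={k} known associations, have {n_pos}")
    fn = _resolve_score_fn(
        score_fn, assoc, disease_semantic, mirna_functional, cfg, fixed_similarity
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pos)
    folds = np.array_split(perm, k)
    (pooled,), per_fold, _, ranks = _evaluate_folds(assoc, folds, fn)
    return CVResult(
        auc=pooled,
        per_fold_auc=per_fold,
        test_ranks=ranks,
        config_echo={
            "mode": "kfold",
            "k": k,
            "alpha": cfg.alpha,
            "beta": cfg.beta,
            "tol": cfg.tol,
            "max_iter": cfg.max_iter,
            "fixed_similarity": fixed_similarity,
        },
        seed=seed,
    )


def grid_search(
    assoc: AssociationTable,
    disease_semantic: Optional[SimilarityMatrix],
    mirna_functional: Optional[SimilarityMatrix],
    alphas: Sequence[float],
    betas: Sequence[float],
    *,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 300,
    fixed_similarity: bool = False,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Evaluate the full (alpha, beta) cross-product by k-fold CV.

    Duplicated grid values are deduplicated before evaluation. Returns
    the (alpha, beta, auc) table and the argmax pair; every cell uses
    the same fold split (fixed seed), so the comparison is paired.
    """
    alphas = list(dict.fromkeys(alphas))
    betas = list(dict.fromkeys(betas))
    if not alphas or not betas:
        raise ValueError("alpha and beta grids must be nonempty")
    rows = []
    for alpha in alphas:
        for beta in betas:
            cfg = SolverConfig(alpha=alpha, beta=beta, tol=tol, max_iter=max_iter)
            result = kfold_cv(
                assoc,
                disease_semantic,
                mirna_functional,
                cfg,
                k=k,
                seed=seed,
                fixed_similarity=fixed_similarity,
            )
            rows.append({"alpha": alpha, "beta": beta, "auc": result.auc})
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax()]
    return table, (float(best["alpha"]), float(best["beta"]))
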