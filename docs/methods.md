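# Methods

## Problem

Given `n_d` diseases, `n_m` miRNAs and a sparse binary matrix `A_DM` of
verified associations, score every unverified pair. The model exploits
two structural assumptions: (i) the completed association landscape is
approximately low rank — a few latent disease/miRNA factors explain the
observed links — and (ii) similar diseases associate with similar
miRNAs, so similarity matrices on both sides carry predictive signal.

## Similarity measures

**Disease semantic similarity.** Each disease carries a descriptor DAG
`DAG(D) = (T(D), E(D))`: its own term plus all ancestors in a
MeSH-style hierarchy, with (parent, child) edges. Two measures are
computed and averaged:

* *Decayed-contribution (Wang) measure.* Each term contributes
  `C_D(t) = 1` for the disease's own term, otherwise
  `θ · max{C_D(t') : t' a child of t in the DAG}`, evaluated
  children-first. The semantic value `V(D)` is the sum of
  contributions, and
  `SS1(d_i, d_j) = Σ_{t ∈ T(d_i) ∩ T(d_j)} (C_{d_i}(t) + C_{d_j}(t)) / (V(d_i) + V(d_j))`.
  The decay factor defaults to `θ = 0.5`, the value conventional for
  this measure; it is exposed as a parameter everywhere.

* *Information-content (Xuan) measure.* Over the descriptor corpus,
  `IC(t) = −log(fraction of DAGs containing t)`, and
  `SS2(d_i, d_j) = 2 Σ_{t ∈ T∩} IC(t) / (Σ_{T(d_i)} IC + Σ_{T(d_j)} IC)`.
  `SS2` is a ratio of logs and therefore invariant to the logarithm
  base; natural log is used and the base recorded in the `ICTable`. If
  every term of both diseases is ubiquitous the measure is undefined
  and 0 is returned with a warning. Terms absent from the IC table are
  rejected rather than imputed: an unseen term has no defined corpus
  frequency.

The combined similarity is `SS = (SS1 + SS2)/2`, averaged
unconditionally for every pair.

**Gaussian interaction profile kernel (GIPK).** With `K(d_i)` the i-th
row of `A_DM` (and `K(m_j)` the j-th column),
`GKSD(d_i, d_j) = exp(−ρ_d ‖K(d_i) − K(d_j)‖²)` with bandwidth
`ρ_d = n_d / Σ_i ‖K(d_i)‖²`, and symmetrically for miRNAs. A single
all-zero profile is fine (the kernel is still defined); an entirely
zero association matrix leaves the bandwidth undefined and is rejected.

**Integration.** `A_DD(i,j) = SS(i,j)` where `SS(i,j) ≠ 0`, else
`GKSD(i,j)`; likewise `A_MM` from functional similarity `FS` with
`GKSM` fallback. The zero test is exact (no epsilon): the fallback is
meant for *structurally* missing similarity — a disease with no
descriptor or a miRNA with no functional-similarity entry contributes
an all-zero row — not for small values. The integrated diagonal is
forced to 1 (self-similarity).

## Heterogeneous network and completion model

The blocks form the symmetric `(n_d+n_m)²` matrix
`M = [[A_DD, A_DM], [A_DM^T, A_MM]]`. Known entries Ω are all
similarity entries plus the verified associations; unverified pairs are
unknown and numerically 0, so `P_Ω(M) = M`. The completion is

```
min_X ‖X‖* + (α/2)‖P_Ω(X) − P_Ω(M)‖_F²   s.t. 0 ≤ X ≤ 1.
```

The nuclear norm is the convex surrogate for rank; the quadratic
fidelity term tolerates noise in the observed entries instead of
forcing interpolation; the box keeps scores on the scale of the inputs.

## Alternating-direction solver

The Lagrangian form in the literature attaches the fidelity term to the
nuclear-norm variable `X`, under which the `X`-subproblem has no closed
form. As is standard for this model, the solver splits the variables so
that the fidelity and box constraint sit on the auxiliary bounded
variable `H` (`X = H` enforced by the multiplier `Y` with penalty `β`),
which gives closed-form updates, applied in this order each iteration:

1. `X ← SVT(H − Y/β, 1/β)` — singular value thresholding, the proximal
   operator of the nuclear norm (full deterministic SVD; matrices here
   are at most ~10³-dimensional, so no randomized truncation).
2. `H̃ ← (αM + Y + βX)/(α + β)` on known entries;
   `H̃ ← X + Y/β` on unknown entries.
3. `H ← clip(H̃, 0, 1)` — the box constraint, so every iterate (and the
   returned completion) lies in `[0, 1]` by construction.
4. `Y ← Y + β(X − H)`.

Initialization is `H₀ = P_Ω(M)`, `Y₀ = 0` (the initial `X` is
irrelevant: step 1 overwrites it). `β` is held fixed across iterations,
matching its treatment as a tuned constant. Defaults `α = 1`, `β = 2`
are the values grid search selects on benchmark-scale association data.

**Stopping.** Iteration stops when
`max(‖X−H‖_F/‖M‖_F, ‖H_k − H_{k−1}‖_F/‖H_{k−1}‖_F) < tol`
(default `tol = 1e-4`) or at `max_iter = 300`. The X–H gap typically
falls below `1e-4` within ~60 iterations on the synthetic problems; the
relative H-change decays more slowly (roughly like 1/k), so runs often
use the full iteration budget with a final gap near `1e-5`.
Non-convergence within the budget is reported in the result, never
raised; the returned `H*` is well defined and box-feasible regardless.
Exactly tied singular values are harmless: all comparisons are on
reconstructed matrices, never on the (non-unique) SVD factors.

## Evaluation protocols

* **Global LOOCV**: each verified association is zeroed in turn, the
  pipeline re-run, and the held-out pair ranked against all candidate
  pairs — pairs that are 0 in the *full* matrix (held-out positives are
  scored but never counted as candidates). A seeded `subsample` option
  evaluates a subset of positives for quick runs; the full sweep is the
  default.
* **k-fold CV**: verified associations are shuffled (seeded
  `numpy` Generator) into k near-equal parts and zeroed per fold.
* **AUC** is exact midrank Mann–Whitney, `P(s⁺>s⁻) + ½P(s⁺=s⁻)`,
  identical to trapezoidal ROC integration over all distinct
  thresholds. The headline k-fold number pools test and candidate
  scores across folds; per-fold AUCs are reported alongside (the two
  conventions are both emitted because neither is canonical).
  Tied ranks use the average-rank convention throughout.
* **Leakage.** GIPK similarity is a function of `A_DM`, so by default
  it (and the integrated `A_DD`/`A_MM`) is recomputed from the training
  matrix in every round; `fixed_similarity=True` reproduces the cheaper
  compute-once convention. The choice is echoed in the result's config
  record.
* **Grid search** evaluates the full (α, β) cross-product with a shared
  fold split (paired comparison), deduplicating repeated grid values.

## Synthetic data

The generator emulates the *shape* of the real inputs at a scale where
the full pipeline runs in seconds:

* **Associations**: nonnegative factors `U (n_d×r)`, `V (n_m×r)` drawn
  uniform on [0,1]; planted scores are `UV^T` rescaled to [0,1]; the
  top density-quantile becomes the verified set; optional symmetric
  label flipping adds noise. Both the binary table and the continuous
  truth are returned, so ranking and recovery can be measured against
  ground truth.
* **Descriptor corpus**: a layered random hierarchy under a single
  root; each non-root term draws its parent uniformly from the level
  above and a second parent with probability 0.2 (so closures are true
  DAGs, not trees); each disease owns one deepest-level term, and its
  DAG is the ancestor closure.
* **Functional similarity**: cosine similarity of the miRNA factor rows
  plus symmetric N(0, 0.05) jitter — the premise of functional
  similarity scores is precisely that functionally similar miRNAs share
  disease associations.
* **Missingness**: a seeded fraction (default 0.1) of diseases gets no
  descriptor (omitted from the disease→term mapping) and of miRNAs no
  functional-similarity row, exercising the GIPK fallback end to end.

Defaults: 30 diseases × 40 miRNAs, rank 2, density 0.1, no label
noise, hierarchy depth 3 / branching 4, seed-addressable throughout
(all randomness flows through per-operation `numpy` Generator streams
derived from the user seed, so every artifact is bitwise reproducible).

**What passing on synthetic data does and does not show.** The
generator produces exactly low-rank association structure with
factor-consistent similarities — the regime the model assumes — so
synthetic AUCs (~0.9) demonstrate correctness of the machinery and
sensible behaviour of the model, not expected performance on curated
databases, whose association matrices are sparser, degree-skewed and
only approximately low rank, and whose descriptor hierarchy is far
deeper than the synthetic one.

## Numerical choices and limitations

* Problem sizes: cross-validation experiments use 20×30 to 30×40
  matrices (40–120 positives); planted-recovery experiments use 40×50
  matrices at 30–70% observation; these sizes give stable medians
  while keeping a full LOOCV sweep at a few seconds.
* Similarity matrices are validated on construction: symmetric to
  1e-8 (then symmetrized exactly), entries in [0, 1] with sub-1e-9
  excursions clipped. File readers symmetrize up to 1e-6 with a
  warning and reject beyond.
* The completed matrix need not be exactly symmetric; predictions use
  the top-right block by default, with an option to average it with
  the transpose of the bottom-left block.
* LOOCV cost grows linearly in the number of positives times the cost
  of one completion (one SVD per iteration); for matrices beyond a few
  hundred entities per side, prefer k-fold CV or the LOOCV subsample
  option.
* The method scores only entities present in the association matrix:
  a disease with no row (or miRNA with no column) cannot be ranked at
  all — cold-start prediction is out of scope.
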