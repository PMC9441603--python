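# mirlink

Prediction of disease–miRNA associations by **bounded nuclear-norm
matrix completion** on a heterogeneous similarity network.

miRNAs regulate gene expression, and their dysregulation is implicated
in many complex diseases, but confirming an individual miRNA–disease
association experimentally is slow and expensive. Given a sparse matrix
of verified associations plus similarity information on both sides —
disease semantic similarity from descriptor DAGs (MeSH-style), miRNA
functional similarity, and Gaussian interaction profile kernel (GIPK)
similarity computed from the association profiles themselves — this
package ranks the unverified pairs by how likely they are to be real.
It is aimed at computational biologists who want a tested, reproducible
implementation of this family of network-completion methods, with a
synthetic-data generator so the whole pipeline can be exercised and
benchmarked without any external downloads.

## Model

Let `A_DM` be the `n_d x n_m` binary association matrix. Disease
similarity `A_DD` combines two semantic measures — Wang's decayed
ancestor-contribution measure and Xuan's information-content measure,
averaged — with GIPK similarity substituted where a disease has no
descriptor; miRNA similarity `A_MM` combines functional similarity with
a GIPK fallback in the same way. These blocks form the symmetric
heterogeneous matrix

```
M = [ A_DD    A_DM ]        Ω = { similarity entries } ∪ { A_DM = 1 }
    [ A_DM^T  A_MM ]
```

and prediction is the bounded nuclear-norm completion

```
min_X  ‖X‖* + (α/2) ‖P_Ω(X) − P_Ω(M)‖_F²    s.t.  0 ≤ X ≤ 1,
```

solved by an alternating-direction scheme whose subproblems are closed
form (singular value thresholding for the low-rank variable, a blended
data/estimate update with box clipping for the bounded variable). The
completed top-right block scores every disease–miRNA pair in `[0, 1]`.
Quality is measured by global leave-one-out and k-fold cross-validated
AUC, ranking each held-out verified association against all unverified
candidate pairs.

## Worked example

```python
from mirlink import SolverConfig, SyntheticSpec, kfold_cv, predict, simulate_dataset

dataset = simulate_dataset(SyntheticSpec(seed=0))   # 30 x 40, rank-2 planted
result = predict(dataset.assoc, dataset.disease_semantic,
                 dataset.mirna_functional, SolverConfig(alpha=1.0, beta=2.0))
cv = kfold_cv(dataset.assoc, dataset.disease_semantic,
              dataset.mirna_functional, k=5, seed=0)
print(f"5-fold pooled AUC: {cv.auc:.4f}")
```

prints

```
5-fold pooled AUC: 0.9107
```

meaning a held-out verified association outscores a random unverified
pair 91% of the time (0.5 is chance). The `examples/` directory holds
three short narrative scripts: semantic similarity on a hand-built
descriptor corpus, end-to-end prediction with the top-ranked candidate
pairs, and cross-validation plus the `(α, β)` grid search. The same
functionality is available from a shell via the `mirlink` CLI
(`simulate`, `similarity`, `predict`, `evaluate`, `grid-search`).

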