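# l12glpca

Robust graph-regularised PCA for feature-gene extraction from expression
matrices, with an entrywise L1/2 error penalty solved by augmented
Lagrange multipliers (ALM).

## The problem

Expression studies measure thousands of genes on a handful of samples;
only a small set of genes drives the leading structure, and the data
carry noise and outliers that ordinary least-squares PCA absorbs into its
loadings. This package factorises a centred genes-by-samples matrix
`X` (m × n) as

```
X = U Vᵀ + S,    VᵀV = I
```

minimising

```
‖S‖_{1/2}^{1/2} + α · tr(Vᵀ L V)
```

where

- `U` (m × k) are gene loadings: the Euclidean norm of a gene's row of
  `U` ranks it as a candidate feature gene;
- `V` (n × k) is an orthonormal sample embedding;
- `S` collects reconstruction errors under the entrywise L1/2 quasi-norm
  `‖S‖_{1/2}^{1/2} = Σᵢⱼ |sᵢⱼ|^{1/2}`, which penalises large entries
  sub-linearly and therefore shunts outliers into `S` instead of letting
  them distort `U`;
- `L = D − W` is the combinatorial Laplacian of a k-nearest-neighbour
  graph on the samples, so `tr(VᵀLV)` keeps neighbouring samples close in
  the embedding.

The trade-off is parameterised by `β ∈ [0, 1]` via
`2α/μ = (β/(1−β))·(σ_m/σ_l)` (top eigenvalues of `MᵀM` and `L`
normalise the two terms): `β = 0` reduces to standard PCA, `β = 1` to
Laplacian embedding, and the closed-form `S ≡ 0` path (`solve_glpca`,
`GLPCA`) is plain graph-Laplacian PCA.

The ALM solver alternates a half-thresholding update of `S` (the exact
proximal map of the entrywise L1/2 penalty), an eigen-update of `V` from
the normalised matrix `G_β`, the closed form `U = M V`, and multiplier
ascent with geometric growth of the penalty `μ`.

The package also ships the planted-factor simulation generator and the
identification-accuracy benchmark used to evaluate the method: 2000
genes × 10 samples with four disjoint 50-gene block factors of covariance
eigenvalues 400/300/200/100 against a unit background, 200 genes selected
per fit and scored against the planted blocks.

## Worked example

```python
import numpy as np
from l12glpca import (SimulationSpec, SolverConfig, simulate_dataset,
                      solve, select_features, accuracy)

expr, truth = simulate_dataset(SimulationSpec(seed=0))   # 2000 x 10
decomp = solve(expr.values, SolverConfig(k=4, beta=0.5))
print(f"converged={decomp.converged} after {decomp.iterations} iterations, "
      f"residual={decomp.residual_trace[-1]:.2e}")
selected = select_features(decomp, r=200)
print(f"identification accuracy: {accuracy(selected, truth):.3f}")
```

prints

```
converged=True after 101 iterations, residual=9.37e-07
identification accuracy: 0.705
```

i.e. the ALM constraint `S = X − UVᵀ` is met to the default tolerance
(relative residual 1e−6) after 101 sweeps, and 141 of the 200 selected
genes fall inside the planted blocks at the default noise level.

The estimator interface composes with scikit-learn (`X` oriented
samples × features):

```python
from l12glpca import L12GLPCA
est = L12GLPCA(n_components=4, beta=0.5).fit(expr.values.T)
est.feature_scores_     # per-gene loading norms
est.embedding_          # orthonormal sample coordinates
```

The same pipeline is available from the shell:

```
l12glpca simulate --m 2000 --n 10 --seed 0 --output sim.tsv
l12glpca fit --input sim.tsv --k 4 --beta 0.5 --output-prefix run
l12glpca benchmark --methods l12glpca,pca --replicates 30 --output bench
```

`fit` writes `run.U.tsv`, `run.V.tsv`, `run.S.tsv`, a gene ranking and a
JSON report sufficient to rerun the fit bit-identically.

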