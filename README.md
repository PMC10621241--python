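# ebmf — empirical Bayes matrix factorization

`ebmf` fits low-rank factorizations

```
Y = Σₖ lₖ fₖᵀ + E,   E_ij ~ N(0, 1/τ_ij),
lₖ ~ iid g_lk,  fₖ ~ iid g_fk,
```

where the priors `g_lk`, `g_fk` are *estimated from the data* within a
chosen family — a point mass at zero, a zero-mean normal, the
sparsity-inducing point-normal `π₀ δ₀ + (1−π₀) N(0, a)`, or a scale
mixture of zero-centered normals on a grid. Because each factor and each
loading gets its own adaptively estimated prior, the model tunes its own
shrinkage: it can combine dense and sparse factors in one fit with no
penalty parameters to cross-validate. It is aimed at the kind of
structure found in genomics matrices (samples × genes, variants ×
tissues), recommender matrices, and any setting where some factors are
sparse and others are not.

Fitting maximizes a variational lower bound F on the log-likelihood over
fully factorized posteriors. Each coordinate update reduces to an
empirical-Bayes normal-means problem on weighted-regression summaries

```
l̂ᵢ = Σⱼ τᵢⱼ Yᵢⱼ f̄ⱼ / Σⱼ τᵢⱼ f²̄ⱼ ,   sᵢ = (Σⱼ τᵢⱼ f²̄ⱼ)^(-1/2),
```

so only first and second posterior moments are ever stored. Factors are
added greedily on residuals and optionally refined by backfitting; a
factor whose estimated priors collapse to point masses at zero is
removed, which selects the rank K automatically and conservatively: a
kept factor certifies that the *likelihood itself* prefers it over the
rank-0 model. Missing entries are handled by setting τ_ij = 0, which
also powers matrix completion via the posterior-mean reconstruction.

## Worked example

Simulate the built-in rank-3 sparse bi-cluster design (150×240, three
disjoint sample blocks each loaded on one factor, noise variance 4), fit
it, and score the reconstruction:

```
$ ebmf simulate --design bicluster --seed 4 --output sim
wrote 150x240 bicluster design (seed 4) to sim
$ ebmf fit --input sim/y.tsv --output fit --kmax 10 --backfit
K=3 objective=-76755.909424
$ ebmf evaluate --truth sim --fit fit
RRMSE=0.416003
K=3
```

The fit recovered the true rank (K=3) and reconstructs the signal matrix
with relative root mean squared error 0.416; the rank-3 truncated-SVD
reconstruction of the same data has RRMSE ≈ 0.72, illustrating the gain
from adaptive shrinkage. `fit/` contains `loadings.tsv` and
`factors.tsv` (loadings normalized to unit norm, factors carrying the
scale) and `fit.json` with the fitted priors, the per-factor proportion
of variance explained (here 0.046, 0.018, 0.003 — the blocks are small
relative to the noise), and the objective trace, which is non-decreasing
by construction.

The same functionality is available as a library:

```python
from ebmf import greedy_fit, backfit, impute, sim_bicluster

truth = sim_bicluster(seed=4)
fit = greedy_fit(truth.Y, kmax=10)          # point-normal priors by default
fit = backfit(truth.Y, fit)
Y_hat = impute(fit)                          # posterior-mean reconstruction
```

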