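# Methods

## Model

The data are an n×p matrix Y, possibly with missing entries, modeled as

    Y_ij = Σₖ l_ki f_kj + E_ij,    E_ij ~ N(0, 1/τ_ij),

with the entries of each loading lₖ i.i.d. from a prior g_lk and the
entries of each factor fₖ i.i.d. from g_fk. The priors are not fixed:
each is estimated from the data within a family G (empirical Bayes).
Supported families, all symmetric with mode 0:

| family            | form                           | estimated          |
|-------------------|--------------------------------|--------------------|
| point_mass_zero   | δ₀                             | —                  |
| normal            | N(0, a)                        | a ≥ 0              |
| point_normal      | π₀ δ₀ + (1−π₀) N(0, a)         | π₀ ∈ [0,1], a ≥ 0  |
| scale_mix_normal  | Σₘ πₘ N(0, σₘ²), σ₁ = 0 fixed grid | weights π     |

The precision τ lies in a structured set: constant, per-column, per-row,
or fixed per entry. Missing cells carry τ_ij = 0, which removes them
from every sum; this is a missing-at-random assumption.

## Variational fitting

The marginal likelihood is intractable, so we maximize the evidence
lower bound F over fully factorized posteriors q = Π q(l_ki) Π q(f_kj):

    F = Σ_obs [ ½ log(τ_ij/2π) − ½ τ_ij E_q R²_ij ]
        − Σₖ KL(q_lk ‖ g_lk) − Σₖ KL(q_fk ‖ g_fk),

with E_q R²_ij the expected squared residual. Only first and second
moments of q are needed anywhere. Coordinate ascent cycles three block
updates, each of which cannot decrease F:

1. **τ update** — per structure block, τ = (#observed cells)/(Σ E_q R²).
2. **loading update** — given the factor moments, the optimal (q_l, g_l)
   is the solution of an empirical-Bayes normal-means (EBNM) problem on
   the weighted regression estimates l̂ᵢ with standard errors sᵢ; the
   EBNM solver returns the estimated prior, its marginal log-likelihood,
   and exact posterior moments.
3. **factor update** — the same with rows and columns swapped.

The KL terms come for free from the EBNM identity
KL(q‖g) = E_q log p(x|θ) − log p(x|ĝ): since the solver returns the
exact posterior, its marginal log-likelihood equals the normal-means
evidence bound. The expected log-likelihood is evaluated in the
cancellation-free form E_q(x−θ)² = (x−θ̄)² + (θ²̄ − θ̄²), which matters
when standard errors are tiny (near-perfect fits).

For K > 1 the same rank-1 update is applied to the residual matrix with
the other factors' posterior means removed. Because the q's factorize
across factors, E_q R² expands to
(Y − Σ l̄f̄ᵀ)² − Σ outer(l̄², f̄²) + Σ outer(l²̄, f²̄); computing the
two correction terms with component-wise squares makes the identity
exact (bitwise) when moments are degenerate.

## EBNM solvers

* **normal**: 1-D bounded search for a on [0, max x²] with the a = 0
  boundary checked; posterior is conjugate.
* **point_normal**: quasi-Newton (L-BFGS-B, analytic gradient) in
  (logit π₀, log a) from four deterministic π₀ starts
  {0.1, 0.5, 0.9, 0.99} with a started at max(mean(x²−s²), min s²); the
  likelihood is non-convex and multi-start is cheap and reproducible.
  Bounds: logit π₀ ∈ [−15, 15], log a ∈ [log(1e−9·min s²), log(4·max x²)].
* **scale_mix_normal**: the likelihood is concave in the weights; EM runs
  until the log-likelihood increment falls below 1e−8 per coordinate
  (cap 1000 iterations). Default grid: σ₁ = 0, then a geometric ladder
  with ratio √2 from (min s)/10 to 2·√max(x²−s², min s²) — dense enough
  that the grid is not a tuning parameter.
* Coordinates with infinite standard error (no information, e.g. a fully
  missing row) contribute nothing to the likelihood and receive the
  prior moments.

**Warm starts.** In iterative fitting, each side's previous prior is
passed back to its solver as an extra starting point (point-normal) or
as the fixed grid plus initial weights (scale mixture). This guarantees
the refit never has lower marginal likelihood than the previous prior
evaluated on the new summaries, which is exactly the condition needed
for F to be non-decreasing across iterations; without it, grid
reconstruction can change the effective prior family mid-run and cause
~1e−5-size objective decreases.

## Rank selection and the null check

A factor whose estimated priors collapse to point masses vanishes
exactly. In addition, after each factor's optimization (and after each
backfit sweep) the objective with the factor as fitted is compared
against the objective with that factor zeroed and τ re-estimated; the
better state is kept. Because F equals the log-likelihood exactly when a
prior is δ₀, a kept factor certifies that the likelihood also prefers
it — rank selection is conservative by construction. The choice to
re-estimate τ in the zeroed comparison (rather than condition on the
current τ) is exposed in the configuration; re-estimation is the default
as it makes the comparison a true rank-0 maximum.

## Initialization

Each new factor is initialized by the leading rank-1 approximation of
the current residual matrix, computed by alternating least squares over
observed cells only (equivalent to the top singular pair when fully
observed; zero-penalty completion otherwise). The start is a normalized
vector of ones, with a deterministic basis-vector restart if that start
is orthogonal to the leading direction, so fits are bit-reproducible.

## Convergence and numerical choices

* Stopping rules are *increment-based*: a factor's coordinate ascent
  (and a backfit sweep cycle) stops when F rises by less than
  tol × (#observed cells), default tol = 1e−7, cap 500 iterations
  (100 backfit sweeps). Increments of F are invariant to rescaling the
  data (a rescale shifts F by a constant), so fits are scale-equivariant:
  fitting cY yields the reconstruction scaled by c. Relative-change
  rules would break this.
* Perfect-fit precision is capped at τ = 1e8 (configurable) to keep F
  finite; blocks with no observed cells get τ = 0.
* A factor counts as zero when max|l̄|·max|f̄| < 1e−12 or both priors
  are point masses.
* The recorded objective trace contains the rank-0 value, one value per
  accepted factor, and one per backfit sweep; each recorded step is
  provably non-decreasing. Per-iteration values inside one factor's
  optimization are monotone as well but are not spliced into the trace,
  because the jump at a new factor's initialization precedes any update.
* Identifiability: each loading/factor pair is determined only up to a
  scalar; on output, loadings are rescaled to unit norm with factors
  absorbing the scale (second moments rescaled consistently; products
  unchanged).

## Synthetic study designs

Two generators reproduce standard evaluation settings, with draw order
(loadings, factors, noise) fixed for reproducibility:

* **rank-1 sparse loading** (n=200, p=300):
  l_i ~ π₀δ₀ + (1−π₀)·(1/5)Σₘ N(0, σₘ²), σ² ∈ {0.25, 0.5, 1, 2, 4},
  f_j ~ N(0,1), noise precision τ; canonical settings
  (π₀, τ) = (0.9, 1), (0.3, 1/16), (0, 1/25).
* **rank-3 bi-cluster** (n=150, p=240, noise variance 4): rows 1–10,
  11–60, 61–150 load factors 1–3 with sds 2, 1, ½; the factors are
  supported on columns 1–80, 81–160, 161–240 with sds ½, 1, 2.

These designs exercise sparsity adaptation and rank selection but are
idealized: noise is exactly Gaussian and homoskedastic, blocks are
disjoint, and entries are independent. Passing tests on them shows the
algorithm recovers planted sparse low-rank structure under correctly
specified noise; it says nothing about heavy-tailed errors, correlated
noise, or overlapping factors in real data.

Evaluation metrics: RRMSE(B̂, B) = √(Σ(B̂−B)²/ΣB²) against the true
signal matrix, and held-out RMSE over masked cells. Hold-out masks come
from orthogonal cross-validation: rows and columns are partitioned into
k random groups and fold t holds out the observed cells whose row-group
plus column-group is t mod k, so no fold empties a row or column. The
truncated SVD (best rank-K approximation) serves as the reference
method.

## Known limitations

* The variational rank selection is conservative. In the bi-cluster
  design the weakest block (10×80 cells, per-cell signal variance 1
  against noise variance 4) sits essentially at the spectral detection
  threshold; on roughly half of random replicates the bound F genuinely
  prefers the rank-2 model (the gap is a few nats even when the
  optimizer is handed the true factor), so the greedy fit returns K = 2
  there. This is the documented cost of the approach: structure that is
  kept is trustworthy, subtle structure can be missed.
* Only the first two posterior moments are computed; no credible
  intervals or posterior correlations between factors.
* Greedy fitting inherits the local-optimum behavior of coordinate
  ascent; backfitting mitigates but does not eliminate it.
* The point-normal and scale-mixture solvers assume symmetric,
  zero-mode signals; asymmetric or nonzero-mode priors are out of scope.
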