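"""Multi-factor EBMF fitting.

Two fitting strategies are provided, both built from the same rank-1
coordinate ascent:

* ``greedy_fit`` adds factors one at a time, each fitted to the residuals
  left by the factors found so far, and stops as soon as a newly added
  factor is optimized to exactly zero;
* ``backfit`` cyclically refines each factor given all the others, which
  can substantially improve a greedy solution.

Rank selection falls out of the empirical-Bayes structure: when the data do
not support a factor, its estimated priors collapse to point masses at
zero. ``nullcheck`` guards against local optima by explicitly comparing the
objective with a factor as fitted against the objective with that factor
zeroed out (the rank-0 alternative is exactly the log-likelihood, so
keeping a factor guarantees the likelihood also prefers it).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from ebmf.core import (
    FactorMoments,
    ObservedMatrix,
    PrecisionModel,
    TAU_CLAMP,
    compute_objective,
    expected_residual2,
    kl_term,
    regression_stats,
    update_tau,
)
from ebmf.ebnm import NormalMeansData, PriorSpec, fit_point_mass, solve_ebnm

__all__ = [
    "RunConfig",
    "EBMFFit",
    "init_rank1",
    "fit_rank1",
    "greedy_fit",
    "backfit",
    "nullcheck",
    "impute",
    "compute_pve",
    "normalize_fit",
]


@dataclass
class RunConfig:
    """Knobs for a fitting run.

    tol is the per-observed-cell increase in the objective F below which a
    factor's coordinate ascent (and a backfit sweep cycle) is considered
    converged; increments are invariant to rescaling the data, so fits are
    scale-equivariant.
    """

    prior_family_l: str = "point_normal"
    prior_family_f: str = "point_normal"
    kmax: int = 20
    tau_structure: str = "constant"
    tol: float = 1e-7
    max_iter: int = 500
    seed: int = 0
    nullcheck: bool = True
    backfit: bool = False
    max_backfit_sweeps: int = 100
    tau_clamp: float = TAU_CLAMP
    nullcheck_retau: bool = True  # re-estimate tau when zeroing a factor

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.kmax < 1:
            raise ValueError("kmax must be at least 1")


@dataclass
class EBMFFit:
    """A fitted EBMF model: K factors' moments, priors, precision, trace."""

    factors: list[FactorMoments] = field(default_factory=list)
    priors_l: list[PriorSpec] = field(default_factory=list)
    priors_f: list[PriorSpec] = field(default_factory=list)
    kl_l: list[float] = field(default_factory=list)
    kl_f: list[float] = field(default_factory=list)
    tau: PrecisionModel | None = None
    objective_trace: list[float] = field(default_factory=list)
    pve: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def K(self) -> int:
        return len(self.factors)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.tau.shape

    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else -np.inf


def init_rank1(Y: ObservedMatrix, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Leading rank-1 approximation by alternating least squares.

    Minimizes sum over observed cells of (Y_ij - l_i f_j)^2, which for a
    fully observed matrix converges to the top singular vector pair and for
    a partially observed matrix is zero-penalty low-rank completion.
    Deterministic: starts from a normalized vector of ones, with a basis-
    vector restart if that start is orthogonal to the leading direction.
    """
    if Y.n_observed == 0:
        raise ValueError("cannot initialize from an all-missing matrix")
    n, p = Y.shape
    vals = Y.values  # zero at unobserved cells already
    mask = Y.mask.astype(float)

    def als(l: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.zeros(p)
        for _ in range(max_iter):
            denom_f = mask.T @ (l * l)
            f = np.where(denom_f > 0, vals.T @ l, 0.0)
            f = np.where(denom_f > 0, f / np.where(denom_f > 0, denom_f, 1.0), 0.0)
            denom_l = mask @ (f * f)
            l_new = np.where(denom_l > 0, vals @ f, 0.0)
            l_new = np.where(
                denom_l > 0, l_new / np.where(denom_l > 0, denom_l, 1.0), 0.0
            )
            norm = np.linalg.norm(l_new)
            if norm == 0:
                return np.zeros(n), np.zeros(p)
            l_new = l_new / norm
            if np.linalg.norm(l_new - l) < 1e-13 or np.linalg.norm(l_new + l) < 1e-13:
                l = l_new
                break
            l = l_new
        denom_f = mask.T @ (l * l)
        f = np.where(denom_f > 0, vals.T @ l, 0.0)
        f = np.where(denom_f > 0, f / np.where(denom_f > 0, denom_f, 1.0), 0.0)
        return l, f

    l, f = als(np.full(n, 1.0 / np.sqrt(n)))
    if np.all(f == 0) and np.any(vals[Y.mask] != 0):
        # the all-ones start was orthogonal to the leading direction
        i = int(np.argmax(np.sum(vals * vals, axis=1)))
        e = np.zeros(n)
        e[i] = 1.0
        l, f = als(e)
    return l, f


def _blank_prior() -> PriorSpec:
    return PriorSpec(family="point_mass_zero")


def _residual_matrix(Y: ObservedMatrix, fit: EBMFFit, k: int) -> ObservedMatrix:
    """Residuals of Y after removing every factor except k."""
    resid = Y.values.copy()
    for j, fm in enumerate(fit.factors):
        if j != k:
            resid -= np.outer(fm.l_mean, fm.f_mean)
    return ObservedMatrix(np.where(Y.mask, resid, 0.0), Y.mask)


def _refresh_tau(Y: ObservedMatrix, fit: EBMFFit, config: RunConfig) -> None:
    R2 = expected_residual2(Y, fit.factors)
    fit.tau = update_tau(
        R2, Y.mask, config.tau_structure, fixed=fit.tau, tau_clamp=config.tau_clamp
    )


def _ebnm_side_update(
    resid: ObservedMatrix,
    tau: PrecisionModel,
    v: np.ndarray,
    w: np.ndarray,
    side: str,
    family: str,
    warm_start: PriorSpec | None = None,
) -> tuple:
    est, se = regression_stats(resid, tau, v, w, side)
    data = NormalMeansData(est, se)
    if not np.any(data.finite):
        nm = fit_point_mass(data)
    else:
        nm = solve_ebnm(data, family, warm_start=warm_start)
    return nm, kl_term(nm, data)


def _update_factor_once(
    Y: ObservedMatrix, fit: EBMFFit, k: int, config: RunConfig,
    resid: ObservedMatrix | None = None,
) -> None:
    """One full coordinate cycle on factor k: tau, loading, factor."""
    if resid is None:
        resid = _residual_matrix(Y, fit, k)
    fm = fit.factors[k]
    _refresh_tau(Y, fit, config)
    nm_l, kl_l = _ebnm_side_update(
        resid, fit.tau, fm.f_mean, fm.f_mean2, "loading", config.prior_family_l,
        warm_start=fit.priors_l[k],
    )
    fm.l_mean, fm.l_mean2 = nm_l.post_mean, nm_l.post_mean2
    fit.priors_l[k], fit.kl_l[k] = nm_l.g_hat, kl_l
    nm_f, kl_f = _ebnm_side_update(
        resid, fit.tau, fm.l_mean, fm.l_mean2, "factor", config.prior_family_f,
        warm_start=fit.priors_f[k],
    )
    fm.f_mean, fm.f_mean2 = nm_f.post_mean, nm_f.post_mean2
    fit.priors_f[k], fit.kl_f[k] = nm_f.g_hat, kl_f


def _objective(Y: ObservedMatrix, fit: EBMFFit) -> float:
    return compute_objective(Y, fit.tau, fit.factors, fit.kl_l, fit.kl_f)


def _optimize_factor(
    Y: ObservedMatrix, fit: EBMFFit, k: int, config: RunConfig
) -> list[float]:
    """Coordinate ascent on factor k with all other factors fixed.

    Returns the per-iteration objective values (monotone non-decreasing).
    """
    resid = _residual_matrix(Y, fit, k)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(config.max_iter):
        _update_factor_once(Y, fit, k, config, resid=resid)
        F = _objective(Y, fit)
        trace.append(F)
        if fit.factors[k].is_zero():
            break
        # increment-based stopping: the objective shifts by a constant when
        # the data are rescaled, so thresholds on |F| are scale-sensitive
        # while thresholds on the per-cell increment are not
        if np.isfinite(prev) and F - prev < config.tol * Y.n_observed:
            break
        prev = F
    return trace


def _zero_factor(fit: EBMFFit, k: int) -> None:
    n, p = fit.factors[k].l_mean.size, fit.factors[k].f_mean.size
    fit.factors[k] = FactorMoments.zeros(n, p)
    fit.priors_l[k] = _blank_prior()
    fit.priors_f[k] = _blank_prior()
    fit.kl_l[k] = 0.0
    fit.kl_f[k] = 0.0


def nullcheck(Y: ObservedMatrix, fit: EBMFFit, k: int,
              config: RunConfig | None = None) -> EBMFFit:
    """Compare factor k against its rank-0 replacement and keep the better.

    The zeroed alternative sets both priors of factor k to point masses at
    zero (so its moments vanish and its KL terms are zero) and re-estimates
    tau. Because the objective equals the log-likelihood exactly when a
    prior is a point mass, keeping the fitted factor certifies that the
    likelihood itself prefers it over the rank-0 model.
    """
    if config is None:
        config = RunConfig()
    if fit.K == 0 or k >= fit.K:
        return fit
    as_is = copy.deepcopy(fit)
    _refresh_tau(Y, as_is, config)
    f_keep = _objective(Y, as_is)

    zeroed = copy.deepcopy(fit)
    _zero_factor(zeroed, k)
    if config.nullcheck_retau:
        _refresh_tau(Y, zeroed, config)
    f_zero = _objective(Y, zeroed)

    if f_zero >= f_keep:
        zeroed.objective_trace = fit.objective_trace
        zeroed.objective_trace.append(f_zero)
        return zeroed
    as_is.objective_trace = fit.objective_trace
    as_is.objective_trace.append(f_keep)
    return as_is


def _new_fit(Y: ObservedMatrix, config: RunConfig) -> EBMFFit:
    fit = EBMFFit()
    _refresh_tau(Y, fit, config)
    fit.objective_trace.append(_objective(Y, fit))
    return fit


def _append_factor(
    Y: ObservedMatrix, fit: EBMFFit, l0: np.ndarray, f0: np.ndarray
) -> None:
    fit.factors.append(FactorMoments.from_vectors(l0, f0))
    fit.priors_l.append(_blank_prior())
    fit.priors_f.append(_blank_prior())
    fit.kl_l.append(0.0)
    fit.kl_f.append(0.0)


def fit_rank1(
    Y: ObservedMatrix,
    family_l: str = "point_normal",
    family_f: str = "point_normal",
    config: RunConfig | None = None,
) -> EBMFFit:
    """Fit a single-factor EBMF model by coordinate ascent.

    Iterates precision, loading, and factor updates until the relative
    change in F drops below the configured tolerance. The recorded
    objective trace is non-decreasing. With the null check enabled, a
    factor not supported by the data is returned as exactly zero (K = 0 in
    effect, though the zeroed moments are kept for shape stability).
    """
    if config is None:
        config = RunConfig()
    config = replace(config, prior_family_l=family_l, prior_family_f=family_f)

    fit = EBMFFit()
    l0, f0 = init_rank1(Y)
    _append_factor(Y, fit, l0, f0)
    _refresh_tau(Y, fit, config)
    sub = _optimize_factor(Y, fit, 0, config)
    fit.objective_trace.extend(sub)
    if config.nullcheck:
        fit = nullcheck(Y, fit, 0, config)
        if fit.factors[0].is_zero():
            fit.factors, fit.priors_l, fit.priors_f = [], [], []
            fit.kl_l, fit.kl_f = [], []
    fit.pve = compute_pve(fit)
    return fit


def greedy_fit(
    Y: ObservedMatrix,
    kmax: int | None = None,
    family_l: str = "point_normal",
    family_f: str = "point_normal",
    config: RunConfig | None = None,
) -> EBMFFit:
    """Greedy factor addition with automatic stopping.

    Starting from the rank-0 model, each new factor is initialized by a
    rank-1 approximation of the current residual matrix, optimized to
    convergence with the other factors held fixed, and passed through the
    null check. The first factor optimized to exactly zero terminates the
    loop. The recorded objective trace (rank-0 value, then one value per
    accepted factor) is non-decreasing.
    """
    if config is None:
        config = RunConfig()
    config = replace(config, prior_family_l=family_l, prior_family_f=family_f)
    if kmax is not None:
        config.kmax = kmax

    fit = _new_fit(Y, config)
    for _ in range(config.kmax):
        resid = _residual_matrix_full(Y, fit)
        l0, f0 = init_rank1(resid)
        _append_factor(Y, fit, l0, f0)
        _optimize_factor(Y, fit, fit.K - 1, config)
        if config.nullcheck:
            fit = nullcheck(Y, fit, fit.K - 1, config)
        else:
            _refresh_tau(Y, fit, config)
            fit.objective_trace.append(_objective(Y, fit))
        if fit.factors[-1].is_zero():
            _drop_zero_factors(fit)
            break
    _drop_zero_factors(fit)
    fit.pve = compute_pve(fit)
    return fit


def _residual_matrix_full(Y: ObservedMatrix, fit: EBMFFit) -> ObservedMatrix:
    resid = Y.values.copy()
    for fm in fit.factors:
        resid -= np.outer(fm.l_mean, fm.f_mean)
    return ObservedMatrix(np.where(Y.mask, resid, 0.0), Y.mask)


def _drop_zero_factors(fit: EBMFFit) -> None:
    keep = [i for i, fm in enumerate(fit.factors) if not fm.is_zero()]
    fit.factors = [fit.factors[i] for i in keep]
    fit.priors_l = [fit.priors_l[i] for i in keep]
    fit.priors_f = [fit.priors_f[i] for i in keep]
    fit.kl_l = [fit.kl_l[i] for i in keep]
    fit.kl_f = [fit.kl_f[i] for i in keep]


def backfit(
    Y: ObservedMatrix, fit: EBMFFit, config: RunConfig | None = None
) -> EBMFFit:
    """Cyclic refinement of all factors (coordinate ascent sweeps).

    Each sweep updates every factor in turn against the residuals of the
    others, then applies the null check factor-by-factor; factors that
    collapse to zero are removed. F never decreases relative to the input
    fit, and one objective value is recorded per sweep.
    """
    if config is None:
        config = RunConfig()
    fit = copy.deepcopy(fit)
    if fit.K == 0:
        return fit
    prev = fit.objective_trace[-1] if fit.objective_trace else -np.inf
    for _ in range(config.max_backfit_sweeps):
        for k in range(fit.K):
            _update_factor_once(Y, fit, k, config)
        if config.nullcheck:
            for k in range(fit.K):
                fit = nullcheck(Y, fit, k, config)
                fit.objective_trace.pop()  # keep one trace entry per sweep
            _drop_zero_factors(fit)
        _refresh_tau(Y, fit, config)
        F = _objective(Y, fit)
        fit.objective_trace.append(F)
        if fit.K == 0:
            break
        if np.isfinite(prev) and F - prev < config.tol * Y.n_observed:
            break
        prev = F
    fit.pve = compute_pve(fit)
    return fit


def impute(fit: EBMFFit) -> np.ndarray:
    """Posterior-mean reconstruction sum_k lbar_k fbar_k^T at every cell."""
    n, p = fit.shape
    out = np.zeros((n, p))
    for fm in fit.factors:
        out += np.outer(fm.l_mean, fm.f_mean)
    return out


def compute_pve(fit: EBMFFit) -> np.ndarray:
    """Proportion of variance explained per factor.

    pve_k = s_k / (sum_k' s_k' + sum_obs 1/tau_ij) with
    s_k = sum_obs (lbar_ki fbar_kj)^2. A loose but convenient summary of
    each factor's share of signal (factors are not orthogonal).
    """
    if fit.K == 0:
        return np.zeros(0)
    obs = fit.tau.tau > 0
    s = np.array(
        [np.sum(np.outer(fm.l_mean, fm.f_mean)[obs] ** 2) for fm in fit.factors]
    )
    noise = float(np.sum(1.0 / fit.tau.tau[obs]))
    return s / (s.sum() + noise)


def normalize_fit(fit: EBMFFit) -> EBMFFit:
    """Rescale each loading to unit Euclidean norm, factors absorb the scale.

    The products lbar_k fbar_k^T are unchanged; second moments are rescaled
    consistently (loadings by 1/c^2, factors by c^2). The stored priors keep
    their original scale. Zero factors are left untouched.
    """
    fit = copy.deepcopy(fit)
    for fm in fit.factors:
        c = float(np.linalg.norm(fm.l_mean))
        if c == 0:
            continue
        fm.l_mean = fm.l_mean / c
        fm.l_mean2 = fm.l_mean2 / c**2
        fm.f_mean = fm.f_mean * c
        fm.f_mean2 = fm.f_mean2 * c**2
    return fit
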