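"""Empirical-Bayes normal-means (EBNM) solvers.

The normal-means model observes x_j ~ N(theta_j, s_j^2) with known s_j and
theta_j drawn i.i.d. from an unknown prior g in a family G. An EBNM solver
(i) estimates g by maximizing the marginal likelihood of x and (ii) returns
the posterior first and second moments of each theta_j under the fitted
prior. Four families are supported, all symmetric and unimodal at zero:

* ``point_mass_zero`` — the degenerate prior delta_0;
* ``normal``          — N(0, a) with a >= 0 estimated;
* ``point_normal``    — pi0 * delta_0 + (1 - pi0) * N(0, a), the fast
  sparsity-inducing family;
* ``scale_mix_normal``— sum_m pi_m N(0, sigma_m^2) over a fixed grid of
  standard deviations that includes sigma = 0; the weights are estimated
  (the adaptive-shrinkage family).

A standard error of ``+inf`` marks a coordinate carrying no information:
it contributes nothing to the marginal likelihood and receives the prior
moments as its posterior moments. This arises in matrix factorization when
an entire row or column of the data is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logsumexp

__all__ = [
    "NormalMeansData",
    "PriorSpec",
    "NormalMeansFit",
    "nm_marginal_loglik",
    "fit_point_mass",
    "fit_normal",
    "fit_point_normal",
    "fit_scale_mix_normal",
    "solve_ebnm",
    "default_smn_grid",
]

_LOG2PI = np.log(2.0 * np.pi)

FAMILIES = ("point_mass_zero", "normal", "point_normal", "scale_mix_normal")


@dataclass
class NormalMeansData:
    """Observations ``x`` with known standard errors ``s`` (``+inf`` allowed)."""

    x: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.x.ndim != 1 or self.s.ndim != 1:
            raise ValueError("x and s must be one-dimensional")
        if self.x.shape != self.s.shape:
            raise ValueError(
                f"length mismatch: len(x)={self.x.size}, len(s)={self.s.size}"
            )
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains non-finite values")
        if np.any(np.isnan(self.s)) or np.any(self.s <= 0):
            raise ValueError("all standard errors must be positive (inf allowed)")

    @property
    def finite(self) -> np.ndarray:
        """Boolean mask of coordinates with finite standard error."""
        return np.isfinite(self.s)


@dataclass
class PriorSpec:
    """A prior g in one of the supported families.

    Only the fields relevant to ``family`` are meaningful: ``pi0`` and ``a``
    for point-normal, ``a`` for normal, ``grid``/``weights`` for the scale
    mixture. ``grid`` holds component standard deviations, strictly
    increasing and starting at 0.
    """

    family: str
    pi0: float | None = None
    a: float | None = None
    grid: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown prior family: {self.family!r}")
        if self.family == "normal":
            if self.a is None or self.a < 0:
                raise ValueError("normal prior requires slab variance a >= 0")
        if self.family == "point_normal":
            if self.pi0 is None or not (0.0 <= self.pi0 <= 1.0):
                raise ValueError("point_normal requires pi0 in [0, 1]")
            if self.a is None or self.a < 0:
                raise ValueError("point_normal requires slab variance a >= 0")
        if self.family == "scale_mix_normal":
            self.grid = np.asarray(self.grid, dtype=float)
            self.weights = np.asarray(self.weights, dtype=float)
            if self.grid.size == 0:
                raise ValueError("scale mixture grid is empty")
            if self.grid[0] != 0.0:
                raise ValueError("scale mixture grid must start at sigma = 0")
            if np.any(np.diff(self.grid) <= 0):
                raise ValueError("scale mixture grid must be strictly increasing")
            if self.weights.shape != self.grid.shape:
                raise ValueError("weights and grid must have the same length")
            if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-10:
                raise ValueError("weights must be a simplex vector")

    def second_moment(self) -> float:
        """E_g[theta^2]: the prior variance (the prior mean is 0)."""
        if self.family == "point_mass_zero":
            return 0.0
        if self.family == "normal":
            return float(self.a)
        if self.family == "point_normal":
            return float((1.0 - self.pi0) * self.a)
        return float(np.sum(self.weights * self.grid**2))

    def is_point_mass(self, tol: float = 0.0) -> bool:
        """Whether g is (numerically) the point mass at zero."""
        if self.family == "point_mass_zero":
            return True
        if self.family == "normal":
            return self.a <= tol
        if self.family == "point_normal":
            return self.pi0 >= 1.0 - tol or self.a <= tol
        return bool(np.sum(self.weights[1:]) <= tol)


@dataclass
class NormalMeansFit:
    """Fitted prior, its marginal log-likelihood, and posterior moments."""

    g_hat: PriorSpec
    loglik: float
    post_mean: np.ndarray
    post_mean2: np.ndarray

    def __post_init__(self) -> None:
        self.post_mean = np.asarray(self.post_mean, dtype=float)
        self.post_mean2 = np.asarray(self.post_mean2, dtype=float)


def _log_norm_pdf(x: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log N(x; 0, var) for var > 0."""
    return -0.5 * (_LOG2PI + np.log(var) + x * x / var)


def _mixture_loglik_terms(g: PriorSpec, x: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Per-coordinate log marginal density under g (finite-s coordinates).

    For every supported family the marginal of x_j is a finite mixture of
    zero-mean normals with variances s_j^2 + sigma_m^2.
    """
    if g.family == "point_mass_zero":
        return _log_norm_pdf(x, s2)
    if g.family == "normal":
        return _log_norm_pdf(x, s2 + g.a)
    if g.family == "point_normal":
        log_w = _safe_log(np.array([g.pi0, 1.0 - g.pi0]))
        comps = np.stack([_log_norm_pdf(x, s2), _log_norm_pdf(x, s2 + g.a)])
        return logsumexp(comps + log_w[:, None], axis=0)
    log_w = _safe_log(g.weights)
    comps = _log_norm_pdf(x[None, :], s2[None, :] + g.grid[:, None] ** 2)
    return logsumexp(comps + log_w[:, None], axis=0)


def _safe_log(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(w)


def nm_marginal_loglik(g: PriorSpec, data: NormalMeansData) -> float:
    """Marginal log-likelihood sum_j log integral N(x_j; theta, s_j^2) g(dtheta).

    Coordinates with infinite standard error contribute zero.
    """
    fin = data.finite
    if not np.any(fin):
        return 0.0
    terms = _mixture_loglik_terms(g, data.x[fin], data.s[fin] ** 2)
    return float(np.sum(terms))


def _prior_moment_fill(g: PriorSpec, data: NormalMeansData,
                       post_mean: np.ndarray, post_mean2: np.ndarray) -> None:
    """Install prior moments at no-information coordinates (in place)."""
    inf = ~data.finite
    if np.any(inf):
        post_mean[inf] = 0.0
        post_mean2[inf] = g.second_moment()


def fit_point_mass(data: NormalMeansData) -> NormalMeansFit:
    """Degenerate fit with g = delta_0; posterior moments are identically zero."""
    g = PriorSpec(family="point_mass_zero")
    m = data.x.size
    return NormalMeansFit(
        g_hat=g,
        loglik=nm_marginal_loglik(g, data),
        post_mean=np.zeros(m),
        post_mean2=np.zeros(m),
    )


def fit_normal(data: NormalMeansData) -> NormalMeansFit:
    """EBNM with a zero-mean normal prior N(0, a), a estimated by marginal ML.

    The marginal likelihood is a smooth one-dimensional function of a; it is
    maximized by bounded search on [0, max(x^2)] (the ML estimate cannot
    exceed the largest squared observation) with the a = 0 boundary checked
    explicitly.
    """
    fin = data.finite
    if not np.any(fin):
        raise ValueError("no informative observations (all standard errors infinite)")
    x, s2 = data.x[fin], data.s[fin] ** 2

    def neg_loglik(a: float) -> float:
        return -float(np.sum(_log_norm_pdf(x, s2 + a)))

    a_hi = max(float(np.max(x * x)), float(np.min(s2))) * 1.000001
    res = minimize_scalar(
        neg_loglik, bounds=(0.0, a_hi), method="bounded",
        options={"xatol": 1e-12 * a_hi},
    )
    a_hat = float(res.x) if res.fun <= neg_loglik(0.0) else 0.0
    g = PriorSpec(family="normal", a=a_hat)

    with np.errstate(invalid="ignore", over="ignore"):
        shrink = np.where(data.finite, a_hat / (a_hat + data.s**2), 0.0)
        post_var = np.where(
            data.finite, a_hat * data.s**2 / (a_hat + data.s**2), 0.0
        )
    post_mean = data.x * shrink
    post_mean2 = post_mean**2 + post_var
    _prior_moment_fill(g, data, post_mean, post_mean2)
    return NormalMeansFit(g, nm_marginal_loglik(g, data), post_mean, post_mean2)


def _pn_negloglik_grad(t: np.ndarray, x: np.ndarray, s2: np.ndarray):
    """Negative point-normal marginal loglik and gradient in (logit pi0, log a)."""
    pi0 = expit(t[0])
    a = np.exp(t[1])
    la = _log_norm_pdf(x, s2)
    lb = _log_norm_pdf(x, s2 + a)
    log_d = logsumexp(
        np.stack([la + _safe_log(np.array(pi0)), lb + _safe_log(np.array(1.0 - pi0))]),
        axis=0,
    )
    nll = -float(np.sum(log_d))
    # dB/da = B * ((x^2 / v^2 - 1 / v) / 2), v = s^2 + a
    v = s2 + a
    ratio_a = np.exp(la - log_d)   # A_j / D_j
    ratio_b = np.exp(lb - log_d)   # B_j / D_j
    d_pi0 = float(np.sum(ratio_a - ratio_b))
    d_a = float(np.sum((1.0 - pi0) * ratio_b * 0.5 * (x * x / v**2 - 1.0 / v)))
    grad = np.array([-d_pi0 * pi0 * (1.0 - pi0), -d_a * a])
    return nll, grad


def fit_point_normal(
    data: NormalMeansData, init: tuple[float, float] | None = None
) -> NormalMeansFit:
    """EBNM with the point-normal prior pi0 * delta_0 + (1 - pi0) * N(0, a).

    The marginal likelihood is non-convex in (pi0, a), so the optimization is
    run in (logit pi0, log a) coordinates from four deterministic starting
    values of pi0, each paired with a method-of-moments start for a, and the
    best optimum is kept. An optional warm start ``init=(pi0, a)`` (e.g. the
    fit from a previous iteration of an outer algorithm) is added as a fifth
    starting point, which guarantees the refit is at least as good as the
    supplied prior. Posterior moments at each coordinate mix a point mass at
    zero with the normal-slab posterior via Bayes' rule.
    """
    fin = data.finite
    if not np.any(fin):
        raise ValueError("no informative observations (all standard errors infinite)")
    x, s2 = data.x[fin], data.s[fin] ** 2
    s2_min = float(np.min(s2))

    a0 = max(float(np.mean(x * x - s2)), s2_min)
    a_lo = 1e-9 * s2_min
    a_hi = 4.0 * max(float(np.max(x * x)), s2_min)
    bounds = [(-15.0, 15.0), (np.log(a_lo), np.log(a_hi))]
    log_a0 = np.clip(np.log(a0), *bounds[1])

    starts = [
        np.array([np.log(p / (1.0 - p)), log_a0]) for p in (0.1, 0.5, 0.9, 0.99)
    ]
    if init is not None:
        pi0_w, a_w = init
        t_w = np.array(
            [
                np.clip(np.log(pi0_w / (1 - pi0_w)) if 0 < pi0_w < 1
                        else np.sign(pi0_w - 0.5) * 15.0, *bounds[0]),
                np.clip(np.log(max(a_w, a_lo)), *bounds[1]),
            ]
        )
        starts.append(t_w)

    best = None
    for t0 in starts:
        res = minimize(
            _pn_negloglik_grad, t0, args=(x, s2), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"point-normal optimizer failed; best iterate: {best}")

    pi0 = float(expit(best.x[0]))
    a = float(np.exp(best.x[1]))
    g = PriorSpec(family="point_normal", pi0=pi0, a=a)
    loglik = nm_marginal_loglik(g, data)

    m = data.x.size
    post_mean = np.zeros(m)
    post_mean2 = np.zeros(m)
    if not g.is_point_mass():  # a = 0 or pi0 = 1 collapses to delta_0
        xf = data.x[fin]
        la = _safe_log(np.array(pi0)) + _log_norm_pdf(xf, s2)
        lb = _safe_log(np.array(1.0 - pi0)) + _log_norm_pdf(xf, s2 + a)
        w_slab = np.exp(lb - np.logaddexp(la, lb))  # posterior slab weight
        mu = xf * a / (a + s2)
        var = a * s2 / (a + s2)
        post_mean[fin] = w_slab * mu
        post_mean2[fin] = w_slab * (mu**2 + var)
    _prior_moment_fill(g, data, post_mean, post_mean2)
    return NormalMeansFit(g, loglik, post_mean, post_mean2)


def default_smn_grid(data: NormalMeansData) -> np.ndarray:
    """Default grid of component standard deviations for the scale mixture.

    sigma_1 = 0, then a geometric ladder with ratio sqrt(2) spanning from
    s_min / 10 up to (at least) 2 * sqrt(max(x^2 - s^2, s_min^2)) — dense
    enough that the grid itself is not a tuning parameter.
    """
    fin = data.finite
    x, s = data.x[fin], data.s[fin]
    s_min = float(np.min(s))
    lo = s_min / 10.0
    hi = 2.0 * np.sqrt(max(float(np.max(x * x - s * s)), s_min**2))
    hi = max(hi, lo)
    n_steps = int(np.ceil(2.0 * np.log2(hi / lo))) if hi > lo else 0
    ladder = lo * np.sqrt(2.0) ** np.arange(n_steps + 1)
    return np.concatenate([[0.0], ladder])


def fit_scale_mix_normal(
    data: NormalMeansData,
    grid: np.ndarray | None = None,
    init_weights: np.ndarray | None = None,
) -> NormalMeansFit:
    """EBNM with a scale mixture of zero-centered normals on a fixed sd grid.

    With the grid fixed, the marginal log-likelihood is concave in the
    mixture weights; EM updates are monotone and run until the largest
    weight change falls below 1e-9 (cap 1000 iterations).
    ``init_weights`` warm-starts EM (monotonicity then guarantees the fit is
    at least as good as the supplied weights on this data).
    """
    fin = data.finite
    if not np.any(fin):
        raise ValueError("no informative observations (all standard errors infinite)")
    if grid is None:
        grid = default_smn_grid(data)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("scale mixture grid is empty")
    if grid[0] != 0.0:
        raise ValueError("scale mixture grid must include a sigma = 0 component")

    x, s2 = data.x[fin], data.s[fin] ** 2
    n_comp = grid.size
    # (m, M) matrix of component log-densities
    comp_ll = _log_norm_pdf(x[:, None], s2[:, None] + grid[None, :] ** 2)

    if init_weights is not None and np.asarray(init_weights).size == n_comp:
        pi = np.maximum(np.asarray(init_weights, dtype=float), 0.0)
        pi = pi / pi.sum()
    else:
        pi = np.full(n_comp, 1.0 / n_comp)

    loglik = -np.inf
    for _ in range(1000):
        lw = comp_ll + _safe_log(pi)[None, :]
        row_ll = logsumexp(lw, axis=1)
        new_loglik = float(np.sum(row_ll))
        resp = np.exp(lw - row_ll[:, None])
        pi = resp.mean(axis=0)
        # the log-likelihood *increment* is invariant to rescaling the data
        # (a rescale only shifts the log-likelihood by a constant), so an
        # absolute per-coordinate threshold keeps EM scale-equivariant
        if new_loglik - loglik < 1e-8 * x.size:
            break
        loglik = new_loglik

    g = PriorSpec(family="scale_mix_normal", grid=grid, weights=pi / pi.sum())
    loglik = nm_marginal_loglik(g, data)

    # posterior responsibilities and per-component normal posterior moments
    lw = comp_ll + _safe_log(g.weights)[None, :]
    resp = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    sig2 = grid**2
    mu = x[:, None] * sig2[None, :] / (sig2[None, :] + s2[:, None])
    var = sig2[None, :] * s2[:, None] / (sig2[None, :] + s2[:, None])

    m = data.x.size
    post_mean = np.zeros(m)
    post_mean2 = np.zeros(m)
    post_mean[fin] = np.sum(resp * mu, axis=1)
    post_mean2[fin] = np.sum(resp * (mu**2 + var), axis=1)
    _prior_moment_fill(g, data, post_mean, post_mean2)
    return NormalMeansFit(g, loglik, post_mean, post_mean2)


def solve_ebnm(
    data: NormalMeansData,
    family: str,
    grid: np.ndarray | None = None,
    warm_start: "PriorSpec | None" = None,
) -> NormalMeansFit:
    """Dispatch to the solver for ``family`` (see module docstring).

    ``warm_start`` may carry a previously fitted prior of the same family;
    solvers use it as an extra starting point so that iterative callers
    never regress below the supplied prior's likelihood.
    """
    if warm_start is not None and warm_start.family != family:
        warm_start = None
    if family == "point_mass_zero":
        return fit_point_mass(data)
    if family == "normal":
        return fit_normal(data)
    if family == "point_normal":
        init = (warm_start.pi0, warm_start.a) if warm_start else None
        return fit_point_normal(data, init=init)
    if family == "scale_mix_normal":
        if warm_start is not None and grid is None:
            return fit_scale_mix_normal(
                data, grid=warm_start.grid, init_weights=warm_start.weights
            )
        return fit_scale_mix_normal(data, grid=grid)
    raise ValueError(f"unknown prior family: {family!r}")
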