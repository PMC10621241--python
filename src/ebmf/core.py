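"""Rank-1 variational coordinate ascent for EBMF.

The variational objective F lower-bounds the marginal log-likelihood of the
factorization model Y = sum_k l_k f_k^T + E, E_ij ~ N(0, 1/tau_ij), under a
fully factorized variational family. Because that family factorizes over
every coordinate of every loading and factor, each coordinate-ascent step
needs only first and second moments:

* updating a loading (or factor) reduces to an empirical-Bayes normal-means
  problem on weighted-regression estimates and their standard errors;
* updating the precision tau needs only the expected squared residuals;
* F itself assembles from the expected Gaussian log-likelihood minus one
  KL(q || g) term per loading and per factor, each available from the EBNM
  solver's marginal log-likelihood.

Missing data is handled by setting tau_ij = 0 at unobserved cells, which
removes them from every sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ebmf.ebnm import NormalMeansData, NormalMeansFit, solve_ebnm

__all__ = [
    "ObservedMatrix",
    "PrecisionModel",
    "FactorMoments",
    "regression_stats",
    "update_side",
    "expected_residual2",
    "update_tau",
    "kl_term",
    "compute_objective",
    "TAU_CLAMP",
]

_LOG2PI = np.log(2.0 * np.pi)

#: Precision assigned to a perfectly fitted block (keeps F finite).
TAU_CLAMP = 1e8

TAU_STRUCTURES = ("constant", "by_column", "by_row", "by_entry_fixed")


@dataclass
class ObservedMatrix:
    """A data matrix with an observation mask (True = observed).

    Values at unobserved cells are arbitrary finite placeholders; they are
    multiplied by a zero precision everywhere and never influence results.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D matrix")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        # placeholder unobserved entries with 0 so they stay finite
        self.values = np.where(self.mask, self.values, 0.0)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed entries must be finite")

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ObservedMatrix":
        """Build from an array where NaN marks a missing cell."""
        values = np.asarray(values, dtype=float)
        mask = ~np.isnan(values)
        return cls(np.where(mask, values, 0.0), mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


@dataclass
class PrecisionModel:
    """Noise precision tau in expanded n x p view, zero at unobserved cells."""

    structure: str
    tau: np.ndarray

    def __post_init__(self) -> None:
        if self.structure not in TAU_STRUCTURES:
            raise ValueError(f"unknown precision structure: {self.structure!r}")
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(self.tau < 0):
            raise ValueError("precisions must be nonnegative")


@dataclass
class FactorMoments:
    """First and second posterior moments of one loading/factor pair."""

    l_mean: np.ndarray
    l_mean2: np.ndarray
    f_mean: np.ndarray
    f_mean2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("l_mean", "l_mean2", "f_mean", "f_mean2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.l_mean.shape != self.l_mean2.shape:
            raise ValueError("loading moment vectors must have equal length")
        if self.f_mean.shape != self.f_mean2.shape:
            raise ValueError("factor moment vectors must have equal length")
        if np.any(self.l_mean2 < self.l_mean**2 - 1e-12) or np.any(
            self.f_mean2 < self.f_mean**2 - 1e-12
        ):
            raise ValueError("second moments must dominate squared first moments")

    @classmethod
    def zeros(cls, n: int, p: int) -> "FactorMoments":
        return cls(np.zeros(n), np.zeros(n), np.zeros(p), np.zeros(p))

    @classmethod
    def from_vectors(cls, l: np.ndarray, f: np.ndarray) -> "FactorMoments":
        """Degenerate (point-mass) moments from plain vectors."""
        l = np.asarray(l, dtype=float)
        f = np.asarray(f, dtype=float)
        return cls(l, l**2, f, f**2)

    def is_zero(self, tol: float = 1e-12) -> bool:
        lmax = float(np.max(np.abs(self.l_mean))) if self.l_mean.size else 0.0
        fmax = float(np.max(np.abs(self.f_mean))) if self.f_mean.size else 0.0
        return lmax * fmax < tol


def regression_stats(
    Y: ObservedMatrix,
    tau: PrecisionModel,
    v: np.ndarray,
    w: np.ndarray,
    side: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-regression estimates and standard errors for one side.

    For ``side="loading"``, regressing each row of Y on the current factor
    moments (v = f_mean, w = f_mean2) gives

        est_i = sum_j tau_ij Y_ij v_j / sum_j tau_ij w_j,
        se_i  = (sum_j tau_ij w_j)^(-1/2),

    with sums running over observed cells only (tau is zero elsewhere).
    A zero denominator (no information) yields est 0 and se +inf.
    ``side="factor"`` swaps the roles of rows and columns.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("moment vectors v and w must have equal length")
    if side == "loading":
        expect = Y.shape[1]
        num = (tau.tau * Y.values) @ v
        denom = tau.tau @ w
    elif side == "factor":
        expect = Y.shape[0]
        num = (tau.tau * Y.values).T @ v
        denom = tau.tau.T @ w
    else:
        raise ValueError(f"side must be 'loading' or 'factor', got {side!r}")
    if v.size != expect:
        raise ValueError(f"moment vectors have length {v.size}, expected {expect}")

    informative = denom > 0
    safe = np.where(informative, denom, 1.0)
    est = np.where(informative, num / safe, 0.0)
    se = np.where(informative, safe**-0.5, np.inf)
    return est, se


def update_side(
    Y: ObservedMatrix,
    tau: PrecisionModel,
    other_mean: np.ndarray,
    other_mean2: np.ndarray,
    side: str,
    family: str,
    grid: np.ndarray | None = None,
    warm_start=None,
) -> NormalMeansFit:
    """One coordinate-ascent update of a loading or factor.

    Forms the weighted-regression statistics against the other side's
    moments and solves the resulting EBNM problem; the caller installs the
    returned posterior moments. With a warm start from the side's previous
    prior, each such update cannot decrease F.
    """
    est, se = regression_stats(Y, tau, other_mean, other_mean2, side)
    data = NormalMeansData(est, se)
    if not np.any(data.finite):
        # no information anywhere (e.g. the other side is identically zero):
        # the degenerate delta_0 fit returns prior moments and zero loglik
        from ebmf.ebnm import fit_point_mass

        return fit_point_mass(data)
    return solve_ebnm(data, family, grid=grid, warm_start=warm_start)


def expected_residual2(
    Y: ObservedMatrix, moments: list[FactorMoments]
) -> np.ndarray:
    """Expected squared residuals E_q[(Y_ij - sum_k l_ki f_kj)^2].

    Under the fully factorized variational family the factors' q's are
    independent, so the expectation expands to

        (Y - sum_k lbar_k fbar_k^T)^2
        - sum_k (lbar_k fbar_k^T)^2 + sum_k l2bar_k f2bar_k^T.

    Unobserved cells are set to zero (they never enter any sum).
    """
    n, p = Y.shape
    fitted = np.zeros((n, p))
    correction = np.zeros((n, p))
    for fm in moments:
        fitted += np.outer(fm.l_mean, fm.f_mean)
        correction += np.outer(fm.l_mean2, fm.f_mean2) - np.outer(
            fm.l_mean**2, fm.f_mean**2
        )
    r2 = (Y.values - fitted) ** 2 + correction
    return np.where(Y.mask, r2, 0.0)


def update_tau(
    R2: np.ndarray,
    mask: np.ndarray,
    structure: str,
    fixed: PrecisionModel | None = None,
    tau_clamp: float = TAU_CLAMP,
) -> PrecisionModel:
    """Maximum-likelihood precision given the expected squared residuals.

    Within each block of the chosen structure, tau is (number of observed
    cells) / (sum of expected squared residuals). A block with no observed
    cells gets tau 0; a perfectly fitted block (zero residual sum) is
    clamped at ``tau_clamp`` to keep the objective finite.
    """
    R2 = np.asarray(R2, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if np.any(R2[mask] < 0):
        raise ValueError("expected squared residuals must be nonnegative")
    if structure == "by_entry_fixed":
        if fixed is None:
            raise ValueError("by_entry_fixed requires the existing precision model")
        return fixed

    def block_tau(count, rss):
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(rss > 0, count / np.where(rss > 0, rss, 1.0), tau_clamp)
        # (near-)perfect fits are capped so the objective stays finite
        return np.where(count > 0, np.minimum(tau, tau_clamp), 0.0)

    if structure == "constant":
        tau_val = block_tau(mask.sum(), R2[mask].sum())
        tau = np.where(mask, tau_val, 0.0)
    elif structure == "by_column":
        col = block_tau(mask.sum(axis=0), np.where(mask, R2, 0.0).sum(axis=0))
        tau = np.where(mask, col[None, :], 0.0)
    elif structure == "by_row":
        row = block_tau(mask.sum(axis=1), np.where(mask, R2, 0.0).sum(axis=1))
        tau = np.where(mask, row[:, None], 0.0)
    else:
        raise ValueError(f"unknown precision structure: {structure!r}")
    return PrecisionModel(structure=structure, tau=tau)


def kl_term(fit: NormalMeansFit, data: NormalMeansData) -> float:
    """KL(q || g) for one fitted EBNM subproblem.

    Uses the identity F_NM = E_q[log p(x | theta)] - KL(q || g), which holds
    with F_NM equal to the marginal log-likelihood because the EBNM solver
    returns the exact posterior. The expected log-likelihood needs only the
    posterior moments. No-information coordinates contribute zero.
    """
    fin = data.finite
    x, s2 = data.x[fin], data.s[fin] ** 2
    tbar, t2bar = fit.post_mean[fin], fit.post_mean2[fin]
    # E_q (x - theta)^2 written as (x - tbar)^2 + Var_q(theta): both terms
    # nonnegative, avoiding catastrophic cancellation when s is tiny
    e_sq = (x - tbar) ** 2 + np.maximum(t2bar - tbar**2, 0.0)
    e_loglik = float(np.sum(-0.5 * (_LOG2PI + np.log(s2)) - e_sq / (2 * s2)))
    kl = e_loglik - fit.loglik
    if kl < -1e-8 * max(1.0, abs(fit.loglik)):
        raise RuntimeError(f"negative KL term ({kl}); inconsistent EBNM fit")
    return max(kl, 0.0)


def compute_objective(
    Y: ObservedMatrix,
    tau: PrecisionModel,
    moments: list[FactorMoments],
    kl_l: list[float],
    kl_f: list[float],
) -> float:
    """The variational lower bound F on the marginal log-likelihood.

    F = sum_obs [ 0.5 log(tau_ij / 2 pi) - 0.5 tau_ij E_q[R_ij^2] ]
        - sum_k KL(q_lk || g_lk) - sum_k KL(q_fk || g_fk).

    With K = 0 this is the Gaussian log-likelihood of Y under pure noise.
    """
    obs = Y.mask
    if np.any(tau.tau[obs] == 0):
        raise ValueError("zero precision at an observed cell; objective is -inf")
    R2 = expected_residual2(Y, moments)
    t = tau.tau[obs]
    gauss = float(np.sum(0.5 * np.log(t / (2.0 * np.pi)) - 0.5 * t * R2[obs]))
    return gauss - float(np.sum(kl_l)) - float(np.sum(kl_f))
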