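"""Synthetic data generators and evaluation metrics.

Two study designs are provided:

* ``sim_rank1`` — a 200 x 300 single-factor model with sparse loadings
  drawn from a spike-and-slab scale mixture and a dense standard-normal
  factor; three canonical (sparsity, noise) settings are
  (pi0, tau) = (0.9, 1), (0.3, 1/16), (0, 1/25).
* ``sim_bicluster`` — a 150 x 240 rank-3 model with disjoint blocks of
  samples loaded on one factor each and disjoint blocks of variables per
  factor, noise variance 4; a test of adapting to different sparsity
  levels across factors and loadings simultaneously.

Metrics: relative root mean squared error of a low-rank reconstruction
against the true signal matrix, RMSE on held-out cells, and orthogonal
cross-validation folds (row-groups x column-groups diagonal blocks, so a
fold never removes an entire row or column). A plain truncated-SVD
baseline is included for reference comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ebmf.core import ObservedMatrix

__all__ = [
    "SimTruth",
    "HoldoutMask",
    "sim_rank1",
    "sim_bicluster",
    "rrmse",
    "rmse_heldout",
    "ocv_folds",
    "svd_baseline",
]

#: slab component variances of the rank-1 loading mixture (equal weights)
RANK1_SLAB_VARIANCES = (0.25, 0.5, 1.0, 2.0, 4.0)

#: the three (pi0, tau) settings of the rank-1 study
RANK1_SETTINGS = ((0.9, 1.0), (0.3, 1.0 / 16.0), (0.0, 1.0 / 25.0))


@dataclass
class SimTruth:
    """A simulated matrix together with its generating signal."""

    Y: ObservedMatrix
    L_true: np.ndarray  # K x n
    F_true: np.ndarray  # K x p
    tau_true: float
    seed: int

    @property
    def signal(self) -> np.ndarray:
        """The noiseless low-rank matrix sum_k l_k f_k^T."""
        return self.L_true.T @ self.F_true


@dataclass
class HoldoutMask:
    """Disjoint boolean fold masks whose union is the observed set."""

    folds: list[np.ndarray]


def sim_rank1(
    pi0: float, tau: float, seed: int, n: int = 200, p: int = 300
) -> SimTruth:
    """Single-factor data with sparse loadings and a dense factor.

    l_i ~ pi0 * delta_0 + (1 - pi0) * (1/5) sum_m N(0, sigma_m^2) with
    sigma^2 in {0.25, 0.5, 1, 2, 4}; f_j ~ N(0, 1); noise N(0, 1/tau).
    Draw order (loadings, factor, noise) is fixed for reproducibility.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    if tau <= 0:
        raise ValueError("noise precision tau must be positive")
    rng = np.random.default_rng(seed)
    nonzero = rng.random(n) >= pi0
    comps = rng.integers(0, len(RANK1_SLAB_VARIANCES), size=n)
    sds = np.sqrt(np.asarray(RANK1_SLAB_VARIANCES))[comps]
    l = np.where(nonzero, rng.standard_normal(n) * sds, 0.0)
    f = rng.standard_normal(p)
    E = rng.standard_normal((n, p)) / np.sqrt(tau)
    Y = np.outer(l, f) + E
    return SimTruth(
        Y=ObservedMatrix(Y, None),
        L_true=l[None, :],
        F_true=f[None, :],
        tau_true=tau,
        seed=seed,
    )


def sim_bicluster(seed: int) -> SimTruth:
    """Rank-3 sparse bi-cluster data (150 x 240, noise variance 4).

    Disjoint sample blocks load one factor each — rows 1-10 on factor 1
    (sd 2), rows 11-60 on factor 2 (sd 1), rows 61-150 on factor 3
    (sd 1/2) — and each factor is supported on its own block of 80
    variables with sds 1/2, 1, 2 respectively.
    """
    n, p, tau = 150, 240, 0.25
    rng = np.random.default_rng(seed)
    L = np.zeros((3, n))
    F = np.zeros((3, p))
    row_blocks = [(0, 10, 2.0), (10, 60, 1.0), (60, 150, 0.5)]
    col_blocks = [(0, 80, 0.5), (80, 160, 1.0), (160, 240, 2.0)]
    for k, (lo, hi, sd) in enumerate(row_blocks):
        L[k, lo:hi] = rng.standard_normal(hi - lo) * sd
    for k, (lo, hi, sd) in enumerate(col_blocks):
        F[k, lo:hi] = rng.standard_normal(hi - lo) * sd
    E = rng.standard_normal((n, p)) / np.sqrt(tau)
    Y = L.T @ F + E
    return SimTruth(
        Y=ObservedMatrix(Y, None), L_true=L, F_true=F, tau_true=tau, seed=seed
    )


def rrmse(B_hat: np.ndarray, B: np.ndarray) -> float:
    """Relative RMSE: sqrt(sum (B_hat - B)^2 / sum B^2)."""
    B_hat = np.asarray(B_hat, dtype=float)
    B = np.asarray(B, dtype=float)
    if B_hat.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    denom = float(np.sum(B * B))
    if denom == 0:
        raise ValueError("reference matrix is identically zero")
    return float(np.sqrt(np.sum((B_hat - B) ** 2) / denom))


def rmse_heldout(Y_hat: np.ndarray, Y: np.ndarray, mask: np.ndarray) -> float:
    """Root mean squared error over the cells selected by ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("held-out mask selects no cells")
    diff = np.asarray(Y, dtype=float)[mask] - np.asarray(Y_hat, dtype=float)[mask]
    return float(np.sqrt(np.mean(diff * diff)))


def ocv_folds(Y: ObservedMatrix, k: int, seed: int) -> HoldoutMask:
    """Orthogonal cross-validation folds over the observed cells.

    Rows and columns are randomly partitioned into k groups each; fold t
    holds out the observed cells whose (row group + column group) mod k
    equals t. The folds are disjoint, cover every observed cell exactly
    once, and each fold leaves observations in every row and column group.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    n, p = Y.shape
    if k > min(n, p):
        raise ValueError("more folds than rows or columns")
    rng = np.random.default_rng(seed)
    row_group = rng.permutation(np.arange(n) % k)
    col_group = rng.permutation(np.arange(p) % k)
    combo = (row_group[:, None] + col_group[None, :]) % k
    folds = [(combo == t) & Y.mask for t in range(k)]
    return HoldoutMask(folds=folds)


def svd_baseline(Y: ObservedMatrix, K: int) -> np.ndarray:
    """Best rank-K approximation by truncated SVD (fully observed only)."""
    if not np.all(Y.mask):
        raise ValueError("SVD baseline requires a fully observed matrix")
    U, s, Vt = np.linalg.svd(Y.values, full_matrices=False)
    K = min(K, s.size)
    return (U[:, :K] * s[:K]) @ Vt[:K]
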