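"""Variational-core tests: regression statistics, expected residuals,
precision updates, KL terms, and objective monotonicity."""

import numpy as np
import pytest

from ebmf import (
    FactorMoments,
    NormalMeansData,
    ObservedMatrix,
    PrecisionModel,
    compute_objective,
    expected_residual2,
    fit_normal,
    fit_point_mass,
    fit_point_normal,
    kl_term,
    regression_stats,
    update_side,
    update_tau,
)
from ebmf.core import TAU_CLAMP

from conftest import masked_rank1


def full_tau(Y, value=1.0):
    return PrecisionModel("by_entry_fixed", np.where(Y.mask, value, 0.0))


class TestRegressionStats:
    def test_hand_arithmetic(self):
        Y = ObservedMatrix(np.array([[2.0, 4.0], [1.0, 2.0]]), None)
        est, se = regression_stats(
            Y, full_tau(Y), np.array([1.0, 2.0]), np.array([1.0, 4.0]), "loading"
        )
        np.testing.assert_allclose(est, [2.0, 1.0])
        np.testing.assert_allclose(se, [5**-0.5, 5**-0.5])

    def test_exact_rank1_identity(self, rng):
        l = rng.standard_normal(8)
        f = rng.standard_normal(6)
        Y = ObservedMatrix(np.outer(l, f), None)
        est, _ = regression_stats(Y, full_tau(Y), f, f * f, "loading")
        np.testing.assert_allclose(est, l, atol=1e-12)
        est, _ = regression_stats(Y, full_tau(Y), l, l * l, "factor")
        np.testing.assert_allclose(est, f, atol=1e-12)

    def test_unobserved_row_gets_no_information(self, rng):
        vals = rng.standard_normal((4, 3))
        mask = np.ones((4, 3), dtype=bool)
        mask[2] = False
        Y = ObservedMatrix(vals, mask)
        v = rng.standard_normal(3)
        est, se = regression_stats(Y, full_tau(Y), v, v * v, "loading")
        assert est[2] == 0.0 and np.isinf(se[2])
        assert np.all(np.isfinite(se[[0, 1, 3]]))

    def test_masked_sums_match_explicit_loops(self):
        """Setting tau=0 at masked cells equals dropping those cells."""
        Y, _ = masked_rank1(77, n=10, p=8)
        tau = full_tau(Y, 0.7)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(8)
        w = v * v + rng.random(8)
        est, se = regression_stats(Y, tau, v, w, "loading")
        for i in range(10):
            obs = Y.mask[i]
            denom = 0.7 * np.sum(w[obs])
            if denom == 0:
                assert est[i] == 0 and np.isinf(se[i])
            else:
                num = 0.7 * np.sum(Y.values[i, obs] * v[obs])
                assert est[i] == pytest.approx(num / denom, rel=1e-12)
                assert se[i] == pytest.approx(denom**-0.5, rel=1e-12)

    def test_negative_tau_rejected(self):
        Y = ObservedMatrix(np.ones((2, 2)), None)
        with pytest.raises(ValueError):
            PrecisionModel("constant", -np.ones((2, 2)))
        with pytest.raises(ValueError):
            regression_stats(Y, full_tau(Y), np.ones(3), np.ones(3), "loading")


class TestExpectedResidual2:
    def test_direct_substitution(self):
        Y = ObservedMatrix(np.array([[1.0]]), None)
        fm = FactorMoments(
            np.array([1.0]), np.array([2.0]), np.array([1.0]), np.array([3.0])
        )
        # (1 - 1)^2 - 1*1 + 2*3 = 5
        assert expected_residual2(Y, [fm])[0, 0] == pytest.approx(5.0)

    def test_degenerate_moments_collapse_to_squared_residuals(self, rng):
        vals = rng.standard_normal((5, 5))
        Y = ObservedMatrix(vals, None)
        moments = [
            FactorMoments.from_vectors(rng.standard_normal(5), rng.standard_normal(5))
            for _ in range(3)
        ]
        fitted = sum(np.outer(fm.l_mean, fm.f_mean) for fm in moments)
        np.testing.assert_array_equal(
            expected_residual2(Y, moments), (vals - fitted) ** 2
        )

    def test_zero_moments_give_squared_data(self, rng):
        Y, _ = masked_rank1(5, n=6, p=4)
        r2 = expected_residual2(Y, [FactorMoments.zeros(6, 4)])
        np.testing.assert_array_equal(r2, np.where(Y.mask, Y.values**2, 0.0))


class TestUpdateTau:
    def test_constant_reciprocal_mean(self):
        mask = np.ones((3, 3), dtype=bool)
        tau = update_tau(np.full((3, 3), 4.0), mask, "constant")
        np.testing.assert_allclose(tau.tau, 0.25)

    def test_missing_cell_hand_arithmetic(self):
        mask = np.array([[True, True], [True, False]])
        R2 = np.array([[1.0, 2.0], [3.0, 99.0]])
        tau = update_tau(R2, mask, "constant")
        assert tau.tau[0, 0] == pytest.approx(0.5)
        assert tau.tau[1, 1] == 0.0

    def test_perfect_fit_clamped(self):
        mask = np.ones((2, 2), dtype=bool)
        R2 = np.array([[0.0, 1.0], [0.0, 1.0]])
        tau = update_tau(R2, mask, "by_column")
        assert tau.tau[0, 0] == TAU_CLAMP
        assert tau.tau[0, 1] == pytest.approx(1.0)

    def test_by_row_and_by_column(self):
        mask = np.ones((2, 3), dtype=bool)
        R2 = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        by_row = update_tau(R2, mask, "by_row")
        np.testing.assert_allclose(by_row.tau[0], 1.0)
        np.testing.assert_allclose(by_row.tau[1], 0.5)
        by_col = update_tau(R2, mask, "by_column")
        np.testing.assert_allclose(by_col.tau[:, 0], 2 / 3)

    def test_negative_residuals_rejected(self):
        with pytest.raises(ValueError):
            update_tau(-np.ones((2, 2)), np.ones((2, 2), dtype=bool), "constant")


class TestKLTerm:
    def test_point_mass_gives_zero(self, rng):
        d = NormalMeansData(rng.standard_normal(10), np.ones(10))
        assert kl_term(fit_point_mass(d), d) == 0.0

    def test_nonnegative_and_finite(self, rng):
        x = rng.standard_normal(30) * 2
        d = NormalMeansData(x, np.ones(30))
        for fit in (fit_normal(d), fit_point_normal(d)):
            kl = kl_term(fit, d)
            assert np.isfinite(kl) and kl >= 0

    def test_matches_closed_form_point_normal_kl(self):
        """KL(q || g) computed from the EBNM identity equals the directly
        assembled mixture KL (atom + Gaussian cross-entropy terms)."""
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        theta = np.where(rng.random(60) < 0.6, 0.0, rng.standard_normal(60) * 1.5)
        x = theta + rng.standard_normal(60) * 0.8
        d = NormalMeansData(x, np.full(60, 0.8))
        fit = fit_point_normal(d)
        pi0, a = fit.g_hat.pi0, fit.g_hat.a
        direct = 0.0
        for xj, sj in zip(d.x, d.s):
            f0 = pi0 * norm.pdf(xj, 0, sj)
            f1 = (1 - pi0) * norm.pdf(xj, 0, np.sqrt(sj**2 + a))
            w0 = f0 / (f0 + f1)
            mu = xj * a / (a + sj**2)
            v = a * sj**2 / (a + sj**2)
            if w0 > 0:
                direct += w0 * np.log(w0 / pi0)
            if w0 < 1:
                direct += (1 - w0) * (
                    np.log((1 - w0) / (1 - pi0))
                    + 0.5 * np.log(a / v)
                    + (v + mu**2) / (2 * a)
                    - 0.5
                )
        assert kl_term(fit, d) == pytest.approx(direct, abs=1e-6)


class TestObjective:
    def test_rank0_single_cell(self):
        Y = ObservedMatrix(np.array([[0.0]]), None)
        tau = PrecisionModel("constant", np.ones((1, 1)))
        F = compute_objective(Y, tau, [], [], [])
        assert F == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_rank0_profile_loglik_identity(self, rng):
        """With MLE tau, F equals -|O|/2 (log(2 pi mean R2) + 1)."""
        Y, _ = masked_rank1(3, n=12, p=9)
        R2 = np.where(Y.mask, Y.values**2, 0.0)
        tau = update_tau(R2, Y.mask, "constant")
        F = compute_objective(Y, tau, [], [], [])
        n_obs = Y.n_observed
        closed = -n_obs / 2 * (np.log(2 * np.pi * R2[Y.mask].mean()) + 1)
        assert F == pytest.approx(closed, rel=1e-12)

    def test_zero_tau_on_observed_cell_rejected(self):
        Y = ObservedMatrix(np.ones((2, 2)), None)
        tau = PrecisionModel("by_entry_fixed", np.zeros((2, 2)))
        with pytest.raises(ValueError, match="zero precision"):
            compute_objective(Y, tau, [], [], [])


class TestCoordinateAscentMonotonicity:
    """The module's master correctness property: F never decreases along
    tau / loading / factor update sequences."""

    @pytest.mark.parametrize("family", ["point_normal", "scale_mix_normal"])
    def test_updates_never_decrease_objective(self, family):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Y, _ = masked_rank1(seed, n=15, p=12, frac_missing=0.2)
            fm = FactorMoments.from_vectors(
                rng.standard_normal(15), rng.standard_normal(12)
            )
            R2 = expected_residual2(Y, [fm])
            tau = update_tau(R2, Y.mask, "constant")
            kl_l = kl_f = 0.0
            # the arbitrary starting moments are not a valid posterior state;
            # F is comparable only from the first full update cycle onward
            prev = -np.inf
            g_l = g_f = None
            for _ in range(5):
                est, se = regression_stats(Y, tau, fm.f_mean, fm.f_mean2, "loading")
                d = NormalMeansData(est, se)
                nm = update_side(
                    Y, tau, fm.f_mean, fm.f_mean2, "loading", family, warm_start=g_l
                )
                fm.l_mean, fm.l_mean2 = nm.post_mean, nm.post_mean2
                kl_l, g_l = kl_term(nm, d), nm.g_hat
                est, se = regression_stats(Y, tau, fm.l_mean, fm.l_mean2, "factor")
                d = NormalMeansData(est, se)
                nm = update_side(
                    Y, tau, fm.l_mean, fm.l_mean2, "factor", family, warm_start=g_f
                )
                fm.f_mean, fm.f_mean2 = nm.post_mean, nm.post_mean2
                kl_f, g_f = kl_term(nm, d), nm.g_hat
                tau = update_tau(expected_residual2(Y, [fm]), Y.mask, "constant")
                F = compute_objective(Y, tau, [fm], [kl_l], [kl_f])
                assert F >= prev - 1e-8 * abs(prev)
                prev = F

    def test_degenerate_other_side_returns_prior_moments(self):
        Y = ObservedMatrix(np.ones((3, 3)), None)
        tau = PrecisionModel("by_entry_fixed", np.ones((3, 3)))
        nm = update_side(Y, tau, np.zeros(3), np.zeros(3), "loading", "point_normal")
        np.testing.assert_array_equal(nm.post_mean, 0.0)
        np.testing.assert_array_equal(nm.post_mean2, 0.0)

    def test_weighted_least_squares_equivalence(self, rng):
        """With degenerate factor moments and a normal prior of growing
        variance, the loading update approaches the plain weighted
        regression estimate (ridge-free limit)."""
        l = rng.standard_normal(10) * 3
        f = rng.standard_normal(7)
        Y = ObservedMatrix(
            np.outer(l, f) + 0.01 * rng.standard_normal((10, 7)), None
        )
        tau = full_tau(Y, 4.0)
        est, se = regression_stats(Y, tau, f, f * f, "loading")
        # explicit weighted regression per row
        for i in range(10):
            num = np.sum(4.0 * Y.values[i] * f)
            den = np.sum(4.0 * f * f)
            assert est[i] == pytest.approx(num / den, rel=1e-12)
            assert se[i] == pytest.approx(den**-0.5, rel=1e-12)
        nm = update_side(Y, tau, f, f * f, "loading", "normal")
        shrink = nm.g_hat.a / (nm.g_hat.a + se**2)
        np.testing.assert_allclose(nm.post_mean, est * shrink, atol=1e-10)
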