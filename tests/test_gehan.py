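import numpy as np
import pytest

from caft import (
    CensoredTaxon,
    NotEstimableError,
    contrast_complement,
    estimate_intercept_km,
    fit_restricted,
    fit_unrestricted,
    gehan_objective,
    gehan_score,
    rank_matrix,
)
from conftest import random_censored_instance


def brute_score(beta, tau, delta, X):
    """Direct double sum over ordered pairs with the tie-splitting indicator."""
    beta = np.atleast_1d(beta)
    e = tau - X @ beta
    n, k = X.shape
    s = np.zeros(k)
    for i in range(n):
        for ip in range(n):
            ind = 0.5 * (e[i] < e[ip]) + 0.5 * (e[i] <= e[ip])
            s += delta[i] * ind * (X[i] - X[ip])
    return s


def brute_objective(beta, tau, delta, X):
    beta = np.atleast_1d(beta)
    e = tau - X @ beta
    return sum(
        delta[i] * max(0.0, e[ip] - e[i])
        for i in range(len(e))
        for ip in range(len(e))
    )


class TestRankMatrix:
    def test_two_point_instance(self):
        R = rank_matrix(np.array([0.0, 1.0]), np.array([1, 1]))
        np.testing.assert_allclose(R, [[0.5, 1.0], [0.0, 0.5]])
        assert np.allclose(R.sum(axis=1), [1.5, 0.5])
        assert np.allclose(R.sum(axis=0), [0.5, 1.5])

    def test_all_ties_give_half(self):
        R = rank_matrix(np.zeros(4), np.ones(4))
        np.testing.assert_allclose(R, 0.5)

    def test_all_censored_gives_zero(self):
        R = rank_matrix(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        np.testing.assert_allclose(R, 0.0)


class TestScoreAndObjective:
    def test_two_point_score(self, micro_instance):
        taxon, X = micro_instance
        np.testing.assert_allclose(gehan_score(np.zeros(1), taxon, X), [-1.0])
        assert gehan_objective(np.zeros(1), taxon, X) == 1.0

    def test_tied_residuals_zero_score_zero_objective(self):
        taxon = CensoredTaxon(tau=np.zeros(3), delta=np.ones(3))
        X = np.array([[-1.0], [0.0], [1.0]])
        np.testing.assert_allclose(gehan_score(np.zeros(1), taxon, X), [0.0])
        assert gehan_objective(np.zeros(1), taxon, X) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, rng, k):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            taxon, X = random_censored_instance(rng, n, k)
            beta = rng.normal(size=k)
            np.testing.assert_allclose(
                gehan_score(beta, taxon, X),
                brute_score(beta, taxon.tau, taxon.delta, X),
                atol=1e-10,
            )
            np.testing.assert_allclose(
                gehan_objective(beta, taxon, X),
                brute_objective(beta, taxon.tau, taxon.delta, X),
                atol=1e-10,
            )

    def test_objective_slope_equals_score_between_kinks(self, rng):
        # d(e_i' - e_i)/dbeta = X_i - X_i', which is the score's covariate
        # difference, so the smooth part of G has slope +S; the minimizer
        # is where S crosses zero either way
        taxon, X = random_censored_instance(rng, 8, 1)
        beta = np.array([0.12345])  # generic point, almost surely not a kink
        h = 1e-7
        slope = (
            gehan_objective(beta + h, taxon, X) - gehan_objective(beta - h, taxon, X)
        ) / (2 * h)
        np.testing.assert_allclose(slope, gehan_score(beta, taxon, X)[0], atol=1e-5)

    def test_convexity(self, rng):
        taxon, X = random_censored_instance(rng, 10, 2)
        for _ in range(20):
            b1, b2 = rng.normal(size=2), rng.normal(size=2)
            t = rng.uniform()
            lhs = gehan_objective(t * b1 + (1 - t) * b2, taxon, X)
            rhs = t * gehan_objective(b1, taxon, X) + (1 - t) * gehan_objective(b2, taxon, X)
            assert lhs <= rhs + 1e-10

    def test_diagonal_cancels_in_score(self, rng):
        taxon, X = random_censored_instance(rng, 7, 2)
        R = rank_matrix(taxon.tau, taxon.delta)
        a_full = R.sum(axis=1) - R.sum(axis=0)
        R0 = R.copy()
        np.fill_diagonal(R0, 0.0)
        a_zeroed = R0.sum(axis=1) - R0.sum(axis=0)
        np.testing.assert_allclose(a_full, a_zeroed)

    def test_score_invariant_to_constant_column_shift(self, rng):
        taxon, X = random_censored_instance(rng, 9, 2)
        beta = rng.normal(size=2)
        s1 = gehan_score(beta, taxon, X)
        s2 = gehan_score(beta, taxon, X + np.array([3.0, -7.0]))
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestUnrestrictedFit:
    def test_matches_grid_search_no_censoring(self, rng):
        # binary covariate, no censoring: the classical generalized
        # Wilcoxon shift estimate, located here by exhaustive grid search
        n = 20
        x = np.repeat([0.0, 1.0], n // 2)
        X = (x - x.mean())[:, None]
        tau = 0.8 * X[:, 0] + rng.normal(size=n)
        taxon = CensoredTaxon(tau=tau, delta=np.ones(n))
        fit = fit_unrestricted(taxon, X)
        grid = np.linspace(-3, 3, 20001)
        vals = [gehan_objective(np.array([b]), taxon, X) for b in grid]
        best = grid[int(np.argmin(vals))]
        # the exact minimizer may sit anywhere on a flat optimal interval;
        # the objective value is the sharp check
        assert abs(fit.beta_hat[0] - best) < 0.05
        assert fit.objective_value <= min(vals) + 1e-9

    def test_parameter_recovery(self):
        # data generated from the censored log-linear model
        rng = np.random.default_rng(7)
        n, beta_true = 500, np.array([1.0, -0.5])
        ests = []
        for _ in range(8):
            X = rng.normal(size=(n, 2))
            X -= X.mean(axis=0)
            tau = X @ beta_true + rng.logistic(size=n)
            cut = np.quantile(tau, 0.8)  # ~20% censoring
            delta = (tau <= cut).astype(int)
            taxon = CensoredTaxon(tau=np.minimum(tau, cut), delta=delta)
            ests.append(fit_unrestricted(taxon, X).beta_hat)
        ests = np.asarray(ests)
        err = ests.mean(axis=0) - beta_true
        mc_sd = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(err) < 3 * mc_sd + 0.05)

    def test_location_shift_invariance(self, rng):
        taxon, X = random_censored_instance(rng, 40, 2)
        fit1 = fit_unrestricted(taxon, X)
        shifted = CensoredTaxon(tau=taxon.tau + 4.2, delta=taxon.delta)
        fit2 = fit_unrestricted(shifted, X)
        np.testing.assert_allclose(fit1.beta_hat, fit2.beta_hat, atol=1e-8)

    def test_all_censored_not_estimable(self):
        taxon = CensoredTaxon(tau=np.array([1.0, 2.0]), delta=np.zeros(2))
        with pytest.raises(NotEstimableError):
            fit_unrestricted(taxon, np.array([[-0.5], [0.5]]))

    def test_bias_offset_in_design_span_shifts_all_taxa_equally(self, rng):
        # a per-sample offset lying in the covariate span moves every
        # taxon's estimate by the same amount, exactly, without censoring
        n = 30
        X = rng.normal(size=(n, 2))
        X -= X.mean(axis=0)
        c = np.array([0.7, -1.3])
        alpha = X @ c
        shifts = []
        for _ in range(3):
            tau = X @ rng.normal(size=2) + rng.normal(size=n)
            taxon = CensoredTaxon(tau=tau, delta=np.ones(n))
            biased = CensoredTaxon(tau=tau + alpha, delta=np.ones(n))
            shifts.append(fit_unrestricted(biased, X).beta_hat - fit_unrestricted(taxon, X).beta_hat)
        for s in shifts:
            np.testing.assert_allclose(s, c, atol=1e-6)

    def test_two_sample_score_is_gehan_wilcoxon_statistic(self, rng):
        # with no censoring and a binary covariate, S at beta=0 reduces to
        # the two-sample pair-count statistic
        n = 12
        grp = np.repeat([0.0, 1.0], n // 2)
        X = (grp - grp.mean())[:, None]
        tau = rng.normal(size=n)
        taxon = CensoredTaxon(tau=tau, delta=np.ones(n))
        s = gehan_score(np.zeros(1), taxon, X)[0]
        # brute-force pair count: each (group0, group1) pair contributes
        # -sign(tau1 - tau0) through the unit covariate difference
        count = 0.0
        for i in np.flatnonzero(grp == 0):
            for ip in np.flatnonzero(grp == 1):
                count += np.sign(tau[ip] - tau[i])
        np.testing.assert_allclose(s, -count, atol=1e-9)


class TestRestrictedFit:
    def test_fully_specified_null_returns_b(self, micro_instance):
        taxon, X = micro_instance
        con = contrast_complement(np.array([[1.0]]), b=[0.37])
        fit = fit_restricted(taxon, X, con)
        np.testing.assert_allclose(fit.beta_hat, [0.37])

    def test_nuisance_recovery_under_restriction(self):
        rng = np.random.default_rng(11)
        n = 500
        X = rng.normal(size=(n, 2))
        X -= X.mean(axis=0)
        tau = X @ np.array([0.0, 1.0]) + rng.logistic(size=n)
        cut = np.quantile(tau, 0.85)
        taxon = CensoredTaxon(tau=np.minimum(tau, cut), delta=(tau <= cut).astype(int))
        con = contrast_complement(np.array([[1.0, 0.0]]), b=[0.0])
        fit = fit_restricted(taxon, X, con)
        assert fit.beta_hat[0] == 0.0
        assert abs(fit.beta_hat[1] - 1.0) < 0.15

    def test_equality_constraint_holds_exactly(self, rng):
        taxon, X = random_censored_instance(rng, 30, 3)
        con = contrast_complement(np.array([[1.0, -1.0, 0.0]]), b=[0.0])
        fit = fit_restricted(taxon, X, con)
        assert abs(fit.beta_hat[0] - fit.beta_hat[1]) < 1e-10


class TestKaplanMeierIntercept:
    def test_uncensored_median(self):
        taxon = CensoredTaxon(tau=np.array([1.0, 2.0, 3.0]), delta=np.ones(3))
        X = np.array([[-1.0], [0.0], [1.0]])
        assert estimate_intercept_km(taxon, X, np.zeros(1)) == 2.0

    def test_single_uncensored_value(self):
        # single point: the survival curve drops to 0 at that value
        taxon = CensoredTaxon(tau=np.array([5.0]), delta=np.ones(1))
        assert estimate_intercept_km(taxon, np.zeros((1, 1)), np.zeros(1)) == 5.0

    def test_textbook_product_limit_median(self):
        # times 1, 2+, 3, 4+, 5, 6 (+' = censored):
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(5)=0.625*1/2=0.3125 -> median 5
        taxon = CensoredTaxon(
            tau=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            delta=np.array([1, 0, 1, 0, 1, 1]),
        )
        X = np.zeros((6, 1))
        assert estimate_intercept_km(taxon, X, np.zeros(1)) == 5.0

    def test_heavy_censoring_returns_nan(self):
        taxon = CensoredTaxon(
            tau=np.array([1.0, 2.0, 3.0, 4.0]), delta=np.array([1, 0, 0, 0])
        )
        X = np.zeros((4, 1))
        assert np.isnan(estimate_intercept_km(taxon, X, np.zeros(1)))
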