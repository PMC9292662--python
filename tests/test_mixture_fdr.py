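"""Gamma-Poisson mixture likelihoods, constrained MLE and local FDR."""

import math

import numpy as np
import pytest
from scipy import stats

from ddimix.mixture_fdr import (
    MixtureParams,
    adjusted_fdr,
    component_moments,
    conditional_loglik,
    fit_conditional,
    full_loglik,
    negbin_logpmf,
    negbin_pmf,
)

PAPER_LIKE = MixtureParams(alpha2=2.19, alpha3=0.22, beta3=0.04, rho=0.08)


def scalar_negbin_pmf(k, alpha, beta, e):
    """Direct closed-form evaluation, independent of the vectorized log-space path."""
    return (
        math.gamma(k + alpha) * e**k * beta**alpha
        / (math.gamma(alpha) * math.factorial(k) * (e + beta) ** (k + alpha))
    )


class TestNegbinPmf:
    def test_closed_form_at_zero(self):
        for alpha, beta, e in [(2.0, 2.0, 3.0), (0.3, 0.1, 7.0), (5.0, 1.0, 0.5)]:
            assert negbin_pmf(0, alpha, beta, e) == pytest.approx(
                (beta / (e + beta)) ** alpha, rel=1e-12
            )

    def test_zero_exposure_is_point_mass(self):
        assert negbin_pmf(0, 2.0, 2.0, 0.0) == 1.0
        assert negbin_pmf(3, 2.0, 2.0, 0.0) == 0.0

    @pytest.mark.parametrize("alpha,beta,e", [(2, 2, 3), (0.22, 0.04, 5.0), (2.19, 2.19, 10.0)])
    def test_normalizes_over_support(self, alpha, beta, e):
        k = np.arange(0, 4000)
        total = negbin_pmf(k, alpha, beta, e).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_scalar_closed_form(self):
        for k in range(0, 20, 3):
            assert negbin_pmf(k, 1.7, 0.6, 4.2) == pytest.approx(
                scalar_negbin_pmf(k, 1.7, 0.6, 4.2), rel=1e-10
            )

    def test_matches_scipy_nbinom(self):
        # N ~ NB(r = alpha, p = beta / (e + beta)) is the same distribution
        alpha, beta, e = 2.0, 2.0, 3.0
        k = np.arange(0, 50)
        np.testing.assert_allclose(
            negbin_pmf(k, alpha, beta, e),
            stats.nbinom.pmf(k, alpha, beta / (e + beta)),
            rtol=1e-10,
        )

    def test_matches_monte_carlo_gamma_poisson_mixture(self, rng):
        alpha, beta, e = 2.0, 2.0, 3.0
        n_draws = 1_000_000
        lam = rng.gamma(alpha, 1.0 / beta, n_draws)
        draws = rng.poisson(lam * e)
        kmax = 30
        freq = np.bincount(draws, minlength=kmax + 1)[: kmax + 1] / n_draws
        pmf = negbin_pmf(np.arange(kmax + 1), alpha, beta, e)
        mc_se = np.sqrt(pmf * (1 - pmf) / n_draws)
        assert np.all(np.abs(freq - pmf) < 3 * np.maximum(mc_se, 1e-9) + 1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            negbin_logpmf(1, -1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            negbin_logpmf(1.5, 1.0, 2.0, 3.0)


class TestConditionalLoglik:
    def test_matches_scalar_loop_oracle(self):
        params = MixtureParams(alpha2=1.8, alpha3=0.9, beta3=0.3, rho=0.2)
        n = np.array([1, 4, 2, 10, 7])
        e = np.array([0.5, 3.0, 1.2, 6.0, 2.4])
        total = 0.0
        for k, ei in zip(n, e):
            f2 = scalar_negbin_pmf(int(k), params.alpha2, params.alpha2, ei)
            f3 = scalar_negbin_pmf(int(k), params.alpha3, params.beta3, ei)
            p2 = 1 - (params.alpha2 / (ei + params.alpha2)) ** params.alpha2
            p3 = 1 - (params.beta3 / (ei + params.beta3)) ** params.alpha3
            total += math.log((f2 + params.rho * f3) / (p2 + params.rho * p3))
        assert conditional_loglik(params, n, e) == pytest.approx(total, abs=1e-12)

    def test_small_rho_approaches_truncated_single_component(self):
        n = np.array([3])
        e = np.array([2.0])
        params = MixtureParams(alpha2=2.0, alpha3=1.0, beta3=0.2, rho=1e-12)
        f2 = scalar_negbin_pmf(3, 2.0, 2.0, 2.0)
        p2 = 1 - (2.0 / 4.0) ** 2.0
        assert conditional_loglik(params, n, e) == pytest.approx(
            math.log(f2 / p2), abs=1e-9
        )

    def test_conditional_pmf_normalizes(self):
        # truncated mixture pmf over k >= 1 must sum to 1; the heavy-tailed
        # signal component (shape 0.22) still carries ~1e-6 mass past k=1000,
        # so the support is truncated at k=5000 where the tail is ~e-40
        e = 5.0
        k = np.arange(1, 5001)
        ll = np.array([
            conditional_loglik(PAPER_LIKE, np.array([ki]), np.array([e])) for ki in k
        ])
        assert np.exp(ll).sum() == pytest.approx(1.0, abs=1e-8)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            conditional_loglik(PAPER_LIKE, np.array([0, 2]), np.array([1.0, 1.0]))


def simulate_mixture_counts(rng, n_comb, params, e_low=1.0, e_high=20.0):
    """Draw (N, E) from the two-gamma mixture (no zero component)."""
    e = rng.uniform(e_low, e_high, n_comb)
    from_signal = rng.random(n_comb) < params.rho / (1 + params.rho)
    lam = np.where(
        from_signal,
        rng.gamma(params.alpha3, 1.0 / params.beta3, n_comb),
        rng.gamma(params.alpha2, 1.0 / params.alpha2, n_comb),
    )
    n = rng.poisson(lam * e)
    return n, e


class TestFitConditional:
    TRUTH = MixtureParams(alpha2=2.0, alpha3=1.0, beta3=0.2, rho=0.1)

    def test_single_seed_fit_is_a_genuine_mle(self, rng):
        # one-seed sanity: the optimiser must beat the generating parameters'
        # likelihood (it is an MLE) and pin down the well-identified null
        # dispersion; the weakly identified signal parameters are checked via
        # the median over 20 seeds elsewhere
        n, e = simulate_mixture_counts(rng, 5000, self.TRUTH)
        fit = fit_conditional(n, e)
        keep = n > 0
        assert fit.loglik >= conditional_loglik(self.TRUTH, n[keep], e[keep])
        assert abs(fit.params.alpha2 - 2.0) / 2.0 < 0.15

    def test_requires_positive_counts(self):
        with pytest.raises(ValueError):
            fit_conditional(np.zeros(10), np.ones(10))

    def test_permutation_invariant_and_deterministic(self, rng):
        n, e = simulate_mixture_counts(rng, 600, self.TRUTH)
        keep = n > 0
        n, e = n[keep], e[keep]
        fit1 = fit_conditional(n, e)
        perm = rng.permutation(n.size)
        fit2 = fit_conditional(n[perm], e[perm])
        assert fit1.params.alpha2 == pytest.approx(fit2.params.alpha2, rel=1e-6)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        fit3 = fit_conditional(n, e)
        assert fit3.params == fit1.params


class TestFullLoglik:
    def test_matches_scalar_loop_on_hand_fixture(self):
        params = MixtureParams(alpha2=2.0, alpha3=1.0, beta3=0.2, rho=0.25, p1=0.4)
        n = np.array([0, 2, 5])
        e = np.array([1.5, 2.0, 4.0])
        p2 = (1 - 0.4) / 1.25
        p3 = 0.25 * p2
        total = 0.0
        for k, ei in zip(n, e):
            f2 = scalar_negbin_pmf(int(k), 2.0, 2.0, ei)
            f3 = scalar_negbin_pmf(int(k), 1.0, 0.2, ei)
            mix = p2 * f2 + p3 * f3 + (0.4 if k == 0 else 0.0)
            total += math.log(mix)
        assert full_loglik(params, n, e) == pytest.approx(total, abs=1e-12)

    def test_monotone_in_p1_when_all_zero(self):
        n = np.zeros(5)
        e = np.full(5, 3.0)
        lls = [
            full_loglik(MixtureParams(2.0, 1.0, 0.2, 0.1, p1=p), n, e)
            for p in (0.1, 0.5, 0.9, 0.999)
        ]
        assert np.all(np.diff(lls) > 0)
        assert lls[-1] > 5 * math.log(0.999)  # approaches 0 per datum

    def test_requires_p1(self):
        with pytest.raises(ValueError):
            full_loglik(MixtureParams(2.0, 1.0, 0.2, 0.1), np.array([1]), np.array([1.0]))

    def test_full_and_conditional_agree_when_truncation_negligible(self, rng):
        # with E large, P(N = 0) is tiny and the two likelihood surfaces
        # share their optimum over the common parameters
        truth = MixtureParams(alpha2=2.0, alpha3=1.0, beta3=0.2, rho=0.15)
        n, e = simulate_mixture_counts(rng, 4000, truth, e_low=15.0, e_high=40.0)
        keep = n > 0
        n, e = n[keep], e[keep]
        cond = fit_conditional(n, e)
        from scipy import optimize

        def neg_full(x):
            try:
                p = MixtureParams(math.exp(x[0]), math.exp(x[1]) + math.exp(x[2]),
                                  math.exp(x[1]), math.exp(x[3]), p1=0.0)
                return -full_loglik(p, n, e)
            except (ValueError, FloatingPointError):
                return 1e12

        res = optimize.minimize(neg_full, np.log([2.0, 0.2, 0.8, 0.15]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        full_params = MixtureParams(
            math.exp(res.x[0]), math.exp(res.x[1]) + math.exp(res.x[2]),
            math.exp(res.x[1]), math.exp(res.x[3]))
        cond_params = cond.params
        np.testing.assert_allclose(
            [full_params.alpha2, full_params.alpha3, full_params.beta3, full_params.rho],
            [cond_params.alpha2, cond_params.alpha3, cond_params.beta3, cond_params.rho],
            rtol=0.20,
        )
        # the operational quantity must agree far more tightly than the
        # weakly identified signal-shape parameters themselves
        k_grid = np.arange(1, 60)
        for e_val in (15.0, 25.0, 40.0):
            np.testing.assert_allclose(
                adjusted_fdr(k_grid, e_val, full_params),
                adjusted_fdr(k_grid, e_val, cond_params),
                atol=0.05,
            )


class TestAdjustedFdr:
    def test_limits_in_rho(self):
        lo = MixtureParams(2.19, 0.22, 0.04, 1e-9)
        hi = MixtureParams(2.19, 0.22, 0.04, 1e9)
        assert adjusted_fdr(5, 5.0, lo) > 1 - 1e-6
        assert adjusted_fdr(5, 5.0, hi) < 1e-6

    def test_bayes_rule_hand_computation(self):
        k, e = 50, 5.0
        f2 = scalar_negbin_pmf(k, 2.19, 2.19, e)
        f3 = scalar_negbin_pmf(k, 0.22, 0.04, e)
        expected = f2 / (f2 + 0.08 * f3)
        assert adjusted_fdr(k, e, PAPER_LIKE) == pytest.approx(expected, rel=1e-10)

    def test_strictly_decreasing_in_count_under_mlr(self):
        # monotone likelihood ratio holds when the signal shape exceeds the
        # null shape: higher counts then always favour the signal component
        params = MixtureParams(alpha2=2.0, alpha3=3.0, beta3=0.5, rho=0.1)
        for e in (1.0, 5.0, 20.0):
            fdr = adjusted_fdr(np.arange(1, 200), e, params)
            assert np.all(np.diff(fdr) < 0)
            assert np.all((fdr > 0) & (fdr < 1))

    def test_eventually_decreasing_for_heavy_tailed_signal(self):
        # with signal shape < 1 the signal component also explains very small
        # counts, so the FDR can rise over the first few counts before the
        # geometric tail term takes over and forces monotone decrease
        fdr = adjusted_fdr(np.arange(1, 200), 5.0, PAPER_LIKE)
        assert np.all(np.diff(fdr[10:]) < 0)
        assert np.all((fdr > 0) & (fdr < 1))

    def test_rejects_zero_count(self):
        with pytest.raises(ValueError):
            adjusted_fdr(0, 5.0, PAPER_LIKE)


class TestComponentMoments:
    def test_background_sd_is_inverse_root_shape(self):
        mean2, sd2, _, _ = component_moments(PAPER_LIKE)
        assert mean2 == 1.0
        assert sd2 == pytest.approx(1.0 / math.sqrt(2.19), rel=1e-12)

    def test_signal_component_closed_form(self):
        _, _, mean3, sd3 = component_moments(MixtureParams(2.0, 4.0, 2.0, 0.1))
        assert mean3 == pytest.approx(2.0)
        assert sd3 == pytest.approx(1.0)

    def test_constraint_rejects_mean_one_signal(self):
        with pytest.raises(ValueError):
            MixtureParams(alpha2=2.0, alpha3=0.3, beta3=0.3, rho=0.1)
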