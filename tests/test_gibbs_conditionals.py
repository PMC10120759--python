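import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from prsbilevel.gibbs import (
    _inv_gamma,
    beta_conditional_moments,
    half_cauchy_mixture_check,
    half_cauchy_mixture_draws,
    sample_beta_block,
    sample_c,
    sample_delta2,
    sample_delta2_interweave,
    sample_lambda2,
    sample_sigma2,
    sample_t,
    sigma2_rate,
)


class TestBetaConditional:
    def test_equal_shrinkage_halves_the_effect(self):
        mean, _ = beta_conditional_moments(np.eye(2), [1.0, 0.0],
                                           [1.0, 1.0], 1.0, 100)
        np.testing.assert_allclose(mean, [0.5, 0.0])

    def test_no_shrinkage_limit_recovers_beta_hat(self):
        beta_hat = np.array([0.3, -0.1, 0.02])
        mean, _ = beta_conditional_moments(np.eye(3), beta_hat,
                                           np.full(3, 1e8), 1.0, 100)
        np.testing.assert_allclose(mean, beta_hat, atol=1e-8)

    def test_shrinkage_monotone_in_psi(self):
        beta_hat = np.array([0.4])
        means = [beta_conditional_moments(np.eye(1), beta_hat, [p], 1.0,
                                          100)[0][0]
                 for p in (0.1, 0.5, 1.0, 5.0, 50.0)]
        assert all(0 < a < b < 0.4 for a, b in zip(means, means[1:]))
        for p, m in zip((0.1, 0.5, 1.0), means):
            assert m == pytest.approx(0.4 / (1 + 1 / p))

    def test_monte_carlo_covariance_matches(self, rng):
        D = np.array([[1.0, 0.4], [0.4, 1.0]])
        beta_hat = np.array([0.2, -0.1])
        psi = np.array([0.5, 2.0])
        sigma2, n = 0.8, 50
        draws = np.array([sample_beta_block(D, beta_hat, psi, sigma2, n, rng)
                          for _ in range(50_000)])
        mean, cov = beta_conditional_moments(D, beta_hat, psi, sigma2, n)
        # tolerances ~5 Monte-Carlo standard errors
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=2.5e-3)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=2.5e-3)


class TestSigma2:
    def test_rate_vanishing_beta(self):
        assert sigma2_rate(np.zeros(3), np.zeros(3), np.zeros(3),
                           np.ones(3), 100) == pytest.approx(50.0)

    def test_rate_worked_example(self):
        # 1 SNP, D=[1], psi=1, beta_hat=0.5, beta=0.5:
        # N/2 (1 - 2*0.25 + 0.25*2) = N/2
        rate = sigma2_rate([0.5], [0.5], [0.5], [1.0], 100)
        assert rate == pytest.approx(50.0)

    def test_draw_distribution_matches_inverse_gamma(self, rng):
        n, m = 100, 5  # shape (n+m)/2 = 52.5
        beta = np.zeros(m)
        draws = np.array([sample_sigma2(beta, beta, beta, np.ones(m),
                                        n, m, rng) for _ in range(5000)])
        ks = st.kstest(draws, st.invgamma(a=52.5, scale=50.0).cdf)
        assert ks.pvalue > 0.01

    def test_rate_floor_prevents_collapse(self, rng):
        # residual term negative (overfit regime): rate falls back to the
        # prior quadratic term rather than ~0
        beta = np.full(50, 0.5)
        beta_hat = np.full(50, 0.5)
        d_beta = beta.copy()
        psi = np.ones(50)
        draws = [sample_sigma2(beta, beta_hat, d_beta, psi, 100, 50, rng)
                 for _ in range(200)]
        floor_rate = 0.5 * 100 * float(np.sum(beta**2))
        assert np.median(draws) > 0.5 * floor_rate / 75  # same order as floor


class TestDelta2:
    def test_as_printed_rate_reduces_to_t(self, rng):
        # beta = 0 with t_k = 2: printed rate is exactly t_k
        draws = np.array([sample_delta2([], [], 1.0, 2.0, 100, rng,
                                        mode="as_printed")
                          for _ in range(4000)])
        ks = st.kstest(draws, st.invgamma(a=0.5, scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_derived_rate_uses_reciprocal_auxiliary(self, rng):
        draws = np.array([sample_delta2([], [], 1.0, 2.0, 100, rng)
                          for _ in range(4000)])
        ks = st.kstest(draws, st.invgamma(a=0.5, scale=0.5).cdf)
        assert ks.pvalue > 0.01

    def test_plugin_rate_and_shape(self, rng):
        # N=100, sigma2=1, one copy beta=0.1, lambda2=0.5, t=1:
        # rate = 100*0.01/(2*0.5) + 1 = 2, shape (1+1)/2 = 1
        draws = np.array([sample_delta2([0.1], [0.5], 1.0, 1.0, 100, rng)
                          for _ in range(4000)])
        ks = st.kstest(draws, st.invgamma(a=1.0, scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_shape_counts_copies(self, rng):
        draws = np.array([sample_delta2(np.zeros(3), np.ones(3), 1.0, 1.0,
                                        100, rng) for _ in range(4000)])
        ks = st.kstest(draws, st.invgamma(a=2.0, scale=1.0).cdf)
        assert ks.pvalue > 0.01


class TestAuxiliaries:
    def test_t_distribution(self, rng):
        draws = sample_t(np.ones(20000), rng)
        ks = st.kstest(draws, st.invgamma(a=1.0, scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_t_rate_limit_large_delta(self, rng):
        draws = sample_t(np.full(20000, 1e12), rng)
        ks = st.kstest(draws, st.invgamma(a=1.0, scale=1.0).cdf)
        assert ks.pvalue > 0.01

    def test_c_matches_direct_inverse_gamma_sampler(self, rng):
        lam2 = 0.7
        ours = sample_c(np.full(20000, lam2), rng)
        direct = _inv_gamma(rng, 1.0, np.full(20000, 1.0 / lam2 + 1.0))
        ks = st.ks_2samp(ours, direct)
        assert ks.pvalue > 0.01


class TestLambda2:
    def test_zero_beta_modes(self, rng):
        c = 1.0  # both modes coincide at c = 1 (rate c vs 1/c)
        for mode in ("derived", "as_printed"):
            draws = sample_lambda2(np.zeros(20000), 1.0, 1.0,
                                   np.full(20000, c), 100, rng, mode)
            ks = st.kstest(draws, st.invgamma(a=1.0, scale=1.0).cdf)
            assert ks.pvalue > 0.01, mode

    def test_plugin_rate_agreement_at_unit_delta(self, rng):
        # N=100, beta=0.1, sigma2=1, delta2=1, c=1 -> rate 1.5 in both modes
        for mode in ("derived", "as_printed"):
            draws = sample_lambda2(np.full(20000, 0.1), 1.0, 1.0,
                                   np.ones(20000), 100, rng, mode)
            ks = st.kstest(draws, st.invgamma(a=1.0, scale=1.5).cdf)
            assert ks.pvalue > 0.01, mode

    def test_modes_differ_when_delta_not_unit(self, rng):
        derived = sample_lambda2(np.full(20000, 0.3), 1.0, 4.0,
                                 np.ones(20000), 100, rng, "derived")
        printed = sample_lambda2(np.full(20000, 0.3), 1.0, 4.0,
                                 np.ones(20000), 100, rng, "as_printed")
        assert st.ks_2samp(derived, printed).pvalue < 1e-6


class TestHalfCauchy:
    def test_ks_distance_small(self):
        assert half_cauchy_mixture_check(100_000, seed=0) < 0.01

    def test_quantiles(self, rng):
        x = half_cauchy_mixture_draws(100_000, rng)
        assert np.median(x) == pytest.approx(1.0, abs=0.02)
        assert np.quantile(x, 0.75) == pytest.approx(np.tan(3 * np.pi / 8),
                                                     abs=0.05)

    def test_minimum_draws_enforced(self):
        with pytest.raises(Exception):
            half_cauchy_mixture_check(100)

    def test_prior_gibbs_cycle_keeps_half_cauchy_marginal(self, rng):
        """Iterating delta2|t and t|delta2 with no data must leave the
        half-Cauchy prior invariant (consistency of the conditional pair)."""
        n = 100_000
        d2 = np.ones(n)
        t = np.ones(n)
        for _ in range(50):
            d2 = _inv_gamma(rng, 0.5, 1.0 / t)
            t = _inv_gamma(rng, 1.0, 1.0 / d2 + 1.0)
        ks = st.kstest(np.sqrt(d2), st.halfcauchy.cdf)
        assert ks.statistic < 0.01


class TestInterweave:
    def test_preserves_products_scale(self, rng):
        psi = np.array([0.2, 1.5, 0.01])
        draws = [sample_delta2_interweave(psi, np.ones(3), 1.0, rng)
                 for _ in range(2000)]
        assert np.all(np.array(draws) > 0)
        # conditional is GIG((M-1)/2, 2S, 2R); check against scipy density
        s = float(np.sum(1.0 / psi))
        gig = st.geninvgauss(1.0, 2 * np.sqrt(s), scale=np.sqrt(1 / s))
        assert st.kstest(draws, gig.cdf).pvalue > 0.01


@given(st_h.floats(0.01, 10), st_h.floats(0.01, 10), st_h.floats(-1, 1),
       st_h.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_all_scale_draws_strictly_positive(delta2, lam2, beta, seed):
    """Every variance-type conditional must produce strictly positive draws."""
    g = np.random.default_rng(seed)
    assert sample_t(delta2, g) > 0
    assert sample_c(lam2, g) > 0
    assert sample_lambda2(beta, 1.0, delta2, 1.0, 100, g) > 0
    assert sample_delta2([beta], [lam2], 1.0, 1.0, 100, g) > 0
    assert sample_sigma2([beta], [beta], [beta], [1.0], 100, 1, g) > 0
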