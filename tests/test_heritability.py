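"""Closed-form lognormal moments, variance decomposition, and heritability
measures, each checked against independent Monte-Carlo oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import corebreak as cb
from corebreak.heritability import _pooling_mask


def _pop(mu_la=math.log(5), mu_lb=math.log(0.6), s_la=0.25, s_lb=0.25,
         rho=0.6, s_tau=0.2, s_phi=0.35):
    return cb.PopulationParams(
        psi0=1.5, kappa=(0.0,), mu_logalpha=mu_la, mu_logbeta=mu_lb,
        sigma_logalpha=s_la, sigma_logbeta=s_lb, rho=rho,
        sigma_tau=s_tau, sigma_phi=s_phi)


class TestLognormalMoments:
    def test_degenerate_sigma(self):
        mean, var = cb.lognormal_moments(1.3, 0.0)
        assert mean == pytest.approx(math.exp(1.3)) and var == 0.0

    def test_standard_lognormal_mean(self):
        mean, var = cb.lognormal_moments(0.0, 1.0)
        assert mean == pytest.approx(math.exp(0.5), rel=1e-12)
        assert mean == pytest.approx(1.64872, abs=1e-5)
        # closed form cross-checked by Monte Carlo
        draws = np.exp(np.random.default_rng(0).standard_normal(1_000_000))
        assert mean == pytest.approx(draws.mean(), rel=0.01)
        assert var == pytest.approx(draws.var(), rel=0.02)

    @given(mu=st.floats(-1, 2), s1=st.floats(0.05, 0.8),
           ds=st.floats(0.01, 0.5))
    def test_variance_increasing_in_sigma(self, mu, s1, ds):
        assert cb.lognormal_moments(mu, s1 + ds)[1] \
            > cb.lognormal_moments(mu, s1)[1]


class TestLognormalCov:
    def test_independence_gives_zero(self):
        assert cb.lognormal_cov(0.3, -0.2, 0.4, 0.3, 0.0) == 0.0

    @given(rho=st.floats(-0.99, 0.99).filter(lambda r: abs(r) > 1e-3))
    def test_sign_matches_rho(self, rho):
        cov = cb.lognormal_cov(0.0, -0.5, 0.3, 0.25, rho)
        assert np.sign(cov) == np.sign(rho)

    def test_monte_carlo_agreement(self, rng):
        mu_a, mu_b, s_a, s_b, rho = 0.0, math.log(0.5), 0.3, 0.3, 0.6
        z1 = rng.standard_normal(1_000_000)
        z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.standard_normal(1_000_000)
        a, b = np.exp(mu_a + s_a * z1), np.exp(mu_b + s_b * z2)
        mc = np.cov(a, b)[0, 1]
        assert cb.lognormal_cov(mu_a, mu_b, s_a, s_b, rho) == pytest.approx(
            mc, rel=0.02)


class TestConditionalResidualVar:
    def test_no_correlation_equals_marginal_variance(self):
        _, var = cb.lognormal_moments(0.4, 0.3)
        assert cb.conditional_residual_var(0.4, 0.3, 0.0) == pytest.approx(
            var, rel=1e-12)

    @pytest.mark.parametrize("rho", [-1.0, 1.0])
    def test_perfect_correlation_gives_zero(self, rho):
        assert cb.conditional_residual_var(0.2, 0.4, rho) == pytest.approx(
            0.0, abs=1e-12)

    def test_nested_monte_carlo_agreement(self, rng):
        # E_b[ Var(alpha | b) ]: sample b, then alpha | b in closed form
        mu_a, s_a, rho = math.log(5), 0.25, 0.6
        z_b = rng.standard_normal(400_000)
        cond_mu = mu_a + rho * s_a * z_b
        cond_s2 = s_a ** 2 * (1 - rho ** 2)
        cond_var = np.exp(2 * cond_mu + cond_s2) * np.expm1(cond_s2)
        assert cb.conditional_residual_var(mu_a, s_a, rho) == pytest.approx(
            cond_var.mean(), rel=0.02)

    @given(mu=st.floats(-0.5, 2.0), s=st.floats(0.01, 0.7),
           rho=st.floats(-1.0, 1.0))
    def test_never_exceeds_marginal_variance(self, mu, s, rho):
        _, var = cb.lognormal_moments(mu, s)
        assert cb.conditional_residual_var(mu, s, rho) <= var + 1e-12


class TestVarianceDecomposition:
    def test_depth_one_kills_alpha_and_covariance_terms(self):
        d = cb.variance_decomposition(_pop(), 1)
        assert d.v_alpha == 0.0 and d.c_alphabeta == 0.0
        assert d.sigma2_genes == pytest.approx(d.v_tau + d.v_beta)

    def test_no_genetic_variation_means_zero_genetic_variance(self):
        pop = _pop(s_la=0.0, s_lb=0.0, s_tau=0.0)
        for t in (1, 5, 18):
            assert cb.variance_decomposition(pop, t).sigma2_genes == 0.0
            assert cb.heritability_curve(pop, "overall", 18)[t - 1] == 0.0

    def test_total_matches_monte_carlo_variance_of_log_theta(self, rng):
        pop = _pop()
        t = 9
        gs = cb.draw_genotypes(pop, 1_000_000, rng)
        tau = np.array([g.tau for g in gs])
        alpha = np.array([g.alpha for g in gs])
        beta = np.array([g.beta for g in gs])
        phi = pop.sigma_phi * rng.standard_normal(tau.size)
        log_theta = tau + (alpha - 1) * math.log(t) - beta * t + phi
        d = cb.variance_decomposition(pop, t)
        assert d.sigma2_logtheta == pytest.approx(log_theta.var(), rel=0.02)

    def test_closed_form_genes_variance_over_random_parameter_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            pop = _pop(mu_la=rng.uniform(0.8, 2.0),
                       mu_lb=rng.uniform(-1.2, 0.0),
                       s_la=rng.uniform(0.05, 0.4),
                       s_lb=rng.uniform(0.05, 0.4),
                       rho=rng.uniform(-0.9, 0.9),
                       s_tau=rng.uniform(0.05, 0.5),
                       s_phi=rng.uniform(0.05, 0.5))
            t = int(rng.integers(2, 19))
            gs = cb.draw_genotypes(pop, 300_000, rng)
            contrib = (np.array([g.tau for g in gs])
                       + (np.array([g.alpha for g in gs]) - 1) * math.log(t)
                       - np.array([g.beta for g in gs]) * t)
            d = cb.variance_decomposition(pop, t)
            assert d.sigma2_genes == pytest.approx(contrib.var(), rel=0.02)

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            cb.variance_decomposition(_pop(), 0)


class TestHeritabilityCurve:
    def test_no_segment_noise_forces_unity(self):
        h2 = cb.heritability_curve(_pop(s_phi=0.0), "overall", 18)
        assert np.allclose(h2, 1.0)

    def test_only_tau_genetic_forced_arithmetic(self):
        pop = _pop(s_la=0.0, s_lb=0.0, s_tau=1.0, s_phi=1.0)
        assert np.allclose(cb.heritability_curve(pop, "overall", 18), 0.5)
        assert cb.heritability_curve(pop, "tau") == pytest.approx(0.5)

    def test_default_truth_more_heritable_at_depth(self):
        h2 = cb.heritability_curve(cb.DEFAULT_TRUTH, "overall", 18)
        assert h2[17] > h2[1]

    def test_alpha_component_zero_at_surface_and_excluded_from_pooling(self):
        h2 = cb.heritability_curve(_pop(), "alpha_given_beta", 18)
        assert h2[0] == 0.0
        mask = _pooling_mask("alpha_given_beta", 18)
        assert not mask[0] and mask[1:].all()
        assert cb.pooled_heritability(_pop(), "alpha_given_beta", 18) > 0.0

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            cb.heritability_curve(_pop(), "epistasis")

    @given(
        s_la=st.floats(0.0, 0.6), s_lb=st.floats(0.0, 0.6),
        rho=st.floats(-0.95, 0.95), s_tau=st.floats(0.0, 1.0),
        s_phi=st.floats(0.01, 1.0),
    )
    def test_all_measures_bounded_in_unit_interval(self, s_la, s_lb, rho,
                                                   s_tau, s_phi):
        pop = _pop(s_la=s_la, s_lb=s_lb, rho=rho, s_tau=s_tau, s_phi=s_phi)
        for measure in cb.MEASURES:
            h2 = np.atleast_1d(cb.heritability_curve(pop, measure, 18))
            assert np.all(h2 >= 0.0) and np.all(h2 <= 1.0)

    @given(
        s_la=st.floats(0.05, 0.5), s_lb=st.floats(0.05, 0.5),
        rho=st.floats(-0.9, 0.9),
    )
    def test_component_measures_bounded_by_overall(self, s_la, s_lb, rho):
        pop = _pop(s_la=s_la, s_lb=s_lb, rho=rho)
        overall = cb.heritability_curve(pop, "overall", 18)
        for measure in ("alpha_given_beta", "beta_given_alpha"):
            comp = cb.heritability_curve(pop, measure, 18)
            assert np.all(comp <= overall + 1e-9)


class TestPooling:
    def test_idempotent_on_equal_values(self):
        assert cb.pool_harmonic([0.7] * 18) == pytest.approx(0.7, rel=1e-12)

    def test_forced_arithmetic(self):
        assert cb.pool_harmonic([0.5, 1.0]) == pytest.approx(2.0 / 3.0,
                                                             rel=1e-12)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=18))
    def test_harmonic_below_arithmetic_mean(self, values):
        assert cb.pool_harmonic(values) <= np.mean(values) + 1e-12

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=18),
           st.randoms(use_true_random=False))
    def test_invariant_to_depth_permutation(self, values, random):
        shuffled = list(values)
        random.shuffle(shuffled)
        assert cb.pool_harmonic(shuffled) == pytest.approx(
            cb.pool_harmonic(values), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cb.pool_harmonic([0.5, 0.0])


class TestPosteriorHeritability:
    def test_degenerate_posterior_equals_plug_in(self, small_fit):
        import copy

        post = small_fit
        # collapse every draw to the first one -> zero-width intervals
        frozen = copy.copy(post)
        frozen.posterior = {
            k: np.broadcast_to(v[:1, :1], v.shape).copy()
            for k, v in post.posterior.items()
        }
        res = cb.posterior_heritability(frozen, "overall")
        pooled = res.curve[res.curve["depth"] == "pooled"].iloc[0]
        assert pooled["lower"] == pytest.approx(pooled["upper"], abs=1e-12)
        # plug-in value from the same single draw
        pop = cb.PopulationParams(
            psi0=float(frozen.posterior["psi0"][0, 0]),
            kappa=(0.0, 0.0),
            mu_logalpha=float(frozen.posterior["mu_logalpha"][0, 0]),
            mu_logbeta=float(frozen.posterior["mu_logbeta"][0, 0]),
            sigma_logalpha=float(frozen.posterior["sigma_logalpha"][0, 0]),
            sigma_logbeta=float(frozen.posterior["sigma_logbeta"][0, 0]),
            rho=float(frozen.posterior["rho"][0, 0]),
            sigma_tau=float(frozen.posterior["sigma_tau"][0, 0]),
            sigma_phi=float(frozen.posterior["sigma_phi"][0, 0]))
        n_d = frozen.design.n_depths
        assert pooled["median"] == pytest.approx(
            cb.pooled_heritability(pop, "overall", n_d), rel=1e-9)

    def test_pooled_draw_below_max_depth_value(self, small_fit):
        res = cb.posterior_heritability(small_fit, "overall")
        depth_rows = res.curve[res.curve["depth"] != "pooled"]
        assert res.pooled_draws.max() <= depth_rows["upper"].max() + 1e-9

    def test_all_four_measures_summarized(self, small_fit):
        for measure in cb.MEASURES:
            res = cb.posterior_heritability(small_fit, measure)
            pooled = res.curve[res.curve["depth"] == "pooled"]
            assert len(pooled) == 1
            assert 0.0 <= pooled.iloc[0]["median"] <= 1.0
            n_depth_rows = len(res.curve) - 1
            assert n_depth_rows == (0 if measure == "tau"
                                    else small_fit.design.n_depths)

    def test_naive_fit_rejected(self, small_dataset):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = cb.fit(small_dataset, "naive",
                          mcmc=cb.McmcConfig(n_chains=2, n_warmup=150,
                                             n_draws=100, seed=2))
        with pytest.raises(ValueError, match="hyper-parameter"):
            cb.posterior_heritability(post, "overall")
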