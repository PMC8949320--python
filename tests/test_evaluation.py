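"""Pointwise likelihood, PSIS-LOO, comparison, PPC and person estimates."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from lpgrowth import (
    GrowthModelSpec,
    SamplerConfig,
    compare_models,
    cross_model_correlation,
    draw_person_effects,
    eap_estimates,
    fit_model,
    loglik_gaussian,
    loglik_student_t,
    model_density_curve,
    pointwise_loglik,
    posterior_predictive,
    psis_loo,
    simulate_scores,
)
from lpgrowth.evaluation import LooResult, psislw
from lpgrowth.gibbs import _scores_to_matrix

from .conftest import make_params


class TestPointwise:
    def test_matches_family_loglik_elementwise(self, small_gauss_fit, small_gauss_data):
        ll = pointwise_loglik(small_gauss_fit, small_gauss_data)
        person = small_gauss_fit.stacked_person()
        sigma = small_gauss_fit.stacked("sigma")
        _, y = _scores_to_matrix(small_gauss_data)
        t = np.arange(8.0)
        s = 17  # arbitrary draw
        eta = person[s, :, :1] + person[s, :, 1:] * t
        np.testing.assert_allclose(
            ll[:, s], loglik_gaussian(y, eta, sigma[s]).ravel(), atol=1e-12
        )

    def test_sum_equals_likelihood_term_of_log_posterior(
        self, small_gauss_fit, small_gauss_data
    ):
        # consistency oracle: column sums reproduce the likelihood term
        ll = pointwise_loglik(small_gauss_fit, small_gauss_data)
        person = small_gauss_fit.stacked_person()
        sigma = small_gauss_fit.stacked("sigma")
        _, y = _scores_to_matrix(small_gauss_data)
        t = np.arange(8.0)
        for s in (0, 100):
            eta = person[s, :, :1] + person[s, :, 1:] * t
            expected = loglik_gaussian(y, eta, sigma[s]).sum()
            assert ll[:, s].sum() == pytest.approx(expected, abs=1e-8)

    def test_t_family_beats_gaussian_at_extreme_residuals(self):
        sigma = 10.0
        extreme = 80.0
        assert loglik_student_t(extreme, 0.0, sigma, 3.22) > loglik_gaussian(
            extreme, 0.0, sigma
        )


class TestPsis:
    def test_identical_draws_give_degenerate_weights_path(self):
        ll = np.tile(np.array([-1.3, -0.7, -2.1])[:, None], (1, 200))
        res = psis_loo(ll)
        np.testing.assert_allclose(res.elpd_pointwise, ll[:, 0])
        assert res.elpd_loo == pytest.approx(ll[:, 0].sum())

    def test_total_is_sum_of_pointwise(self, small_gauss_fit, small_gauss_data):
        res = psis_loo(pointwise_loglik(small_gauss_fit, small_gauss_data))
        assert res.elpd_loo == pytest.approx(res.elpd_pointwise.sum())

    def test_se_formula_against_bootstrap_oracle(self, rng):
        pointwise = rng.normal(-2.0, 0.7, size=300)
        res = LooResult(pointwise, np.zeros(300), float(pointwise.sum()),
                        float(np.sqrt(300 * np.var(pointwise, ddof=1))))
        boots = [
            pointwise[rng.integers(0, 300, 300)].sum() for _ in range(2000)
        ]
        assert res.se == pytest.approx(np.std(boots), rel=0.15)

    def test_agreement_with_reference_psis_on_fixed_matrices(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from arviz.stats.stats import _psislw

        rng = np.random.default_rng(11)
        # n_draws <= 225 so the 20% tail convention coincides with the
        # reference implementation's min(S/5, 3*sqrt(S)) rule
        lr = rng.normal(size=(25, 200)) + rng.standard_t(3, size=(25, 200))
        lw, khat = psislw(lr)
        cutoff_ind = -int(np.ceil(min(200 / 5.0, 3 * np.sqrt(200)))) - 1
        for i in range(25):
            ref_lw, ref_k = _psislw(
                lr[i].copy(), cutoff_ind, np.log(np.finfo(float).tiny), True
            )
            np.testing.assert_allclose(lw[i], ref_lw, atol=1e-10)
            assert khat[i] == pytest.approx(ref_k, abs=1e-10)

    def test_too_few_draws_rejected(self):
        with pytest.raises(Exception):
            psis_loo(np.zeros((5, 50)))


class TestCompare:
    def test_model_compared_with_itself_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        pw = rng.normal(-2, 1, 100)
        a = LooResult(pw, np.zeros(100), float(pw.sum()), 1.0, model="a")
        b = LooResult(pw.copy(), np.zeros(100), float(pw.sum()), 1.0, model="b")
        comp = compare_models([a, b])
        assert (comp.table["elpd_diff"] == 0.0).all()
        assert (comp.table["diff_se"] == 0.0).all()

    def test_difference_antisymmetry(self):
        rng = np.random.default_rng(1)
        pw_a = rng.normal(-2, 1, 100)
        pw_b = pw_a + rng.normal(0.3, 0.5, 100)
        a = LooResult(pw_a, np.zeros(100), float(pw_a.sum()), 1.0, model="a")
        b = LooResult(pw_b, np.zeros(100), float(pw_b.sum()), 1.0, model="b")
        comp = compare_models([a, b])
        worse = comp.table["elpd_diff"].min()
        assert worse == pytest.approx(-abs(pw_a.sum() - pw_b.sum()))
        # the pointwise difference SE is symmetric in the pair
        se_ab = np.sqrt(100 * np.var(pw_a - pw_b, ddof=1))
        assert comp.table["diff_se"].max() == pytest.approx(se_ab)

    def test_mismatched_observation_sets_rejected(self):
        a = LooResult(np.zeros(10), np.zeros(10), 0.0, 1.0, model="a")
        b = LooResult(np.zeros(12), np.zeros(12), 0.0, 1.0, model="b")
        with pytest.raises(Exception):
            compare_models([a, b])


class TestPosteriorPredictive:
    def test_reps_of_near_deterministic_model_follow_the_line(self):
        params = make_params(sd_b0=0.0, sd_b1=0.0, rho=0.0, sigma=1e-6)
        eff = draw_person_effects(params, 30, seed=0)
        data = simulate_scores(eff, params, 8, seed=1)
        fit = fit_model(
            data, GrowthModelSpec(family="gaussian"),
            SamplerConfig(chains=2, iterations=600, seed=2, store_person_draws=True),
            fixed={"sigma": 1e-6, "Sigma": np.eye(2) * 1e-12,
                   "mu": np.array([params.mu_b0, params.mu_b1])},
        )
        ppc = posterior_predictive(fit, data, n_reps=5, seed=3)
        line_min = params.mu_b0  # slope positive: minimum at t=0
        line_max = params.mu_b0 + params.mu_b1 * 7
        assert ppc["rep_summaries"]["min"].to_numpy() == pytest.approx(line_min, abs=0.01)
        assert ppc["rep_summaries"]["max"].to_numpy() == pytest.approx(line_max, abs=0.01)

    def test_gaussian_ranges_within_normal_tail_bound(
        self, small_gauss_fit, small_gauss_data
    ):
        ppc = posterior_predictive(small_gauss_fit, small_gauss_data, n_reps=10, seed=4)
        p = small_gauss_fit.mean_params()
        total_sd = np.sqrt(p.sd_b0**2 + (7 * p.sd_b1) ** 2 + p.sigma**2)
        center = p.mu_b0 + p.mu_b1 * 3.5
        # a normal sample of n*T values virtually never exceeds ~4.5 total SDs
        assert ppc["rep_summaries"]["max"].max() < center + 5.5 * total_sd
        assert ppc["rep_summaries"]["min"].min() > center - 5.5 * total_sd

    def test_t_reps_produce_more_extreme_minima_than_gaussian(self, heavy_tail_data):
        cfg = dict(chains=2, iterations=1200, seed=5, store_person_draws=True)
        fit_g = fit_model(
            heavy_tail_data, GrowthModelSpec(family="gaussian"), SamplerConfig(**cfg)
        )
        fit_t = fit_model(
            heavy_tail_data, GrowthModelSpec(family="student_t"), SamplerConfig(**cfg)
        )
        ppc_g = posterior_predictive(fit_g, heavy_tail_data, n_reps=10, seed=6)
        ppc_t = posterior_predictive(fit_t, heavy_tail_data, n_reps=10, seed=6)
        assert ppc_t["rep_summaries"]["min"].min() < ppc_g["rep_summaries"]["min"].min()

    def test_too_many_reps_rejected(self, small_gauss_fit, small_gauss_data):
        with pytest.raises(Exception):
            posterior_predictive(small_gauss_fit, small_gauss_data, n_reps=10**6)


class TestDensityCurve:
    # the fitted response distributions at the first timepoint of an
    # average student: N(-13.98, 34.10), t(-12.79, 14.55, 3.22),
    # ALD(-12.70, 7.67, 0.50)
    TRIPLES = {
        "gaussian": (-13.98, 34.10, None),
        "student_t": (-12.79, 14.55, 3.22),
        "asym_laplace": (-12.70, 7.67, None),
    }

    @pytest.mark.parametrize("family", list(TRIPLES))
    def test_integrates_to_one(self, family):
        loc, scale, nu = self.TRIPLES[family]
        val, _ = integrate.quad(
            lambda y: model_density_curve(family, loc, scale, np.array([y, y]), nu)[0],
            -np.inf, np.inf,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_robust_tails_exceed_gaussian(self):
        grid = np.array([-180.0, 160.0])
        g = model_density_curve("gaussian", *self.TRIPLES["gaussian"][:2], grid)
        t = model_density_curve("student_t", -12.79, 14.55, grid, nu=3.22)
        a = model_density_curve("asym_laplace", -12.70, 7.67, grid)
        assert (t > g).all()
        assert (a > g).all()

    def test_symmetry_about_location_for_median_families(self):
        d = np.linspace(0.5, 40, 9)
        for family, (loc, scale, nu) in self.TRIPLES.items():
            up = model_density_curve(family, loc, scale, loc + d, nu)
            dn = model_density_curve(family, loc, scale, loc - d, nu)
            np.testing.assert_allclose(up, dn, rtol=1e-10)


class TestPersonEstimates:
    def test_noise_free_recovery_of_slopes(self):
        params = make_params(sd_b0=5.0, sd_b1=2.0, rho=0.0, sigma=0.05)
        eff = draw_person_effects(params, 40, seed=7)
        data = simulate_scores(eff, params, 8, seed=8)
        fit = fit_model(
            data, GrowthModelSpec(family="gaussian"),
            SamplerConfig(chains=2, iterations=800, seed=9, store_person_draws=True),
        )
        est = eap_estimates(fit).merge(eff, on="person_id")
        np.testing.assert_allclose(est["eap_b1"], est["b1"], atol=0.05)

    def test_posterior_sds_shrink_with_more_timepoints(self):
        # population parameters held at truth so the comparison isolates
        # per-person measurement precision from estimation noise
        params = make_params()
        eff = draw_person_effects(params, 60, seed=10)
        fixed = {
            "mu": np.array([params.mu_b0, params.mu_b1]),
            "Sigma": params.latent_cov,
            "sigma": params.sigma,
        }
        out = {}
        for t_n in (4, 8):
            data = simulate_scores(eff, params, t_n, seed=11)
            fit = fit_model(
                data, GrowthModelSpec(family="gaussian", n_timepoints=t_n),
                SamplerConfig(chains=2, iterations=800, seed=12, store_person_draws=True),
                fixed=fixed,
            )
            out[t_n] = eap_estimates(fit)["sd_b1"].median()
        assert out[8] < out[4]

    def test_intercepts_better_resolved_than_slopes(self, small_gauss_fit):
        est = eap_estimates(small_gauss_fit)
        assert est["relprec_b0"].median() < est["relprec_b1"].median()

    def test_cross_model_correlation_with_itself_is_one(self, small_gauss_fit):
        est = eap_estimates(small_gauss_fit)
        r = cross_model_correlation(est, est)
        assert r["r_b0"] == pytest.approx(1.0)
        assert r["r_b1"] == pytest.approx(1.0)

    def test_correlation_invariant_to_linear_rescaling(self, small_gauss_fit):
        est = eap_estimates(small_gauss_fit)
        scaled = est.copy()
        scaled[["eap_b0", "eap_b1"]] = scaled[["eap_b0", "eap_b1"]] * 30.0 + 2.0
        r = cross_model_correlation(est, scaled)
        assert r["r_b0"] == pytest.approx(1.0)
        assert r["r_b1"] == pytest.approx(1.0)

    def test_too_few_shared_persons_rejected(self, small_gauss_fit):
        est = eap_estimates(small_gauss_fit)
        with pytest.raises(Exception):
            cross_model_correlation(est.head(2), est.head(2))
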