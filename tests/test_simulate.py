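"""Synthetic-data generator: distributional correctness and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from lpgrowth import (
    ItemDesign,
    ParameterError,
    default_growth_params,
    draw_person_effects,
    rald,
    simulate_item_responses,
    simulate_scores,
)

from .conftest import make_params


class TestPersonEffects:
    def test_degenerate_sds_give_exact_means(self):
        params = make_params(sd_b0=0.0, sd_b1=0.0, rho=0.0)
        eff = draw_person_effects(params, 50, seed=1)
        assert np.allclose(eff["b0"], params.mu_b0)
        assert np.allclose(eff["b1"], params.mu_b1)

    def test_sample_correlation_matches_reference_gaussian_values(self):
        # generative rho = -0.55; MC error of r at n=50000 is ~(1-rho^2)/sqrt(n)
        params = default_growth_params("gaussian")
        eff = draw_person_effects(params, 50_000, seed=2)
        r = np.corrcoef(eff["b0"], eff["b1"])[0, 1]
        assert r == pytest.approx(-0.55, abs=4 * (1 - 0.55**2) / np.sqrt(50_000))

    def test_slope_mean_within_clt_bound(self):
        params = make_params()
        n = 50_000
        eff = draw_person_effects(params, n, seed=3)
        assert abs(eff["b1"].mean() - params.mu_b1) < 4 * params.sd_b1 / np.sqrt(n)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParameterError):
            make_params(rho=1.5)
        with pytest.raises(ParameterError):
            make_params(sigma=0.0)
        with pytest.raises(ParameterError):
            make_params(family="student_t")  # missing nu
        with pytest.raises(ParameterError):
            draw_person_effects(make_params(), 0, seed=0)


class TestSimulateScores:
    def test_noise_free_line(self):
        params = make_params(sd_b0=0.0, sd_b1=0.0, rho=0.0, sigma=1e-12)
        eff = draw_person_effects(params, 3, seed=0)
        data = simulate_scores(eff, params, 8, seed=0)
        t = data["timepoint"].to_numpy()
        assert np.allclose(data["y"], params.mu_b0 + params.mu_b1 * t)

    def test_design_shape_eight_rows_per_person(self):
        params = default_growth_params("gaussian")
        data = simulate_scores(draw_person_effects(params, 11, seed=0), params, 8, seed=0)
        assert len(data) == 88
        assert (data.groupby("person_id").size() == 8).all()
        assert sorted(data["timepoint"].unique()) == list(range(8))
        assert not data["y"].isna().any()

    def test_variance_decomposition_at_t0(self):
        params = default_growth_params("gaussian")
        eff = draw_person_effects(params, 60_000, seed=4)
        data = simulate_scores(eff, params, 2, seed=5)
        v0 = data.loc[data.timepoint == 0, "y"].var()
        expected = params.sd_b0**2 + params.sigma**2
        assert v0 == pytest.approx(expected, rel=0.03)

    def test_student_t_residual_tails_heavier_than_gaussian(self):
        # nu = 3.22 < 4: kurtosis undefined, so compare tail quantile ratios
        # against the analytic t quantiles instead of moments
        params = default_growth_params("student_t")
        base = make_params(sd_b0=0.0, sd_b1=0.0, rho=0.0, sigma=params.sigma,
                           family="student_t", nu=params.nu, mu_b0=0.0, mu_b1=0.0)
        eff = draw_person_effects(base, 100_000, seed=6)
        data = simulate_scores(eff, base, 2, seed=7)
        resid = data["y"].to_numpy()
        q995 = np.quantile(resid, 0.995)
        expected = params.sigma * stats.t.ppf(0.995, params.nu)
        assert q995 == pytest.approx(expected, rel=0.1)
        # heavier than a scale-matched normal
        assert q995 > params.sigma * stats.norm.ppf(0.995)

    def test_reproducible_bit_identical(self):
        params = default_growth_params("asym_laplace")
        eff = draw_person_effects(params, 20, seed=9)
        a = simulate_scores(eff, params, 8, seed=10)
        b = simulate_scores(eff, params, 8, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterError):
            make_params(family="cauchy")


class TestRald:
    def test_symmetric_case_median_and_skewness(self):
        x = rald(200_000, mu=2.0, sigma=1.5, p=0.5, seed=0)
        assert np.median(x) == pytest.approx(2.0, abs=0.02)
        assert stats.skew(x) == pytest.approx(0.0, abs=0.05)

    def test_cdf_at_mu_equals_p(self):
        x = rald(100_000, mu=-1.0, sigma=2.0, p=0.25, seed=1)
        assert np.mean(x < -1.0) == pytest.approx(0.25, abs=0.01)

    def test_mean_absolute_deviation_matches_quadrature_oracle(self):
        mu, sigma, p = 0.7, 1.3, 0.35
        dens = lambda y: p * (1 - p) / sigma * np.exp(
            -((y - mu) / sigma) * (p - ((y - mu) < 0))
        )
        expected, _ = integrate.quad(lambda y: abs(y - mu) * dens(y), -60, 60)
        x = rald(400_000, mu, sigma, p, seed=2)
        assert np.mean(np.abs(x - mu)) == pytest.approx(expected, rel=0.02)

    def test_variance_matches_density_integration(self):
        # moment checked against numeric integration of the stated density,
        # not an assumed closed form
        sigma, p = 2.0, 0.5
        dens = lambda y: p * (1 - p) / sigma * np.exp(-(y / sigma) * (p - (y < 0)))
        total, _ = integrate.quad(dens, -200, 200)
        assert total == pytest.approx(1.0, abs=1e-8)
        m2, _ = integrate.quad(lambda y: y * y * dens(y), -200, 200)
        x = rald(400_000, 0.0, sigma, p, seed=3)
        assert np.var(x) == pytest.approx(m2, rel=0.03)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        p=st.floats(0.05, 0.95),
        sigma=st.floats(0.1, 10.0),
        mu=st.floats(-50.0, 50.0),
    )
    def test_quantile_property_for_any_parameters(self, p, sigma, mu):
        x = rald(4000, mu, sigma, p, seed=17)
        assert np.mean(x < mu) == pytest.approx(p, abs=0.05)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            rald(10, sigma=-1.0)
        with pytest.raises(ParameterError):
            rald(10, p=1.0)


@pytest.fixture(scope="module")
def effects():
    params = default_growth_params("gaussian")
    return draw_person_effects(params, 150, seed=30), params


class TestItemResponses:

    def test_clean_responses_inside_support(self, effects):
        eff, params = effects
        design = ItemDesign(fast_rate=0.0, slow_rate=0.0)
        items = simulate_item_responses(eff, params, design, seed=31)
        for sub, grp in items.groupby("subscale"):
            assert grp["rt_ms"].min() >= design.clean_low_ms[sub]
            assert grp["rt_ms"].max() <= design.clean_high_ms[sub]

    def test_fast_guess_rate_close_to_nominal(self, effects):
        eff, params = effects
        design = ItemDesign(fast_rate=0.05, slow_rate=0.0)
        items = simulate_item_responses(eff, params, design, seed=32)
        frac = 0.0
        for sub, grp in items.groupby("subscale"):
            frac += np.mean(grp["rt_ms"] < design.clean_low_ms[sub])
        frac /= items["subscale"].nunique()
        # binomial proportion oracle: 4 SEs around 0.05
        n_per = len(items) / 3
        assert frac == pytest.approx(0.05, abs=4 * np.sqrt(0.05 * 0.95 / n_per))

    def test_higher_latent_level_means_higher_accuracy(self):
        params = make_params(sd_b0=0.0, sd_b1=0.0, rho=0.0)
        lo = draw_person_effects(make_params(mu_b0=-50, sd_b0=0, sd_b1=0, rho=0), 80, seed=33)
        hi = draw_person_effects(make_params(mu_b0=40, sd_b0=0, sd_b1=0, rho=0), 80, seed=33)
        acc_lo = simulate_item_responses(lo, params, seed=34)["correct"].mean()
        acc_hi = simulate_item_responses(hi, params, seed=34)["correct"].mean()
        assert acc_hi > acc_lo

    def test_reproducible_and_validated(self, effects):
        eff, params = effects
        a = simulate_item_responses(eff.head(10), params, seed=35)
        b = simulate_item_responses(eff.head(10), params, seed=35)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ParameterError):
            simulate_item_responses(eff, params, ItemDesign(items_per_subscale={}), seed=0)
        with pytest.raises(ParameterError):
            simulate_item_responses(eff, params, ItemDesign(fast_rate=1.0), seed=0)
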