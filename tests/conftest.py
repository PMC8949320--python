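import numpy as np
import pandas as pd
import pytest

from lpgrowth import (
    GrowthModelSpec,
    GrowthParams,
    SamplerConfig,
    default_growth_params,
    draw_person_effects,
    fit_model,
    simulate_scores,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gauss_params():
    return default_growth_params("gaussian")


@pytest.fixture(scope="session")
def small_gauss_data():
    """80 persons x 8 timepoints simulated at the reference Gaussian values."""
    params = default_growth_params("gaussian")
    eff = draw_person_effects(params, 80, seed=7)
    return simulate_scores(eff, params, 8, seed=8)


@pytest.fixture(scope="session")
def small_gauss_fit(small_gauss_data):
    """A quick Gaussian fit with stored person draws, shared across tests."""
    spec = GrowthModelSpec(family="gaussian")
    cfg = SamplerConfig(chains=2, iterations=1200, seed=3, store_person_draws=True)
    return fit_model(small_gauss_data, spec, cfg)


@pytest.fixture(scope="session")
def heavy_tail_data():
    """Data with Student-t (nu ~ 3.2) residuals at the reference t values."""
    params = default_growth_params("student_t")
    eff = draw_person_effects(params, 120, seed=21)
    return simulate_scores(eff, params, 8, seed=22)


def make_params(**overrides) -> GrowthParams:
    base = dict(
        mu_b0=-13.98, mu_b1=4.52, sd_b0=34.10, sd_b1=2.79, rho=-0.55,
        sigma=21.90, family="gaussian",
    )
    base.update(overrides)
    return GrowthParams(**base)
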