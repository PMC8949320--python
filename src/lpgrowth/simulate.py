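"""Synthetic data generation for learning-progress assessment analyses.

Two levels of data are generated:

* score level — long tables ``(person_id, timepoint, y)`` following the linear
  latent growth model with Gaussian, Student-t or asymmetric-Laplace residuals;
* item level — raw responses ``(person_id, timepoint, subscale, item_id,
  correct, rt_ms)`` that exercise the response-time filtering and CISRT
  scoring chain, including configurable fractions of fast-guess and
  overly-slow contaminant responses.

Everything is driven by a single integer seed, split deterministically per
stream, so identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import GrowthParams, ParameterError, default_growth_params

SUBSCALES = ("word", "sentence", "text")


def draw_person_effects(
    params: GrowthParams, n: int, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw person intercepts and slopes from the bivariate normal latent
    distribution MVN((mu_b0, mu_b1), Sigma).

    Returns a DataFrame with columns ``person_id, b0, b1``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    # method="svd" handles the degenerate sd=0 cases exactly
    eff = rng.multivariate_normal(params.latent_mean, params.latent_cov, size=n, method="svd")
    return pd.DataFrame({"person_id": np.arange(n), "b0": eff[:, 0], "b1": eff[:, 1]})


def rald(
    n: int, mu: float = 0.0, sigma: float = 1.0, p: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw from the asymmetric Laplace distribution ALD(mu, sigma, p).

    Density: ``p(1-p)/sigma * exp(-rho_p((y-mu)/sigma))`` with the check
    function ``rho_p(u) = u * (p - 1{u<0})``.  Sampling inverts the
    closed-form CDF, which is exponential on each side of ``mu``.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if not 0.0 < p < 1.0:
        raise ParameterError("p must lie in (0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    u = rng.uniform(size=n)
    below = u < p
    out = np.empty(n)
    out[below] = mu + sigma / (1.0 - p) * np.log(u[below] / p)
    out[~below] = mu - sigma / p * np.log((1.0 - u[~below]) / (1.0 - p))
    return out


def _residuals(params: GrowthParams, size: int, rng: np.random.Generator) -> np.ndarray:
    if params.family == "gaussian":
        return rng.normal(0.0, params.sigma, size=size)
    if params.family == "student_t":
        return params.sigma * stats.t.rvs(params.nu, size=size, random_state=rng)
    if params.family == "asym_laplace":
        return rald(size, 0.0, params.sigma, params.p, seed=rng)
    raise ParameterError(f"unknown family {params.family!r}")


def simulate_scores(
    effects: pd.DataFrame,
    params: GrowthParams,
    n_timepoints: int = 8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate the long score table ``y_pt = b0_p + b1_p * X_t + e_pt``.

    Timepoints are coded 0..T-1, so the intercept is the initial level and the
    slope the average progress per assessment interval.  Residuals come from
    the family named in ``params``.  The table is complete (no missing cells).
    """
    if n_timepoints < 2:
        raise ParameterError("need at least 2 timepoints")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    t = np.arange(n_timepoints, dtype=float)
    b0 = effects["b0"].to_numpy()[:, None]
    b1 = effects["b1"].to_numpy()[:, None]
    eta = b0 + b1 * t  # (n_persons, T)
    e = _residuals(params, eta.size, rng).reshape(eta.shape)
    y = eta + e
    n = len(effects)
    return pd.DataFrame(
        {
            "person_id": np.repeat(effects["person_id"].to_numpy(), n_timepoints),
            "timepoint": np.tile(np.arange(n_timepoints), n),
            "y": y.ravel(),
        }
    )


def simulate_dataset(
    family: str = "gaussian",
    n: int = 4970,
    n_timepoints: int = 8,
    seed: int = 0,
    params: GrowthParams | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: effects + scores under the reference conditions
    (defaults mirror the study design: N = 4970 persons, T = 8 timepoints)."""
    params = default_growth_params(family) if params is None else params
    rng_eff, rng_res = np.random.SeedSequence(seed).spawn(2)
    eff = draw_person_effects(params, n, np.random.default_rng(rng_eff))
    return simulate_scores(eff, params, n_timepoints, np.random.default_rng(rng_res))


@dataclass(frozen=True)
class ItemDesign:
    """Design of the item-level generator.

    The clean response-time distribution per subscale is a truncated
    log-normal inside ``(clean_low_ms, clean_high_ms)``; fast guesses fall
    below ``clean_low_ms``, overly slow responses above ``clean_high_ms``.
    Correctness is Bernoulli with a logistic link on the person's
    standardized current latent level.
    """

    items_per_subscale: dict = field(
        default_factory=lambda: {"word": 10, "sentence": 10, "text": 10}
    )
    rt_log_mean: dict = field(
        default_factory=lambda: {"word": 8.8, "sentence": 9.1, "text": 9.4}
    )
    rt_log_sd: dict = field(
        default_factory=lambda: {"word": 0.45, "sentence": 0.45, "text": 0.50}
    )
    clean_low_ms: dict = field(
        default_factory=lambda: {"word": 1500.0, "sentence": 1600.0, "text": 1000.0}
    )
    clean_high_ms: dict = field(
        default_factory=lambda: {"word": 40000.0, "sentence": 52000.0, "text": 84000.0}
    )
    discrimination: float = 1.7
    difficulty: dict = field(
        default_factory=lambda: {"word": -1.0, "sentence": -0.8, "text": -0.6}
    )
    speed_loading: float = -0.25  # effect of latent level on log response time
    guess_accuracy: float = 0.25  # accuracy of a fast guess
    fast_rate: float = 0.05
    slow_rate: float = 0.005


def simulate_item_responses(
    effects: pd.DataFrame,
    params: GrowthParams,
    design: ItemDesign | None = None,
    n_timepoints: int = 8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate item-level responses for the scoring chain.

    Per item the probability of a correct response increases with the
    person's current latent level ``eta_pt``; response times are log-normal,
    truncated to the clean support, and a stated fraction of responses is
    replaced by fast guesses (below the clean support, random accuracy) or
    overly slow responses (above the clean support).
    """
    design = ItemDesign() if design is None else design
    if not design.items_per_subscale:
        raise ParameterError("empty item design")
    if not (0 <= design.fast_rate < 1 and 0 <= design.slow_rate < 1):
        raise ParameterError("contamination rates must lie in [0, 1)")
    if design.fast_rate + design.slow_rate >= 1:
        raise ParameterError("contamination rates must sum to < 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed

    t = np.arange(n_timepoints, dtype=float)
    b0 = effects["b0"].to_numpy()[:, None]
    b1 = effects["b1"].to_numpy()[:, None]
    eta = b0 + b1 * t
    # standardize against the population trajectory spread so defaults are
    # insensitive to the score scale
    sd_ref = np.sqrt(params.sd_b0**2 + params.sigma**2)
    z = (eta - (params.mu_b0 + params.mu_b1 * t)) / sd_ref  # (n, T)

    frames = []
    n = len(effects)
    for subscale in design.items_per_subscale:
        k = design.items_per_subscale[subscale]
        if k < 1:
            raise ParameterError(f"subscale {subscale!r} has no items")
        zz = np.repeat(z[:, :, None], k, axis=2)  # (n, T, k)
        p_correct = 1.0 / (1.0 + np.exp(-(design.discrimination * zz - design.difficulty[subscale])))
        correct = rng.uniform(size=zz.shape) < p_correct

        log_rt = rng.normal(
            design.rt_log_mean[subscale] + design.speed_loading * zz,
            design.rt_log_sd[subscale],
        )
        rt = np.exp(log_rt)
        lo, hi = design.clean_low_ms[subscale], design.clean_high_ms[subscale]
        rt = np.clip(rt, lo * 1.001, hi * 0.999)

        u = rng.uniform(size=zz.shape)
        fast = u < design.fast_rate
        slow = (u >= design.fast_rate) & (u < design.fast_rate + design.slow_rate)
        rt[fast] = rng.uniform(200.0, lo * 0.95, size=int(fast.sum()))
        rt[slow] = hi * rng.uniform(1.05, 3.0, size=int(slow.sum()))
        correct[fast] = rng.uniform(size=int(fast.sum())) < design.guess_accuracy

        pid = effects["person_id"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(pid, n_timepoints * k),
                    "timepoint": np.tile(np.repeat(np.arange(n_timepoints), k), n),
                    "subscale": subscale,
                    "item_id": np.tile(np.arange(k), n * n_timepoints),
                    "correct": correct.ravel().astype(int),
                    "rt_ms": rt.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["person_id", "timepoint", "subscale", "item_id"], ignore_index=True)
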