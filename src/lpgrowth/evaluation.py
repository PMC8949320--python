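"""Model comparison and post-fit analyses.

Implements the predictive-accuracy workflow used to compare the three
growth-model families:

* pointwise log-likelihood matrices (conditional on each draw's person
  effects, the convention under which reported ELPD differences between
  Gaussian and robust fits are large);
* PSIS-LOO — approximate leave-one-out cross-validation by Pareto-smoothed
  importance sampling, with generalized-Pareto tail smoothing and the
  expected log pointwise predictive density (ELPD) as the accuracy metric;
* pairwise model comparison with pointwise ELPD-difference standard errors;
* posterior predictive replication (conditional: each rep keeps its draw's
  person effects) with range/quartile and kernel-density summaries;
* person-level EAP estimates, their posterior SDs, relative measurement
  precision, and cross-model correlations of person estimates;
* exact leave-one-observation-out refits (the brute-force oracle against
  which PSIS-LOO is validated on small problems).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .families import family_loglik
from .gibbs import EstimationError, PosteriorDraws, _scores_to_matrix, fit_model
from .params import GrowthModelSpec, ParameterError, SamplerConfig
from .simulate import rald

PARETO_K_BANDS = ((0.5, "good"), (0.7, "ok"), (1.0, "bad"), (np.inf, "very bad"))


# ---------------------------------------------------------------------------
# pointwise log-likelihood


def _aligned_population_draws(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Population draws subsampled to align with stored person draws."""
    thin = draws.config.person_thin
    out = {}
    for k, v in draws.draws.items():
        kept = v[:, ::thin]
        out[k] = kept.reshape(-1)
    return out


def pointwise_loglik(
    draws: PosteriorDraws, data: pd.DataFrame, marginal: bool = False
) -> np.ndarray:
    """Log density of every observation under every posterior draw.

    Returns an (n_obs, n_draws) matrix, observations ordered person-major
    (person 0: t=0..T-1, person 1: ...).  By default the density is
    CONDITIONAL on the draw's person effects (b0_p, b1_p); with
    ``marginal=True`` (Gaussian family only) person effects are integrated
    out analytically per cell.
    """
    person_ids, y = _scores_to_matrix(data)
    if not np.array_equal(person_ids, draws.person_ids):
        raise EstimationError("data persons do not match the fitted model")
    t = draws.spec.time_codes
    if marginal:
        if draws.family != "gaussian":
            raise NotImplementedError("marginal pointwise likelihood: gaussian family only")
        pop = {k: v.reshape(-1) for k, v in draws.draws.items()}
        n_draws = pop["sigma"].size
        out = np.empty((y.size, n_draws))
        for s in range(n_draws):
            eta = pop["mu_b0"][s] + pop["mu_b1"][s] * t
            var = (
                pop["sd_b0"][s] ** 2
                + (t**2) * pop["sd_b1"][s] ** 2
                + 2 * t * pop["rho"][s] * pop["sd_b0"][s] * pop["sd_b1"][s]
                + pop["sigma"][s] ** 2
            )
            out[:, s] = np.broadcast_to(
                family_loglik("gaussian", y, eta, np.sqrt(var)), y.shape
            ).ravel()
        return out

    person = draws.stacked_person()  # (n_draws, n, 2)
    pop = _aligned_population_draws(draws)
    n_draws = person.shape[0]
    out = np.empty((y.size, n_draws))
    for s in range(n_draws):
        eta = person[s, :, :1] + person[s, :, 1:] * t
        ll = family_loglik(
            draws.family, y, eta, pop["sigma"][s],
            pop.get("nu", np.full(n_draws, np.nan))[s] if draws.family == "student_t" else None,
            draws.spec.p,
        )
        out[:, s] = ll.ravel()
    return out


# ---------------------------------------------------------------------------
# PSIS


def _gpdfit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to sorted exceedances by the
    quantile-profile posterior-mean method (weakly regularized)."""
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m_est = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m_est / (np.arange(1, m_est + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.mean(np.log1p(-b[:, None] * x), axis=1)
    len_scale = n * (np.log(-(b / k)) - k - 1.0)
    weights = 1.0 / np.exp(len_scale - len_scale[:, None]).sum(axis=1)
    keep = weights >= 10 * np.finfo(float).eps
    weights, b = weights[keep], b[keep]
    weights /= weights.sum()
    b_post = np.sum(b * weights)
    k_post = np.mean(np.log1p(-b_post * x))
    # scale from the unregularized k; then weakly shrink k toward 1/2
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return float(k_post), float(sigma)


def _gpinv(probs: np.ndarray, kappa: float, sigma: float) -> np.ndarray:
    """Generalized-Pareto quantile function."""
    x = np.full_like(probs, np.nan)
    if sigma <= 0:
        return x
    ok = (probs > 0) & (probs < 1)
    if np.abs(kappa) < np.finfo(float).eps:
        x[ok] = -np.log1p(-probs[ok])
    else:
        x[ok] = np.expm1(-kappa * np.log1p(-probs[ok])) / kappa
    x *= sigma
    x[probs == 0] = 0.0
    x[probs == 1] = np.inf if kappa >= 0 else -sigma / kappa
    return x


def psislw(log_ratios: np.ndarray, tail_frac: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Pareto-smoothed importance sampling.

    ``log_ratios`` is (n_obs, n_draws).  Per observation the largest
    ``tail_frac`` of the ratios (at least 5) is replaced by expected order
    statistics of a generalized Pareto fitted to the tail, then weights are
    truncated at the raw maximum and self-normalized.  Returns the
    normalized log weights and the Pareto shape k per observation.
    """
    lw = np.array(log_ratios, float)
    n_obs, n_draws = lw.shape
    tail = max(int(np.ceil(tail_frac * n_draws)), 5)
    khat = np.empty(n_obs)
    cutoff_min = np.log(np.finfo(float).tiny)
    for i in range(n_obs):
        x = lw[i] - lw[i].max()
        cutoff = max(np.sort(x)[-tail - 1], cutoff_min)
        tail_idx = np.flatnonzero(x > cutoff)
        if tail_idx.size <= 4:
            khat[i] = np.inf
        else:
            order = np.argsort(x[tail_idx])
            exc = np.exp(x[tail_idx][order]) - np.exp(cutoff)
            k, sigma = _gpdfit(exc)
            khat[i] = k
            if np.isfinite(k):
                probs = (np.arange(tail_idx.size) + 0.5) / tail_idx.size
                smoothed = _gpinv(probs, k, sigma)
                x[tail_idx[order]] = np.log(smoothed + np.exp(cutoff))
        x = np.minimum(x, 0.0)  # truncate at the raw maximum
        lw[i] = x - logsumexp(x)
    return lw, khat


@dataclass
class LooResult:
    """PSIS-LOO estimate of expected log pointwise predictive density."""

    elpd_pointwise: np.ndarray
    pareto_k: np.ndarray
    elpd_loo: float
    se: float
    model: str = ""

    @property
    def n_obs(self) -> int:
        return self.elpd_pointwise.size

    def k_summary(self) -> dict[str, int]:
        """Counts of observations per Pareto-k quality band."""
        out, prev = {}, -np.inf
        for bound, label in PARETO_K_BANDS:
            out[label] = int(np.sum((self.pareto_k > prev) & (self.pareto_k <= bound)))
            prev = bound
        return out


def psis_loo(loglik: np.ndarray, model: str = "") -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood matrix (n_obs, n_draws).

    Importance ratios are the inverse pointwise likelihoods; the ELPD per
    observation is the smoothed-weight average of its predictive density,
    and the total's standard error is ``sqrt(n * var(pointwise))``.
    """
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ParameterError("need an (n_obs, n_draws) matrix")
    if ll.shape[1] < 100:
        raise ParameterError("need at least 100 draws for stable PSIS")
    if np.ptp(ll, axis=1).max() == 0:
        # degenerate: all draws identical; weights are uniform
        pointwise = ll[:, 0]
        khat = np.zeros(ll.shape[0])
    else:
        lw, khat = psislw(-ll)
        pointwise = logsumexp(ll + lw, axis=1)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(ll.shape[0] * np.var(pointwise, ddof=1)))
    return LooResult(pointwise, khat, elpd, se, model=model)


def loo(draws: PosteriorDraws, data: pd.DataFrame, model: str | None = None) -> LooResult:
    """Convenience: pointwise conditional log-likelihood then PSIS-LOO."""
    return psis_loo(pointwise_loglik(draws, data), model=model or draws.family)


@dataclass
class LooComparison:
    """Pairwise ELPD differences against the best model."""

    table: pd.DataFrame  # index: model; columns: elpd_loo, se, elpd_diff, diff_se

    @property
    def best(self) -> str:
        return str(self.table.index[0])


def compare_models(loos: list[LooResult] | dict[str, LooResult]) -> LooComparison:
    """Rank models by ELPD and compute pointwise ELPD differences.

    The standard error of each difference is ``sqrt(n * var(pointwise
    differences))``; the best model's row is exactly 0.00 / 0.00.
    """
    if isinstance(loos, dict):
        items = [(k, v) for k, v in loos.items()]
    else:
        items = [(l.model or f"model{i}", l) for i, l in enumerate(loos)]
    if len(items) < 2:
        raise ParameterError("need at least two models to compare")
    n = items[0][1].n_obs
    if any(l.n_obs != n for _, l in items):
        raise EstimationError("models were evaluated on different observation sets")
    items = sorted(items, key=lambda kv: kv[1].elpd_loo, reverse=True)
    best = items[0][1]
    rows = []
    for name, l in items:
        diff_pt = l.elpd_pointwise - best.elpd_pointwise
        diff = float(diff_pt.sum())
        diff_se = float(np.sqrt(n * np.var(diff_pt, ddof=1))) if l is not best else 0.0
        if l is best:
            diff = 0.0
        rows.append(
            {"model": name, "elpd_loo": l.elpd_loo, "se": l.se,
             "elpd_diff": diff, "diff_se": diff_se}
        )
    return LooComparison(pd.DataFrame(rows).set_index("model"))


def exact_loo(
    data: pd.DataFrame, spec: GrowthModelSpec, config: SamplerConfig
) -> np.ndarray:
    """Brute-force exact leave-one-observation-out ELPD.

    Refits the model once per held-out cell (likelihood masked) and scores
    the held-out observation by the log posterior-mean predictive density,
    conditional on person effects — feasible only for tiny problems.
    Observations are ordered person-major as in ``pointwise_loglik``.
    """
    person_ids, y = _scores_to_matrix(data)
    n, T = y.shape
    t = spec.time_codes
    cfg = SamplerConfig(
        chains=config.chains, iterations=config.iterations, warmup=config.warmup,
        seed=config.seed, store_person_draws=True,
    )
    out = np.empty(n * T)
    for i in range(n * T):
        p_i, t_i = divmod(i, T)
        mask = np.ones_like(y, bool)
        mask[p_i, t_i] = False
        fit = fit_model(data, spec, cfg, obs_mask=mask)
        person = fit.stacked_person()
        pop = _aligned_population_draws(fit)
        eta_i = person[:, p_i, 0] + person[:, p_i, 1] * t[t_i]
        ll = family_loglik(
            fit.family, y[p_i, t_i], eta_i, pop["sigma"],
            pop.get("nu"), spec.p,
        )
        out[i] = logsumexp(ll) - np.log(ll.size)
    return out


# ---------------------------------------------------------------------------
# posterior predictive checking


def posterior_predictive(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_reps: int = 10,
    seed: int = 0,
    grid_size: int = 200,
) -> dict:
    """Replicate the dataset under ``n_reps`` retained posterior draws.

    Conditional replication: each rep keeps its draw's person effects and
    redraws only the residuals from the fitted family.  Returns five-number
    summaries and kernel-density curves (normal-reference bandwidth) for the
    observed data and each replicate.
    """
    person = draws.stacked_person()
    n_draws = person.shape[0]
    if n_reps > n_draws:
        raise ParameterError(f"n_reps={n_reps} exceeds the {n_draws} stored draws")
    _, y = _scores_to_matrix(data)
    t = draws.spec.time_codes
    pop = _aligned_population_draws(draws)
    rng = np.random.default_rng(seed)
    pick = np.linspace(0, n_draws - 1, n_reps).astype(int)

    lo, hi = y.min(), y.max()
    span = max(hi - lo, 1e-12)
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, grid_size)

    def _summarize(v: np.ndarray) -> dict:
        q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}

    def _kde(v: np.ndarray) -> np.ndarray:
        if np.ptp(v) == 0:
            out = np.zeros_like(grid)
            out[np.argmin(np.abs(grid - v[0]))] = 1.0
            return out
        return stats.gaussian_kde(v, bw_method="silverman")(grid)

    reps, summaries, kdes = [], [], []
    for s in pick:
        eta = person[s, :, :1] + person[s, :, 1:] * t
        sig = pop["sigma"][s]
        if draws.family == "gaussian":
            e = rng.normal(0.0, sig, size=eta.shape)
        elif draws.family == "student_t":
            e = sig * stats.t.rvs(pop["nu"][s], size=eta.shape, random_state=rng)
        else:
            e = rald(eta.size, 0.0, sig, draws.spec.p, seed=rng).reshape(eta.shape)
        rep = (eta + e).ravel()
        reps.append(rep)
        summaries.append(_summarize(rep))
        kdes.append(_kde(rep))

    return {
        "grid": grid,
        "observed": {"summary": _summarize(y.ravel()), "kde": _kde(y.ravel())},
        "replicates": reps,
        "rep_summaries": pd.DataFrame(summaries),
        "rep_kdes": np.asarray(kdes),
        "draw_indices": pick,
    }


def model_density_curve(
    family: str,
    loc: float,
    scale: float,
    grid: np.ndarray,
    nu: float | None = None,
    p: float = 0.5,
) -> np.ndarray:
    """Family density on a grid at given (location, scale[, extra]) — used to
    overlay the fitted response distributions at the first timepoint of an
    average person."""
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or grid.size < 2:
        raise ParameterError("grid must be a 1-D array with >= 2 points")
    return np.exp(family_loglik(family, grid, loc, scale, nu, p))


# ---------------------------------------------------------------------------
# person-level estimates


def eap_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Person-level EAP (posterior-mean) intercepts and slopes with posterior
    SDs and relative measurement precision.

    Relative precision divides each person's posterior SD by the estimated
    SD of the respective latent variable distribution (posterior mean of
    sd_b0 or sd_b1); smaller is more precise.
    """
    person = draws.stacked_person()
    pop = _aligned_population_draws(draws)
    eap = person.mean(axis=0)
    sd = person.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "person_id": draws.person_ids,
            "eap_b0": eap[:, 0],
            "eap_b1": eap[:, 1],
            "sd_b0": sd[:, 0],
            "sd_b1": sd[:, 1],
            "relprec_b0": sd[:, 0] / pop["sd_b0"].mean(),
            "relprec_b1": sd[:, 1] / pop["sd_b1"].mean(),
        }
    )


def cross_model_correlation(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Product-moment correlations of person estimates between two fits."""
    merged = a.merge(b, on="person_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise EstimationError("need at least 3 shared persons")
    return {
        "r_b0": float(np.corrcoef(merged["eap_b0_a"], merged["eap_b0_b"])[0, 1]),
        "r_b1": float(np.corrcoef(merged["eap_b1_a"], merged["eap_b1_b"])[0, 1]),
    }
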