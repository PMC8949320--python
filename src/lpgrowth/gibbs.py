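"""Posterior sampling for the linear latent growth models.

A vectorized data-augmentation Gibbs sampler owns the full posterior of all
three response families:

* Gaussian — conjugate person-effect and mean updates; the residual scale is
  updated by independence Metropolis-Hastings with an inverse-gamma proposal
  matched to the conditional likelihood (the half-t prior enters only through
  the acceptance ratio, which is near 1).
* Student-t — Gaussian scale-mixture augmentation: per-observation mixing
  precisions ``w ~ Gamma(nu/2, nu/2)``; the degrees of freedom move by a
  Metropolis step on ``log nu`` targeting the *marginal* t likelihood (the
  mixing weights integrated out), which avoids the slow nu-w coupling.
* asymmetric Laplace — the exponential mean-variance mixture of Bayesian
  quantile regression: ``y = eta + theta*z + sqrt(tau2*sigma*z)*u`` with
  ``z ~ Exp(mean sigma)``, ``theta = (1-2p)/(p(1-p))``, ``tau2 = 2/(p(1-p))``;
  ``1/z`` has an inverse-Gaussian full conditional.

The latent covariance (two SDs and a correlation, half-t and LKJ priors) is
updated by independence MH with an inverse-Wishart proposal whose kernel
equals the conditional likelihood; the intercept-mean Student-t prior is
handled by a further Gamma scale-mixture augmentation, keeping that update
conjugate.  Convergence is summarized with rank-normalized split R-hat and
bulk/tail ESS; the fit report flags R-hat >= 1.01 or ESS <= 400.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from . import diagnostics as dg
from .families import family_loglik, loglik_student_t
from .params import (
    GrowthModelSpec,
    GrowthParams,
    ParameterError,
    SamplerConfig,
)


class EstimationError(RuntimeError):
    """Raised when the data cannot support estimation."""


POPULATION_PARAMS = ("mu_b0", "mu_b1", "sd_b0", "sd_b1", "rho", "sigma", "nu")


@dataclass
class PosteriorDraws:
    """Post-warmup draws and diagnostics of one model fit."""

    family: str
    draws: dict[str, np.ndarray]  # name -> (chains, kept)
    person_draws: np.ndarray | None  # (chains, kept/thin, n_persons, 2)
    person_ids: np.ndarray
    spec: GrowthModelSpec
    config: SamplerConfig
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)

    def stacked_person(self) -> np.ndarray:
        """Person-effect draws with chains concatenated: (draws, n, 2)."""
        if self.person_draws is None:
            raise EstimationError("fit was run without store_person_draws")
        c, k, n, _ = self.person_draws.shape
        return self.person_draws.reshape(c * k, n, 2)

    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs, central 95% credible intervals (posterior
        quantiles) and convergence diagnostics per population parameter."""
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            diag = self.diagnostics.get(name, {})
            rows.append(
                {
                    "param": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "ci_2.5%": np.quantile(flat, 0.025),
                    "ci_97.5%": np.quantile(flat, 0.975),
                    "rhat": diag.get("rhat", np.nan),
                    "ess_bulk": diag.get("ess_bulk", np.nan),
                    "ess_tail": diag.get("ess_tail", np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def converged(self, rhat_max: float = 1.01, ess_min: float = 400.0) -> bool:
        """True when every monitored parameter satisfies the thresholds."""
        return not self.flagged_params(rhat_max, ess_min)

    def flagged_params(self, rhat_max: float = 1.01, ess_min: float = 400.0) -> list[str]:
        bad = []
        for name, diag in self.diagnostics.items():
            if not (diag["rhat"] < rhat_max) or diag["ess_bulk"] <= ess_min or diag["ess_tail"] <= ess_min:
                bad.append(name)
        return bad

    def mean_params(self) -> GrowthParams:
        """Posterior means packed as a GrowthParams (plug-in estimate)."""
        m = {k: float(self.stacked(k).mean()) for k in self.draws}
        return GrowthParams(
            mu_b0=m["mu_b0"], mu_b1=m["mu_b1"], sd_b0=m["sd_b0"], sd_b1=m["sd_b1"],
            rho=m["rho"], sigma=m["sigma"], family=self.family,
            nu=m.get("nu"), p=self.spec.p if self.family == "asym_laplace" else None,
        )


# ---------------------------------------------------------------------------
# helpers


def _scores_to_matrix(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Validate the long table and return (person_ids, (N, T) matrix)."""
    wide = data.pivot(index="person_id", columns="timepoint", values="y")
    t_seen = np.asarray(sorted(wide.columns))
    if not np.array_equal(t_seen, np.arange(len(t_seen))):
        raise EstimationError("timepoints must be coded 0..T-1 without gaps")
    if wide.isna().any().any():
        raise EstimationError("score table must be complete (no missing cells)")
    wide = wide.sort_index(axis=1)
    return np.asarray(wide.index), wide.to_numpy(float)


def _log_half_t(x: float, scale: float, df: float) -> float:
    return float(-0.5 * (df + 1.0) * np.log1p(x * x / (df * scale * scale)))


def _sample_mvn2(mean: np.ndarray, prec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(mean, prec^-1) for a single 2x2 precision."""
    cov = np.linalg.inv(prec)
    l = np.linalg.cholesky(cov)
    return mean + l @ rng.standard_normal(2)


def _invgauss_rvs(mean: np.ndarray, shape: float | np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-Gaussian sampler (Michael-Schucany-Haas)."""
    nu2 = rng.standard_normal(mean.shape) ** 2
    x = mean + mean**2 * nu2 / (2.0 * shape) - mean / (2.0 * shape) * np.sqrt(
        4.0 * mean * shape * nu2 + (mean * nu2) ** 2
    )
    x = np.maximum(x, 1e-300)
    take_x = rng.uniform(size=mean.shape) <= mean / (mean + x)
    with np.errstate(over="ignore"):
        alt = np.minimum(mean**2 / x, 1e300)
    return np.where(take_x, x, alt)


# ---------------------------------------------------------------------------
# the sampler


def fit_model(
    data: pd.DataFrame,
    spec: GrowthModelSpec,
    config: SamplerConfig,
    fixed: dict[str, Any] | None = None,
    obs_mask: np.ndarray | None = None,
) -> PosteriorDraws:
    """Sample from the joint posterior of the growth model on a long score
    table ``(person_id, timepoint, y)``.

    ``fixed`` may hold any of ``mu`` (length-2), ``Sigma`` (2x2), ``sigma``,
    ``nu`` to freeze a block at a known value (used in conjugate validation
    studies); frozen blocks are skipped by the sampler.  ``obs_mask`` is an
    optional boolean (n_persons, T) array; False cells are excluded from the
    likelihood (used for exact leave-one-observation-out refits).
    """
    fixed = {} if fixed is None else fixed
    person_ids, y = _scores_to_matrix(data)
    n, T = y.shape
    if T != spec.n_timepoints:
        spec = GrowthModelSpec(
            family=spec.family, p=spec.p, priors=spec.priors, n_timepoints=T
        )
    if n < 5:
        raise EstimationError("need at least 5 persons to estimate the latent covariance")
    if np.std(y) == 0:
        raise EstimationError("scores are constant; growth model is degenerate")

    if obs_mask is None:
        obs_mask = np.ones_like(y, bool)
    else:
        obs_mask = np.asarray(obs_mask, bool)
        if obs_mask.shape != y.shape:
            raise EstimationError("obs_mask shape must match the score matrix")
        if (obs_mask.sum(axis=1) < 1).any():
            raise EstimationError("every person needs at least one observed cell")
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [
        _run_chain(y, spec, config, fixed, np.random.default_rng(s), obs_mask)
        for s in seeds
    ]

    names = list(chains[0]["draws"].keys())
    draws = {k: np.stack([c["draws"][k] for c in chains]) for k in names}
    person = (
        np.stack([c["person"] for c in chains]) if config.store_person_draws else None
    )
    accept = {
        k: float(np.mean([c["accept"][k] for c in chains]))
        for k in chains[0]["accept"]
    }
    out = PosteriorDraws(
        family=spec.family,
        draws=draws,
        person_draws=person,
        person_ids=person_ids,
        spec=spec,
        config=config,
        accept_rates=accept,
    )
    monitored = {k: v for k, v in draws.items() if np.ptp(v) > 0}
    if config.chains >= 2:
        out.diagnostics = dg.rhat_ess_summary(monitored)
    return out


def _run_chain(
    y: np.ndarray,
    spec: GrowthModelSpec,
    config: SamplerConfig,
    fixed: dict[str, Any],
    rng: np.random.Generator,
    obs_mask: np.ndarray,
) -> dict:
    n, T = y.shape
    t = spec.time_codes
    family = spec.family
    priors = spec.priors
    mask = obs_mask.astype(float)
    n_obs = int(obs_mask.sum())

    # --- initial values: per-person least squares, jittered per chain
    st, stt = t.sum(), (t * t).sum()
    det_x = T * stt - st * st
    sy = y.sum(axis=1)
    sty = y @ t
    b = np.empty((n, 2))
    b[:, 0] = (stt * sy - st * sty) / det_x
    b[:, 1] = (T * sty - st * sy) / det_x
    b += rng.normal(scale=0.1 * max(np.std(b), 1e-3), size=b.shape)

    mu = np.asarray(fixed.get("mu", b.mean(axis=0)), float)
    cov_b = np.cov(b, rowvar=False) + np.eye(2) * 1e-6
    sigma_mat = np.asarray(fixed.get("Sigma", cov_b), float)

    # floor the residual-scale start: with T = 2 the per-person least-squares
    # line interpolates the data and the raw residual SD collapses to zero
    resid_sd = max(float(np.std(y - (b[:, :1] + b[:, 1:] * t))), 0.1 * float(np.std(y)))
    if family == "asym_laplace":
        p = spec.p
        theta_a = (1.0 - 2.0 * p) / (p * (1.0 - p))
        tau2 = 2.0 / (p * (1.0 - p))
        var_factor = (1.0 - 2.0 * p + 2.0 * p * p) / (p * p * (1.0 - p) ** 2)
        sigma = float(fixed.get("sigma", resid_sd / np.sqrt(var_factor)))
        z = np.full((n, T), sigma)
    else:
        sigma = float(fixed.get("sigma", resid_sd))
        z = None
    nu = float(fixed.get("nu", 5.0 * np.exp(rng.normal(scale=0.2)))) if family == "student_t" else None
    w = np.ones((n, T)) if family == "student_t" else None
    g_mu = 1.0  # scale-mixture weight of the intercept-mean t prior

    nu_step = 0.25
    accept_counts = {"sigma": 0, "Sigma": 0, "Sigma_nc": 0, "nu": 0}
    total = {"sigma": 0, "Sigma": 0, "Sigma_nc": 0, "nu": 0}

    warmup: int = config.warmup  # type: ignore[assignment]
    kept = config.iterations - warmup
    out = {k: np.empty(kept) for k in ("mu_b0", "mu_b1", "sd_b0", "sd_b1", "rho", "sigma")}
    if family == "student_t":
        out["nu"] = np.empty(kept)
    person_kept = (kept + config.person_thin - 1) // config.person_thin
    person = (
        np.empty((person_kept, n, 2)) if config.store_person_draws else None
    )

    sd_pr, sig_pr = priors.sd_prior, priors.sigma_prior
    mu_pr = priors.intercept_mean_prior

    for it in range(config.iterations):
        eta = b[:, :1] + b[:, 1:] * t

        # --- family-specific augmentation (and nu)
        if family == "student_t":
            r = y - eta
            if "nu" not in fixed:
                # marginal MH on log(nu), mixing weights integrated out
                lp_cur = float(np.sum(mask * loglik_student_t(r, 0.0, sigma, nu)))
                nu_prop = float(np.exp(np.log(nu) + rng.normal(scale=nu_step)))
                total["nu"] += 1
                if nu_prop > priors.nu_prior.lower:
                    lp_prop = float(np.sum(mask * loglik_student_t(r, 0.0, sigma, nu_prop)))
                    npr = priors.nu_prior
                    log_r = (
                        lp_prop - lp_cur
                        + (npr.shape * np.log(nu_prop) - npr.rate * nu_prop)
                        - (npr.shape * np.log(nu) - npr.rate * nu)
                    )  # includes the log-scale Jacobian via shape* (shape-1+1)
                    if np.log(rng.uniform()) < log_r:
                        nu = nu_prop
                        accept_counts["nu"] += 1
                if it < warmup:  # Robbins-Monro toward 44% acceptance
                    rate = accept_counts["nu"] / max(total["nu"], 1)
                    nu_step = float(np.clip(nu_step * np.exp((rate - 0.44) / 10), 1e-3, 2.0))
            w = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + (r / sigma) ** 2))
            prec = mask * w / sigma**2
            y_eff = y
        elif family == "asym_laplace":
            d = y - eta
            absd = np.maximum(np.abs(d), 1e-10 * sigma)
            c2 = theta_a**2 + 2.0 * tau2
            ig_mean = np.sqrt(c2) / absd
            ig_shape = c2 / (tau2 * sigma)
            z = 1.0 / _invgauss_rvs(ig_mean, ig_shape, rng)
            prec = mask / (tau2 * sigma * z)
            y_eff = y - theta_a * z
        else:
            prec = mask / sigma**2
            y_eff = y

        # --- person effects: conjugate bivariate normal, vectorized 2x2
        q = np.linalg.inv(sigma_mat)
        a11 = prec.sum(axis=1) + q[0, 0]
        a12 = prec @ t + q[0, 1]
        a22 = prec @ (t * t) + q[1, 1]
        r1 = (prec * y_eff).sum(axis=1) + q[0, 0] * mu[0] + q[0, 1] * mu[1]
        r2 = (prec * y_eff) @ t + q[0, 1] * mu[0] + q[1, 1] * mu[1]
        det = a11 * a22 - a12 * a12
        m1 = (a22 * r1 - a12 * r2) / det
        m2 = (a11 * r2 - a12 * r1) / det
        # cholesky of the 2x2 covariance inv([[a11,a12],[a12,a22]])
        c11 = a22 / det
        c12 = -a12 / det
        c22 = a11 / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-300))
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        b[:, 0] = m1 + l11 * e1
        b[:, 1] = m2 + l21 * e1 + l22 * e2

        # --- population mean
        if "mu" not in fixed:
            if mu_pr is not None:
                zscore = (mu[0] - mu_pr.loc) / mu_pr.scale
                g_mu = rng.gamma((mu_pr.df + 1.0) / 2.0, 2.0 / (mu_pr.df + zscore**2))
                d_prec = g_mu / mu_pr.scale**2
            else:
                d_prec = 0.0
            q = np.linalg.inv(sigma_mat)
            prec_mu = n * q + np.array([[d_prec, 0.0], [0.0, 0.0]])
            rhs = q @ b.sum(axis=0) + np.array([d_prec * (mu_pr.loc if mu_pr else 0.0), 0.0])
            mu = _sample_mvn2(np.linalg.solve(prec_mu, rhs), prec_mu, rng)

            # non-centered interweave for the mean (ASIS translation move):
            # holding the deviations u = b - mu fixed, mu enters the
            # observation model linearly, so its conditional is Gaussian and
            # independent of the latent-prior shrinkage — this removes the
            # slow mu <-> b random walk under strong shrinkage.
            u_dev = b - mu
            v = y_eff - u_dev[:, :1] - u_dev[:, 1:] * t
            a11 = float(prec.sum())
            a12 = float((prec @ t).sum())
            a22 = float((prec @ (t * t)).sum())
            r1 = float((prec * v).sum())
            r2 = float(((prec * v) @ t).sum())
            prec_mu = np.array([[a11 + d_prec, a12], [a12, a22]])
            rhs = np.array([r1 + d_prec * (mu_pr.loc if mu_pr else 0.0), r2])
            mu = _sample_mvn2(np.linalg.solve(prec_mu, rhs), prec_mu, rng)
            b = u_dev + mu

        # --- latent covariance: independence MH, inverse-Wishart proposal
        if "Sigma" not in fixed:
            diff = b - mu
            s_mat = diff.T @ diff
            total["Sigma"] += 1
            prop = stats.invwishart.rvs(df=n - 3, scale=s_mat, random_state=rng)
            log_r = _log_sigma_prior(prop, sd_pr, priors.lkj_shape) - _log_sigma_prior(
                sigma_mat, sd_pr, priors.lkj_shape
            )
            if np.log(rng.uniform()) < log_r:
                sigma_mat = prop
                accept_counts["Sigma"] += 1

        # --- latent covariance, non-centered interweave (ASIS):
        # with u = L^-1 (b - mu) held fixed, the free elements of the
        # Cholesky factor L enter the observation model linearly, so their
        # conditional is Gaussian; proposing from it and accepting on the
        # induced prior ratio decouples Sigma from the person effects and
        # removes the slow sd_b1 random walk of the centered sampler.
        if "Sigma" not in fixed:
            total["Sigma_nc"] += 1
            l_cur = np.linalg.cholesky(sigma_mat)
            u = np.linalg.solve(l_cur, (b - mu).T).T  # (n, 2)
            v = y_eff - mu[0] - mu[1] * t
            sp0 = prec.sum(axis=1)
            sp1 = prec @ t
            sp2 = prec @ (t * t)
            sv0 = (prec * v).sum(axis=1)
            sv1 = (prec * v) @ t
            u1, u2 = u[:, 0], u[:, 1]
            a_mat = np.array(
                [
                    [np.dot(u1 * u1, sp0), np.dot(u1 * u1, sp1), np.dot(u1 * u2, sp1)],
                    [0.0, np.dot(u1 * u1, sp2), np.dot(u1 * u2, sp2)],
                    [0.0, 0.0, np.dot(u2 * u2, sp2)],
                ]
            )
            a_mat = a_mat + np.triu(a_mat, 1).T
            rhs = np.array([np.dot(u1, sv0), np.dot(u1, sv1), np.dot(u2, sv1)])
            try:
                a_chol = np.linalg.cholesky(a_mat)
            except np.linalg.LinAlgError:
                a_chol = None
            if a_chol is not None:
                mean_l = np.linalg.solve(a_mat, rhs)
                prop_l = mean_l + np.linalg.solve(a_chol.T, rng.standard_normal(3))
                l11, l21, l22 = prop_l
                if l11 > 0 and l22 > 0:
                    l_prop = np.array([[l11, 0.0], [l21, l22]])
                    sigma_prop = l_prop @ l_prop.T
                    # induced prior on L: p_Sigma(LL') * |d Sigma / d L|, the
                    # Jacobian being 4 * l11^2 * l22 for the 2x2 case
                    log_r = (
                        _log_sigma_prior(sigma_prop, sd_pr, priors.lkj_shape)
                        + 2.0 * np.log(l11) + np.log(l22)
                        - _log_sigma_prior(sigma_mat, sd_pr, priors.lkj_shape)
                        - 2.0 * np.log(l_cur[0, 0]) - np.log(l_cur[1, 1])
                    )
                    if np.log(rng.uniform()) < log_r:
                        sigma_mat = sigma_prop
                        b = mu + u @ l_prop.T
                        accept_counts["Sigma_nc"] += 1

        # --- residual scale
        if "sigma" not in fixed:
            eta = b[:, :1] + b[:, 1:] * t
            total["sigma"] += 1
            if family == "asym_laplace":
                d = y - eta - theta_a * z
                a_sum = float(np.sum(mask * (d * d / (2.0 * tau2 * z) + z)))
                prop = a_sum / rng.gamma(1.5 * n_obs - 1.0)
                log_r = _log_half_t(prop, sig_pr.scale, sig_pr.df) - _log_half_t(
                    sigma, sig_pr.scale, sig_pr.df
                )
                if np.log(rng.uniform()) < log_r:
                    sigma = float(prop)
                    accept_counts["sigma"] += 1
            else:
                r = y - eta
                ssq = float(np.sum(mask * (w if family == "student_t" else 1.0) * r * r))
                prop_var = 0.5 * ssq / rng.gamma(0.5 * n_obs - 1.0)
                prop = float(np.sqrt(prop_var))
                log_r = (
                    _log_half_t(prop, sig_pr.scale, sig_pr.df)
                    - np.log(prop)
                    - _log_half_t(sigma, sig_pr.scale, sig_pr.df)
                    + np.log(sigma)
                )
                if np.log(rng.uniform()) < log_r:
                    sigma = prop
                    accept_counts["sigma"] += 1

        # --- store
        if it >= warmup:
            j = it - warmup
            out["mu_b0"][j] = mu[0]
            out["mu_b1"][j] = mu[1]
            out["sd_b0"][j] = np.sqrt(sigma_mat[0, 0])
            out["sd_b1"][j] = np.sqrt(sigma_mat[1, 1])
            out["rho"][j] = sigma_mat[0, 1] / np.sqrt(sigma_mat[0, 0] * sigma_mat[1, 1])
            out["sigma"][j] = sigma
            if family == "student_t":
                out["nu"][j] = nu
            if person is not None and j % config.person_thin == 0:
                person[j // config.person_thin] = b

    accept = {
        k: (accept_counts[k] / total[k] if total[k] else np.nan) for k in accept_counts
    }
    return {"draws": out, "person": person, "accept": accept}


def _log_sigma_prior(sigma_mat: np.ndarray, sd_pr, lkj_shape: float) -> float:
    """Log prior density of the latent covariance, induced on the matrix by
    half-t priors on the SDs and LKJ on the correlation (Jacobian included)."""
    v0, v1, c = sigma_mat[0, 0], sigma_mat[1, 1], sigma_mat[0, 1]
    if v0 <= 0 or v1 <= 0 or v0 * v1 - c * c <= 0:
        return -np.inf
    s0, s1 = np.sqrt(v0), np.sqrt(v1)
    rho = c / (s0 * s1)
    lp = _log_half_t(s0, sd_pr.scale, sd_pr.df) + _log_half_t(s1, sd_pr.scale, sd_pr.df)
    lp += (lkj_shape - 1.0) * np.log1p(-rho * rho)
    lp -= np.log(4.0) + 2.0 * np.log(s0) + 2.0 * np.log(s1)  # d(Sigma)/d(s0,s1,rho)
    return float(lp)
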