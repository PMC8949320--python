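"""Log-densities of the three response families and the joint log-posterior.

The three families share the linear predictor ``eta_pt = b0_p + b1_p * X_t``
and differ only in the residual law:

* Gaussian          ``y ~ N(eta, sigma)``
* Student-t         ``y ~ t(eta, sigma, nu)``       (heavy tails, robust)
* asymmetric Laplace ``y ~ ALD(eta, sigma, p)``     (quantile regression;
  p = 0.5 gives the conditional median)

``sigma`` is a scale parameter throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import GrowthModelSpec, GrowthParams, ParameterError, PriorSet

_LOG_2PI = np.log(2.0 * np.pi)


def loglik_gaussian(y, eta, sigma):
    """Normal log density with mean ``eta`` and scale ``sigma``."""
    if np.any(np.asarray(sigma) <= 0):
        raise ParameterError("sigma must be > 0")
    z = (np.asarray(y, float) - eta) / sigma
    return -0.5 * (_LOG_2PI + z * z) - np.log(sigma)


def loglik_student_t(y, eta, sigma, nu):
    """Location-scale Student-t log density."""
    sigma = np.asarray(sigma, float)
    nu = np.asarray(nu, float)
    if np.any(sigma <= 0) or np.any(nu <= 0):
        raise ParameterError("sigma and nu must be > 0")
    z = (np.asarray(y, float) - eta) / sigma
    return (
        special.gammaln((nu + 1.0) / 2.0)
        - special.gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


def check_function(u, p):
    """Quantile-regression check function rho_p(u) = u * (p - 1{u < 0})."""
    u = np.asarray(u, float)
    return u * (p - (u < 0))


def loglik_ald(y, eta, sigma, p=0.5):
    """Asymmetric-Laplace log density: log[p(1-p)/sigma] - rho_p((y-eta)/sigma)."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ParameterError("sigma must be > 0")
    if not 0.0 < p < 1.0:
        raise ParameterError("p must lie in (0, 1)")
    u = (np.asarray(y, float) - eta) / sigma
    return np.log(p * (1.0 - p)) - np.log(sigma) - check_function(u, p)


def family_loglik(family: str, y, eta, sigma, nu=None, p=0.5):
    """Dispatch on the family name."""
    if family == "gaussian":
        return loglik_gaussian(y, eta, sigma)
    if family == "student_t":
        return loglik_student_t(y, eta, sigma, nu)
    if family == "asym_laplace":
        return loglik_ald(y, eta, sigma, p)
    raise ParameterError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# priors


def _log_student_t_pdf(x, loc, scale, df):
    z = (x - loc) / scale
    return (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def _log_half_t_pdf(x, scale, df):
    # half-t on [0, inf): twice the symmetric t density
    return np.log(2.0) + _log_student_t_pdf(x, 0.0, scale, df)


def _log_gamma_pdf(x, shape, rate):
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - special.gammaln(shape)


def log_prior(params: GrowthParams, priors: PriorSet | None = None) -> float:
    """Joint log prior density of the population parameters (up to a constant).

    Out-of-support values return ``-inf`` rather than raising; the improper
    flat prior on the mean slope contributes zero; LKJ(1) is constant in rho
    for a 2x2 correlation matrix (uniform on (-1, 1)).
    """
    priors = PriorSet() if priors is None else priors
    if (
        params.sd_b0 < 0
        or params.sd_b1 < 0
        or params.sigma <= 0
        or not -1.0 < params.rho < 1.0
    ):
        return -np.inf
    lp = 0.0
    if priors.intercept_mean_prior is not None:
        pr = priors.intercept_mean_prior
        lp += float(_log_student_t_pdf(params.mu_b0, pr.loc, pr.scale, pr.df))
    lp += float(_log_half_t_pdf(params.sd_b0, priors.sd_prior.scale, priors.sd_prior.df))
    lp += float(_log_half_t_pdf(params.sd_b1, priors.sd_prior.scale, priors.sd_prior.df))
    lp += float(_log_half_t_pdf(params.sigma, priors.sigma_prior.scale, priors.sigma_prior.df))
    # LKJ(shape) for a 2x2 correlation matrix: density prop. to (1-rho^2)^(shape-1)
    lp += float((priors.lkj_shape - 1.0) * np.log1p(-params.rho**2))
    if params.family == "student_t":
        npr = priors.nu_prior
        if params.nu is None or params.nu <= npr.lower:
            return -np.inf
        lp += float(_log_gamma_pdf(params.nu, npr.shape, npr.rate))
    return lp


def _log_mvn2(b: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Sum of bivariate-normal log densities for rows of ``b``."""
    diff = b - mean
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 0:
        return -np.inf
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
    quad = np.einsum("ni,ij,nj->n", diff, inv, diff)
    return float(-0.5 * np.sum(quad) - len(b) * (_LOG_2PI + 0.5 * np.log(det)))


def log_posterior(
    y: np.ndarray,
    params: GrowthParams,
    effects: np.ndarray,
    spec: GrowthModelSpec | None = None,
) -> float:
    """Joint log posterior (up to a constant) of the latent growth model.

    Parameters
    ----------
    y : (n_persons, T) array of scores.
    params : population parameters (family taken from here).
    effects : (n_persons, 2) array of person intercepts and slopes.
    spec : model spec supplying priors and the time coding.
    """
    y = np.asarray(y, float)
    effects = np.asarray(effects, float)
    if y.ndim != 2 or effects.shape != (y.shape[0], 2):
        raise ValueError("dimension mismatch between scores and person effects")
    spec = GrowthModelSpec(family=params.family, n_timepoints=y.shape[1]) if spec is None else spec
    if y.shape[1] != spec.n_timepoints:
        raise ValueError("score table does not match the spec's number of timepoints")
    lp = log_prior(params, spec.priors)
    if not np.isfinite(lp):
        return -np.inf
    t = spec.time_codes
    eta = effects[:, :1] + effects[:, 1:] * t
    p = params.p if params.p is not None else spec.p
    ll = family_loglik(params.family, y, eta, params.sigma, params.nu, p)
    lp += float(np.sum(ll))
    lp += _log_mvn2(effects, params.latent_mean, params.latent_cov)
    return lp
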