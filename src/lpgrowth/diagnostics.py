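"""Rank-normalized MCMC convergence diagnostics.

Implements the modern convergence toolkit for multi-chain samplers:

* ``split_rhat`` — rank-normalized split potential-scale-reduction, reported
  as the max of the bulk (rank-normalized) and tail (folded, rank-normalized)
  variants;
* ``ess_bulk`` — effective sample size of the rank-normalized split draws,
  using Geyer's initial positive and monotone sequence estimators on
  chain-averaged autocovariances;
* ``ess_tail`` — the minimum ESS of the 5% and 95% quantile indicator
  variables.

Conventions follow the rank-normalization methodology as implemented in Stan:
chains split in half, average ranks for ties, Blom offset 3/8 for the
normal-scores transform.  For four chains the recommended thresholds are
R-hat < 1.01 and ESS > 400.
"""

from __future__ import annotations

import numpy as np
from scipy import fft, stats

__all__ = ["split_rhat", "ess_bulk", "ess_tail", "rhat_ess_summary"]


def _as_chains(draws: np.ndarray) -> np.ndarray:
    ary = np.asarray(draws, float)
    if ary.ndim == 1:
        ary = ary[None, :]
    if ary.ndim != 2:
        raise ValueError("draws must be a (chains, iterations) array")
    return ary


def _split_chains(ary: np.ndarray) -> np.ndarray:
    """Split each chain in half and stack the halves as separate chains."""
    half = ary.shape[1] // 2
    return np.vstack([ary[:, :half], ary[:, -half:]])


def _z_scale(ary: np.ndarray) -> np.ndarray:
    """Rank-normalize: average ranks over the pooled draws, Blom offset,
    then the standard-normal quantile transform."""
    rank = stats.rankdata(ary, method="average")
    size = rank.size
    c = 3.0 / 8.0
    return stats.norm.ppf((rank - c) / (size - 2 * c + 1)).reshape(ary.shape)


def _basic_rhat(ary: np.ndarray) -> float:
    """Classic split-R-hat on an already split (chains, draws) array."""
    n = ary.shape[1]
    chain_mean = ary.mean(axis=1)
    within = np.mean(np.var(ary, axis=1, ddof=1))
    if within == 0:
        return np.nan
    between = n * np.var(chain_mean, ddof=1)
    return float(np.sqrt((between / within + n - 1.0) / n))


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split potential scale reduction.

    ``draws`` is a (chains, iterations) array with >= 2 chains and >= 4
    draws per chain.  Returns NaN (with zero total variance) rather than
    raising.  Values should be < 1.01 for trustworthy inference.
    """
    ary = _as_chains(draws)
    if ary.shape[0] < 2 or ary.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    split = _split_chains(ary)
    bulk = _basic_rhat(_z_scale(split))
    folded = _basic_rhat(_z_scale(np.abs(split - np.median(split))))
    return max(bulk, folded)


def _autocov(ary: np.ndarray) -> np.ndarray:
    """FFT autocovariance per chain, biased normalization (divide by n)."""
    n = ary.shape[1]
    m = fft.next_fast_len(2 * n)
    centered = ary - ary.mean(axis=1, keepdims=True)
    freq = np.fft.rfft(centered, n=m, axis=1)
    freq *= np.conjugate(freq)
    cov = np.fft.irfft(freq, n=m, axis=1)[:, :n]
    return cov / n


def _ess_split(ary: np.ndarray) -> float:
    """ESS of an already split (chains, draws) array via Geyer pair sums."""
    ary = np.asarray(ary, float)
    if (np.max(ary) - np.min(ary)) < np.finfo(float).resolution:
        return float(ary.size)
    n_chain, n_draw = ary.shape
    acov = _autocov(ary)
    chain_mean = ary.mean(axis=1)
    mean_var = np.mean(acov[:, 0]) * n_draw / (n_draw - 1.0)
    var_plus = mean_var * (n_draw - 1.0) / n_draw
    if n_chain > 1:
        var_plus += np.var(chain_mean, ddof=1)

    rho_hat = np.zeros(n_draw)
    rho_even = 1.0
    rho_hat[0] = rho_even
    rho_odd = 1.0 - (mean_var - np.mean(acov[:, 1])) / var_plus
    rho_hat[1] = rho_odd

    # Geyer's initial positive sequence
    t = 1
    while t < (n_draw - 3) and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - np.mean(acov[:, t + 1])) / var_plus
        rho_odd = 1.0 - (mean_var - np.mean(acov[:, t + 2])) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho_hat[t + 1] = rho_even
            rho_hat[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho_hat[max_t + 1] = rho_even

    # Geyer's initial monotone sequence
    t = 1
    while t <= max_t - 2:
        if (rho_hat[t + 1] + rho_hat[t + 2]) > (rho_hat[t - 1] + rho_hat[t]):
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2

    size = n_chain * n_draw
    tau_hat = -1.0 + 2.0 * np.sum(rho_hat[: max_t + 1]) + np.sum(rho_hat[max_t + 1 : max_t + 2])
    tau_hat = max(tau_hat, 1.0 / np.log10(size))
    if np.isnan(rho_hat).any():
        return np.nan
    return float(size / tau_hat)


def ess_bulk(draws: np.ndarray) -> float:
    """Bulk effective sample size of the rank-normalized split draws."""
    ary = _as_chains(draws)
    if ary.shape[1] < 4:
        raise ValueError("need >= 4 draws per chain")
    return _ess_split(_z_scale(_split_chains(ary)))


def ess_tail(draws: np.ndarray, probs: tuple[float, float] = (0.05, 0.95)) -> float:
    """Tail effective sample size: minimum ESS over the ``probs`` quantile
    indicator variables (R type-7 quantile of the pooled draws)."""
    ary = _as_chains(draws)
    if ary.shape[1] < 4:
        raise ValueError("need >= 4 draws per chain")
    out = np.inf
    for prob in probs:
        q = stats.mstats.mquantiles(ary.ravel(), prob, alphap=1, betap=1)[0]
        out = min(out, _ess_split(_split_chains(ary <= q)))
    return float(out)


def rhat_ess_summary(draws_by_param: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Compute all three diagnostics per parameter name."""
    return {
        name: {
            "rhat": split_rhat(d),
            "ess_bulk": ess_bulk(d),
            "ess_tail": ess_tail(d),
        }
        for name, d in draws_by_param.items()
    }
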