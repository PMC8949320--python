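"""Scoring chain from raw item responses to analysis-ready scores.

Steps, in order:

1. per-subscale response-time quantile bounds (fast-guess cut at the 5%
   quantile, overly-slow cut at the 99.5% quantile by default);
2. validity filtering against those bounds (closed interval);
3. CISRT efficiency scoring — a correct *and* valid item earns its residual
   time ``upper - rt``; everything else earns 0; item scores are averaged per
   person x timepoint x subscale and mapped linearly to [0, 10];
4. optional linear rescaling of downstream (factor) scores;
5. multivariate outlier screening via Mahalanobis distance against a
   chi-square cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .params import ParameterError


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


def rt_quantile_bounds(
    responses: pd.DataFrame, q_low: float = 0.05, q_high: float = 0.995
) -> pd.DataFrame:
    """Empirical response-time quantile bounds per subscale.

    Quantiles are computed across all items and persons of a subscale with
    the linear-interpolation convention (numpy default).  Returns a
    DataFrame with columns ``subscale, lower_ms, upper_ms``.
    """
    if not 0.0 < q_low < q_high < 1.0:
        raise ParameterError("need 0 < q_low < q_high < 1")
    if responses.empty:
        raise DataError("no responses")
    rows = []
    for subscale, grp in responses.groupby("subscale", sort=True):
        rt = grp["rt_ms"].to_numpy(float)
        lo = float(np.quantile(rt, q_low))
        hi = float(np.quantile(rt, q_high))
        if not lo < hi:
            raise DataError(f"degenerate bounds for subscale {subscale!r} (lower == upper)")
        rows.append({"subscale": subscale, "lower_ms": lo, "upper_ms": hi})
    return pd.DataFrame(rows)


def filter_responses(responses: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Flag each response as valid iff ``lower_ms <= rt_ms <= upper_ms``
    (closed interval) for its subscale.  Adds a boolean ``valid`` column."""
    missing = set(responses["subscale"]) - set(bounds["subscale"])
    if missing:
        raise DataError(f"no bounds for subscale(s): {sorted(missing)}")
    out = responses.merge(bounds, on="subscale", how="left")
    out["valid"] = (out["rt_ms"] >= out["lower_ms"]) & (out["rt_ms"] <= out["upper_ms"])
    return out.drop(columns=["lower_ms", "upper_ms"])


def cisrt_score(responses: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Correct item summed residual time (CISRT) efficiency scores in [0, 10].

    A correct, valid response earns the residual time ``upper_ms - rt_ms``;
    incorrect or invalid (too fast / too slow) responses earn 0, so fast
    guessing is not rewarded.  Item scores are divided by the bound width
    ``upper_ms - lower_ms``, scaled by 10 and averaged per
    person x timepoint x subscale.
    """
    if "valid" not in responses.columns:
        responses = filter_responses(responses, bounds)
    df = responses.merge(bounds, on="subscale", how="left")
    residual = (df["upper_ms"] - df["rt_ms"]).clip(lower=0.0)
    earn = np.where(df["valid"] & (df["correct"] == 1), residual, 0.0)
    width = df["upper_ms"] - df["lower_ms"]
    df["item_score"] = 10.0 * earn / width
    grouped = df.groupby(["person_id", "timepoint", "subscale"], sort=True)
    counts = grouped["item_score"].size()
    if (counts < 1).any():  # pragma: no cover - groupby cannot emit empty groups
        raise DataError("person x timepoint cell with zero administered items")
    score = grouped["item_score"].mean().reset_index(name="score")
    if ((score["score"] < 0) | (score["score"] > 10)).any():
        raise DataError("CISRT score outside [0, 10]; check the bounds")
    return score


def rescale_scores(scores: pd.DataFrame, factor: float, column: str = "y") -> pd.DataFrame:
    """Multiply a score column by ``factor`` (e.g. 30 to move factor scores
    to a scale that is numerically friendlier for MCMC).  The factor is
    recorded in ``DataFrame.attrs['rescale_factor']``."""
    if factor == 0:
        raise ParameterError("rescale factor must be nonzero")
    out = scores.copy()
    out[column] = out[column] * factor
    out.attrs["rescale_factor"] = factor * scores.attrs.get("rescale_factor", 1.0)
    return out


def mahalanobis_outliers(wide: pd.DataFrame | np.ndarray, alpha: float = 0.001) -> pd.DataFrame:
    """Multivariate outlier screening on a person x timepoint score matrix.

    Computes each row's squared Mahalanobis distance to the sample mean under
    the sample covariance and flags rows whose distance exceeds the
    chi-square(T) upper-``alpha`` quantile.  On clean multivariate-normal
    data the flagged proportion converges to ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    x = np.asarray(wide, float)
    if x.ndim != 2 or x.shape[0] <= x.shape[1]:
        raise DataError("need more complete rows than timepoints")
    if np.isnan(x).any():
        raise DataError("rows must be complete (no missing values)")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise DataError("singular sample covariance")
    diff = x - mean
    d2 = np.einsum("ni,ij,nj->n", diff, np.linalg.inv(cov), diff)
    cutoff = stats.chi2.ppf(1.0 - alpha, df=x.shape[1])
    index = wide.index if isinstance(wide, pd.DataFrame) else pd.RangeIndex(len(x))
    return pd.DataFrame({"distance2": d2, "outlier": d2 > cutoff}, index=index)


def scores_to_wide(scores: pd.DataFrame, column: str = "y") -> pd.DataFrame:
    """Pivot a long score table to a complete person x timepoint matrix."""
    wide = scores.pivot(index="person_id", columns="timepoint", values=column)
    if wide.isna().any().any():
        raise DataError("incomplete person x timepoint grid")
    return wide
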