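"""Accuracy statistics for observed-vs-predicted AGB, residual
spatial-autocorrelation testing, and AGB-range-stratified error profiles.

Errors are defined as predicted - observed.  RMSE, bias and the population
standard deviation of errors satisfy the exact identity
``RMSE^2 = bias^2 + SD^2``; %RMSE is 100 * RMSE / mean(observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationReport",
    "compute_metrics",
    "morans_i_test",
    "stratified_error_profile",
    "DEFAULT_PROFILE_EDGES",
]

#: default AGB-range bin edges (Mg ha^-1) of the error profile
DEFAULT_PROFILE_EDGES = (0.0, 50.0, 100.0, 150.0, 200.0, np.inf)


@dataclass
class ValidationReport:
    """Container of the evaluation statistics of one model run."""

    n: int
    r_squared: float
    rmse: float
    pct_rmse: float
    bias: float
    sd_error: float
    morans_i: dict | None = None
    stratified_profile: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n,
                "r_squared": self.r_squared,
                "rmse": self.rmse,
                "pct_rmse": self.pct_rmse,
                "bias": self.bias,
                "sd_error": self.sd_error,
            }
        )


def compute_metrics(observed, predicted, r2_definition: str = "pearson") -> ValidationReport:
    """Core accuracy statistics of predictions against reference values.

    R^2 is by default the squared Pearson correlation of observed and
    predicted (``r2_definition='pearson'``); ``'ss'`` selects the
    1 - SSE/SST coefficient of determination instead.  Zero variance in
    either vector yields R^2 = NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two observations")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sd = float(np.std(err))  # population denominator so rmse^2 = bias^2 + sd^2
    mean_obs = obs.mean()
    pct = float(100.0 * rmse / mean_obs) if mean_obs > 0 else np.nan
    if obs.std() == 0 or pred.std() == 0:
        r2 = np.nan
    elif r2_definition == "pearson":
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    elif r2_definition == "ss":
        r2 = float(1.0 - np.sum(err**2) / np.sum((obs - mean_obs) ** 2))
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")
    return ValidationReport(n=n, r_squared=r2, rmse=rmse, pct_rmse=pct, bias=bias, sd_error=sd)


def _inverse_distance_weights(xy: np.ndarray) -> np.ndarray:
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if np.any(d[~np.eye(len(xy), dtype=bool)] == 0):
        raise ValueError("locations must be distinct")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)  # row standardization
    return w


def morans_i_test(residuals, locations, permutations: int = 0, seed: int | None = None) -> dict:
    """Global Moran's I of residuals with inverse-distance, row-standardized
    weights.

    Returns a dict with the statistic, its null expectation -1/(n-1), a
    z-score and two-sided p-value from the normal approximation under the
    randomization assumption, and optionally a permutation p-value
    (``permutations`` > 0, seeded).  All residuals equal -> statistic
    undefined, reported as NaN.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(locations, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("Moran's I test needs at least 10 observations")
    if xy.shape != (n, 2):
        raise ValueError("locations must be (n, 2)")
    if np.ptp(z) == 0:
        return {"I": np.nan, "expected_i": -1.0 / (n - 1), "z_score": np.nan, "p_value": np.nan}
    w = _inverse_distance_weights(xy)
    zc = z - z.mean()
    s0 = w.sum()
    i_obs = (n / s0) * (zc @ w @ zc) / (zc @ zc)
    e_i = -1.0 / (n - 1)

    # moments under the randomization assumption
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (zc**4).sum() / ((zc**2).sum() ** 2)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    z_score = (i_obs - e_i) / np.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(z_score))
    out = {
        "I": float(i_obs),
        "expected_i": e_i,
        "var_i": float(var_i),
        "z_score": float(z_score),
        "p_value": float(p),
        "weights": "inverse-distance, row-standardized, no cutoff",
    }
    if permutations:
        rng = np.random.default_rng(seed)
        count = 0
        denom = zc @ zc
        for _ in range(permutations):
            zp = rng.permutation(zc)
            i_p = (n / s0) * (zp @ w @ zp) / denom
            if abs(i_p - e_i) >= abs(i_obs - e_i):
                count += 1
        out["p_value_perm"] = (count + 1) / (permutations + 1)
    return out


def stratified_error_profile(observed, predicted, bin_edges=DEFAULT_PROFILE_EDGES) -> pd.DataFrame:
    """Mean error (predicted - observed) with t-based 95% CI per reference
    AGB range.

    Bins are half-open [lo, hi) on the observed values and must cover their
    range.  Empty bins are reported with NaN mean and CI.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if obs.min() < edges[0] or obs.max() >= edges[-1] and not np.isinf(edges[-1]):
        raise ValueError("bin edges do not cover the observed range")
    err = pred - obs
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (obs >= lo) & (obs < hi)
        k = int(m.sum())
        if k == 0:
            rows.append({"lo": lo, "hi": hi, "n": 0, "mean_error": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        e = err[m]
        mean = float(e.mean())
        if k > 1 and e.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, k - 1) * e.std(ddof=1) / np.sqrt(k)
        else:
            half = 0.0 if k > 1 else np.nan
        rows.append({"lo": lo, "hi": hi, "n": k, "mean_error": mean,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows)
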