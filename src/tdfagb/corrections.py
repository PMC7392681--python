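"""Plot-level AGB corrections: small-tree correction factors per AGB stratum
and temporal (stand-age) correction to a common baseline year.

NFI plots only record stems >= 7.5 cm DBH, so their AGB misses the small-stem
component that ICM plots measure in a nested subplot.  Because the small-stem
share shrinks as stands mature, and AGB is a proxy for stand age, plots are
stratified into 5 strata by the 10/25/50/75% percentiles of large-stem AGB
per forest type, and a multiplicative correction factor

    f = sum(agb_total) / sum(agb_large)   over the stratum's ICM plots

is applied to the large-stem AGB of NFI plots in the matching stratum.

NFI plots were also measured in different years; the age correction inverts a
monotone chronosequence AGB(t) = A (1 - exp(-r t)) to an approximate stand
age, advances the age by the years elapsed to the baseline (2015), and reads
the curve forward again.  Corrections are growth-only (output >= input) and
applied small-tree first, then age, since the chronosequence describes total
AGB.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .allometry import DECIDUOUS_GROUP, FOREST_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "StratificationError",
    "CorrectionStateError",
    "build_strata",
    "assign_stratum",
    "SmallTreeCorrector",
    "Chronosequence",
    "fit_chronosequences",
    "apply_age_correction",
    "correct_plots",
    "chrono_group",
]

PERCENTILES = (10, 25, 50, 75)
BASELINE_YEAR = 2015
#: AGB at or above this fraction of the chronosequence asymptote is treated
#: as mature forest and the age correction becomes the identity
MATURE_FRACTION = 0.99


class StratificationError(ValueError):
    pass


class CorrectionStateError(RuntimeError):
    pass


def chrono_group(forest_type: str) -> str:
    """Map a forest type to its chronosequence group (one curve shared by the
    deciduous and semi-deciduous forests, one for the semi-evergreen)."""
    return "deciduous_group" if forest_type in DECIDUOUS_GROUP else "semi_evergreen"


def build_strata(plots: pd.DataFrame, value_col: str = "agb_large") -> dict:
    """Per-forest-type stratum breakpoints from the pooled NFI+ICM large-stem
    AGB distribution.

    Breakpoints are the 10/25/50/75% linear-interpolation percentiles; they
    must be strictly increasing (5 non-degenerate strata).  Returns
    ``{forest_type: array of 4 breakpoints}``.
    """
    strata = {}
    for ftype, g in plots.groupby("forest_type"):
        vals = g[value_col].to_numpy(dtype=float)
        if len(vals) < 5:
            raise StratificationError(f"fewer than 5 units for forest type {ftype!r}")
        bp = np.percentile(vals, PERCENTILES, method="linear")
        if not np.all(np.diff(bp) > 0):
            raise StratificationError(
                f"degenerate strata for {ftype!r}: ties collapse a stratum to zero width"
            )
        strata[ftype] = bp
    return strata


def assign_stratum(values, breakpoints) -> np.ndarray:
    """Stratum index 0-4 via half-open intervals [b_i, b_{i+1}); a value equal
    to a breakpoint falls in the upper stratum."""
    return np.searchsorted(np.asarray(breakpoints), np.asarray(values, dtype=float), side="right")


class SmallTreeCorrector(BaseEstimator, TransformerMixin):
    """Stratum-wise multiplicative small-tree correction for NFI plots.

    ``fit`` estimates the (forest type, stratum) factor table from ICM plots
    (ratio of sums, total over large-stem AGB); ``transform`` scales the
    large-stem AGB of NFI plots by the factor of their stratum.  Empty cells
    fall back to the forest-type-wide factor (logged).

    Parameters
    ----------
    strata : dict
        ``{forest_type: breakpoints}`` from :func:`build_strata`.
    """

    def __init__(self, strata: dict | None = None):
        self.strata = strata

    def fit(self, icm_plots: pd.DataFrame, y=None):
        if self.strata is None:
            raise ValueError("strata must be provided (built on pooled NFI+ICM plots)")
        rows = []
        for ftype in FOREST_TYPES:
            g = icm_plots.loc[icm_plots["forest_type"] == ftype]
            if g.empty:
                continue
            tot_l, tot_t = g["agb_large"].sum(), g["agb_total"].sum()
            type_factor = tot_t / tot_l if tot_l > 0 else 1.0
            strat = assign_stratum(g["agb_large"], self.strata[ftype])
            for s in range(5):
                cell = g.loc[strat == s]
                if cell.empty or cell["agb_large"].sum() <= 0:
                    logger.info(
                        "empty small-tree cell (%s, stratum %d): type-wide factor %.3f",
                        ftype, s, type_factor,
                    )
                    f = type_factor
                else:
                    f = cell["agb_total"].sum() / cell["agb_large"].sum()
                rows.append(
                    {"forest_type": ftype, "stratum": s, "factor": f, "n_plots": len(cell)}
                )
        self.factors_ = pd.DataFrame(rows)
        if (self.factors_["factor"] < 1.0 - 1e-12).any():
            raise ValueError("correction factors below 1 (small trees only add biomass)")
        return self

    def transform(self, nfi_plots: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise CorrectionStateError("corrector is not fitted")
        if (nfi_plots["source"] != "NFI").any():
            raise ValueError("small-tree correction applies to NFI plots only")
        if nfi_plots.get("small_tree_corrected", pd.Series(False, index=nfi_plots.index)).any():
            raise CorrectionStateError("plots are already small-tree corrected")
        out = nfi_plots.copy()
        lookup = self.factors_.set_index(["forest_type", "stratum"])["factor"]
        strat = np.concatenate(
            [
                assign_stratum(
                    out.loc[out["forest_type"] == ft, "agb_large"], self.strata[ft]
                )
                for ft in FOREST_TYPES
                if (out["forest_type"] == ft).any()
            ]
        ) if len(out) else np.array([], dtype=int)
        # keep row order aligned with the concatenation above
        order = np.concatenate(
            [out.index[out["forest_type"] == ft].to_numpy() for ft in FOREST_TYPES]
        ) if len(out) else np.array([], dtype=int)
        strat = pd.Series(strat, index=order).reindex(out.index)
        factors = np.array(
            [lookup[(ft, s)] for ft, s in zip(out["forest_type"], strat)]
        )
        out["stratum"] = strat.to_numpy()
        out["agb_total"] = factors * out["agb_large"].to_numpy()
        out["agb_small"] = out["agb_total"] - out["agb_large"]
        out["small_tree_corrected"] = True
        return out


class Chronosequence(BaseEstimator):
    """Monotone saturating stand-growth curve AGB(t) = A (1 - exp(-r t)).

    ``fit`` estimates (A, r) from chronosequence observations by nonlinear
    least squares; the curve is analytically invertible, with g(0) = 0 and g
    strictly increasing, so stand age can be recovered from AGB on [0, A).
    """

    def __init__(self, asymptote: float | None = None, rate: float | None = None):
        self.asymptote = asymptote
        self.rate = rate

    def fit(self, ages, agb):
        ages = np.asarray(ages, dtype=float)
        agb = np.asarray(agb, dtype=float)
        p0 = (max(agb.max(), 1.0) * 1.1, 0.05)
        (a, r), _ = curve_fit(
            lambda t, a, r: a * (1.0 - np.exp(-r * t)),
            ages, agb, p0=p0,
            bounds=([1e-6, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        self.asymptote_, self.rate_ = float(a), float(r)
        return self

    def _params(self):
        if hasattr(self, "asymptote_"):
            return self.asymptote_, self.rate_
        if self.asymptote is None or self.rate is None:
            raise ValueError("chronosequence has neither fixed parameters nor a fit")
        return self.asymptote, self.rate

    def predict(self, t):
        a, r = self._params()
        return a * (1.0 - np.exp(-r * np.asarray(t, dtype=float)))

    def inverse(self, agb):
        a, r = self._params()
        agb = np.asarray(agb, dtype=float)
        if np.any(agb < 0) or np.any(agb >= a):
            raise ValueError("AGB outside the invertible range [0, asymptote)")
        return -np.log(1.0 - agb / a) / r


def fit_chronosequences(observations: pd.DataFrame) -> dict:
    """Fit one :class:`Chronosequence` per group from a frame with columns
    group, age, agb."""
    return {
        grp: Chronosequence().fit(g["age"], g["agb"])
        for grp, g in observations.groupby("group")
    }


def apply_age_correction(
    agb,
    year_measured,
    model: Chronosequence,
    baseline_year: int = BASELINE_YEAR,
):
    """Project plot AGB from its measurement year to the baseline year along
    the chronosequence.

    Mature plots (AGB >= MATURE_FRACTION * asymptote) pass through unchanged
    (logged); the correction is growth-only, so output >= input.
    """
    scalar = np.isscalar(agb) or np.asarray(agb).ndim == 0
    agb = np.atleast_1d(np.asarray(agb, dtype=float))
    years = np.broadcast_to(np.atleast_1d(year_measured), agb.shape).astype(int)
    if np.any(years > baseline_year):
        raise ValueError("measurement year is after the baseline year")
    if np.any(agb < 0):
        raise ValueError("AGB must be non-negative")
    a, r = model._params()
    out = agb.copy()
    mature = agb >= MATURE_FRACTION * a
    if mature.any():
        logger.info("%d plots at/above %.0f%% of the asymptote kept as mature",
                    int(mature.sum()), 100 * MATURE_FRACTION)
    act = ~mature
    if act.any():
        t_hat = model.inverse(agb[act])
        out[act] = model.predict(t_hat + (baseline_year - years[act]))
    return float(out[0]) if scalar else out


def correct_plots(
    nfi_plots: pd.DataFrame,
    icm_plots: pd.DataFrame,
    chrono_models: dict,
    baseline_year: int = BASELINE_YEAR,
    small_tree: bool = True,
    age: bool = True,
    strata: dict | None = None,
) -> pd.DataFrame:
    """Composed NFI correction: small-tree factors first, then age.

    ``chrono_models`` maps chronosequence group ('deciduous_group' |
    'semi_evergreen') to a fitted :class:`Chronosequence`.  Strata default to
    :func:`build_strata` on the pooled NFI+ICM plots.
    """
    if strata is None:
        strata = build_strata(pd.concat([nfi_plots, icm_plots], ignore_index=True))
    out = nfi_plots.copy()
    if small_tree:
        corrector = SmallTreeCorrector(strata=strata).fit(icm_plots)
        out = corrector.transform(out)
    if age:
        corrected = np.empty(len(out))
        for i, (_, row) in enumerate(out.iterrows()):
            model = chrono_models[chrono_group(row["forest_type"])]
            corrected[i] = apply_age_correction(
                row["agb_total"], row["year_measured"], model, baseline_year
            )
        out["agb_total"] = corrected
        out["age_corrected"] = True
    return out
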