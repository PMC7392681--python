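"""Two-stage LiDAR upscaling of field AGB.

Stage 1 fits a parsimonious linear model of sqrt(AGB) on plot-level LiDAR
canopy metrics by exhaustive best-subset selection (adjusted R^2 criterion),
validated by leave-one-out cross-validation.  Stage 2 applies the model over
LiDAR-covered areas to mint dense "LiDAR plots": non-overlapping 1-ha
circular plots whose predicted AGB then augments (or replaces) field plots
when training the wall-to-wall mapping model.

The square-root transform linearizes the AGB-structure relation; predictions
are back-transformed by squaring, with the linear predictor floored at zero.
No retransformation-bias correction is applied by default; Duan's smearing
estimate is available as an option for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .grids import Grid
from .sar import PLOT_RADIUS_M
from .validation import ValidationReport, compute_metrics

logger = logging.getLogger(__name__)

__all__ = ["BestSubsetRegressor", "loocv_validate", "sample_lidar_plots"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class BestSubsetRegressor(BaseEstimator, RegressorMixin):
    """Exhaustive best-subset linear regression on sqrt-transformed AGB.

    All predictor subsets up to ``max_size`` are fitted by OLS on
    sqrt(y); the subset with the highest adjusted R^2 wins, with ties broken
    toward the smaller subset and then lexicographic metric order.  Subsets
    whose design matrix is ill-conditioned (condition number above
    ``cond_threshold``) are skipped and logged.

    Attributes (after fit): ``selected_features_``, ``coef_``,
    ``intercept_``, ``adj_r2_``, ``n_features_in_``.
    """

    def __init__(
        self,
        max_size: int = 5,
        sqrt_transform: bool = True,
        retransformation: str = "none",  # 'none' | 'smearing'
        cond_threshold: float = 1e10,
    ):
        self.max_size = max_size
        self.sqrt_transform = sqrt_transform
        self.retransformation = retransformation
        self.cond_threshold = cond_threshold

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        n, p = Xf.shape
        if n <= self.max_size + 1:
            raise ValueError("need n > max_size + 1 observations")
        const = [c for c in Xf.columns if Xf[c].nunique() == 1]
        if const:
            raise ValueError(f"constant predictor columns: {const}")
        z = np.sqrt(y) if self.sqrt_transform else y
        cols = list(Xf.columns)
        best = None  # (adj_r2, subset, coefs)
        sst = np.sum((z - z.mean()) ** 2)
        for k in range(1, min(self.max_size, p) + 1):
            for subset in combinations(range(p), k):
                a = np.column_stack([np.ones(n), Xf.iloc[:, list(subset)].to_numpy()])
                if np.linalg.cond(a) > self.cond_threshold:
                    logger.info("skipping ill-conditioned subset %s", subset)
                    continue
                coef, _, _, _ = np.linalg.lstsq(a, z, rcond=None)
                resid = z - a @ coef
                r2 = 1.0 - np.sum(resid**2) / sst
                adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
                if best is None or adj > best[0]:
                    best = (adj, subset, coef, resid)
        if best is None:
            raise ValueError("no admissible subset found")
        adj, subset, coef, resid = best
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = p
        self.selected_features_ = [cols[i] for i in subset]
        self.selected_idx_ = list(subset)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:].copy()
        self.adj_r2_ = float(adj)
        self.smearing_factor_ = float(np.mean(resid**2))
        self.fitted_sqrt_ = z - resid
        return self

    def linear_predictor(self, X) -> np.ndarray:
        Xf = _as_frame(X)
        xs = Xf[self.selected_features_].to_numpy(dtype=float)
        return self.intercept_ + xs @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Predicted AGB (original scale, floored at 0)."""
        lp = self.linear_predictor(X)
        if not self.sqrt_transform:
            return np.maximum(lp, 0.0)
        out = np.maximum(lp, 0.0) ** 2
        if self.retransformation == "smearing":
            out = out + self.smearing_factor_
        elif self.retransformation != "none":
            raise ValueError(f"unknown retransformation {self.retransformation!r}")
        return out


def loocv_validate(model: BestSubsetRegressor, X, y) -> ValidationReport:
    """Leave-one-out cross-validation of a fitted subset model.

    Each fold refits the OLS coefficients with the *fixed* selected subset;
    held-out predictions are back-transformed by squaring.  Folds with a
    singular design are dropped and counted in ``report.meta``.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 observations")
    feats = model.selected_features_
    z = np.sqrt(y) if model.sqrt_transform else y
    a_full = np.column_stack([np.ones(n), Xf[feats].to_numpy(dtype=float)])
    preds, obs = [], []
    dropped = 0
    for i in range(n):
        keep = np.arange(n) != i
        a = a_full[keep]
        try:
            coef, _, rank, _ = np.linalg.lstsq(a, z[keep], rcond=None)
            if rank < a.shape[1]:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            dropped += 1
            continue
        lp = a_full[i] @ coef
        preds.append(max(lp, 0.0) ** 2 if model.sqrt_transform else max(lp, 0.0))
        obs.append(y[i])
    report = compute_metrics(np.asarray(obs), np.asarray(preds))
    report.meta["folds_dropped"] = dropped
    return report


def sample_lidar_plots(
    model: BestSubsetRegressor,
    metric_rasters: dict,
    grid: Grid,
    coverage_mask: np.ndarray,
    radius_m: float = PLOT_RADIUS_M,
) -> pd.DataFrame:
    """Stage 2: predicted-AGB plots tiling the LiDAR-covered area.

    Candidate plot centres lie on a regular grid of spacing 2 * radius (so
    the 1-ha circular footprints cannot overlap); a candidate is kept when
    every pixel of its footprint carries LiDAR metrics.  Each plot's AGB is
    the model prediction on the footprint-mean metrics, floored at 0.
    Returns a frame with columns unit_id, x, y, agb, provenance='lidar'.
    """
    if coverage_mask.shape != grid.shape:
        raise ValueError("coverage mask does not match the grid")
    step = 2.0 * radius_m
    xs0 = grid.x0 + radius_m
    ys0 = grid.y0 + radius_m
    nx = int((grid.ncols * grid.px - radius_m) // step) + 1
    ny = int((grid.nrows * grid.px - radius_m) // step) + 1
    span = int(np.ceil(radius_m / grid.px)) + 1
    rows = []
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            cx, cy = xs0 + ix * step, ys0 + iy * step
            if not grid.contains(cx, cy):
                continue
            rc, cc = grid.rowcol(cx, cy)
            rr, cols = np.mgrid[rc - span : rc + span + 1, cc - span : cc + span + 1]
            px_x, px_y = grid.xy(rr, cols)
            incircle = (px_x - cx) ** 2 + (px_y - cy) ** 2 <= radius_m**2
            inraster = (rr >= 0) & (rr < grid.nrows) & (cols >= 0) & (cols < grid.ncols)
            if not incircle.any() or np.any(incircle & ~inraster):
                continue
            ridx, cidx = rr[incircle], cols[incircle]
            if not coverage_mask[ridx, cidx].all():
                continue
            means = {
                name: float(np.nanmean(ras[ridx, cidx]))
                for name, ras in metric_rasters.items()
            }
            agb = float(model.predict(pd.DataFrame([means]))[0])
            rows.append({"unit_id": f"lidar_{k:05d}", "x": cx, "y": cy, "agb": agb,
                         "provenance": "lidar"})
            k += 1
    if not rows:
        warnings.warn("LiDAR coverage too small to hold a single 1-ha plot")
        return pd.DataFrame(columns=["unit_id", "x", "y", "agb", "provenance"])
    return pd.DataFrame(rows)
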