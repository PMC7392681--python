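"""Wall-to-wall AGB mapping with a 500-tree random forest.

Calibration/validation plots are split 70/30 with stratification over
(forest type x AGB stratum) cells using largest-remainder allocation, which
reproduces exact printed split sizes (e.g. 152/66 from 218 plots, 200/87
from 287).  Three modelling approaches share one held-out field validation
set: training on corrected field plots, on LiDAR-derived plots, or on their
union.  Per-pixel uncertainty is the coefficient of variation of the
individual tree predictions (SD over trees divided by the ensemble mean).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .grids import Grid
from .validation import ValidationReport, compute_metrics, morans_i_test

logger = logging.getLogger(__name__)

__all__ = [
    "stratified_split",
    "AGBRandomForest",
    "predict_map",
    "run_approach",
    "LeakageError",
]

#: ensemble mean below this AGB (Mg/ha) makes the CV ratio unstable: no-data
CV_EPSILON = 1.0


class LeakageError(RuntimeError):
    pass


def stratified_split(
    plots: pd.DataFrame, fraction: float = 0.70, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified calibration/validation split.

    Validation units are drawn within each (forest type x stratum) cell;
    the global calibration size is exactly floor(fraction * n), achieved by
    largest-remainder allocation of the validation quota across cells.
    Cells holding a single unit go to calibration (logged).  Deterministic
    under ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(plots)
    n_cal = int(np.floor(fraction * n))
    n_val = n - n_cal
    rng = np.random.default_rng(seed)
    cells = list(plots.groupby(["forest_type", "stratum"], sort=True).groups.items())
    singles = [idx for _, idx in cells if len(idx) == 1]
    if singles:
        logger.info("%d single-unit cells assigned to calibration", len(singles))
    eligible = [(key, idx) for key, idx in cells if len(idx) > 1]
    n_elig = sum(len(idx) for _, idx in eligible)
    val_index = []
    if n_val > 0 and n_elig > 0:
        quota = np.array([len(idx) * n_val / n_elig for _, idx in eligible])
        take = np.floor(quota).astype(int)
        remainder = quota - take
        short = n_val - take.sum()
        for i in np.argsort(-remainder, kind="stable")[:short]:
            take[i] += 1
        # a cell cannot give more units than it has
        for i, (_, idx) in enumerate(eligible):
            take[i] = min(take[i], len(idx))
        deficit = n_val - take.sum()
        i = 0
        while deficit > 0 and i < len(eligible):
            room = len(eligible[i][1]) - take[i]
            extra = min(room, deficit)
            take[i] += extra
            deficit -= extra
            i += 1
        for (_, idx), k in zip(eligible, take):
            if k > 0:
                val_index.extend(rng.choice(np.asarray(idx), size=k, replace=False))
    val_mask = plots.index.isin(val_index)
    cal = plots.loc[~val_mask].copy()
    val = plots.loc[val_mask].copy()
    cal["split"] = "calibration"
    val["split"] = "validation"
    return cal, val


class AGBRandomForest(BaseEstimator, RegressorMixin):
    """Random-forest AGB model with OOB-tuned predictors-per-split.

    500 trees by default; the number of candidate predictors at each split is
    tuned over a grid centred on p/3 by out-of-bag R^2.  Individual tree
    predictions remain accessible for uncertainty mapping; the ensemble
    prediction is their mean.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry_offsets: tuple = (-4, -2, 0, 2, 4),
        random_state: int = 0,
        allow_constant: bool = False,
    ):
        self.n_trees = n_trees
        self.mtry_offsets = mtry_offsets
        self.random_state = random_state
        self.allow_constant = allow_constant

    def fit(self, X, y):
        Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if len(Xf) < 20:
            raise ValueError("need at least 20 training rows")
        if np.ptp(y) == 0:
            if not self.allow_constant:
                raise ValueError("constant response: degenerate model")
            self.constant_ = float(y[0])
        p = Xf.shape[1]
        base = max(p // 3, 1)
        grid = sorted({int(np.clip(base + s, 1, p)) for s in self.mtry_offsets})
        best = None
        for mtry in grid:
            rf = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=mtry,
                oob_score=True,
                bootstrap=True,
                random_state=self.random_state,
                n_jobs=1,
            )
            rf.fit(Xf.to_numpy(dtype=float), y)
            if best is None or rf.oob_score_ > best[0]:
                best = (rf.oob_score_, mtry, rf)
        self.oob_score_, self.max_features_, self.model_ = best
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = p
        imp = self.model_.feature_importances_
        self.importances_ = pd.Series(imp, index=list(Xf.columns)).sort_values(ascending=False)
        return self

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing predictor columns: {missing}")
            return X[list(self.feature_names_in_)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict(self, X) -> np.ndarray:
        if hasattr(self, "constant_"):
            return np.full(len(X), self.constant_)
        return self.model_.predict(self._matrix(X))

    def predict_per_tree(self, X) -> np.ndarray:
        """(n_trees, n_samples) matrix of individual tree predictions."""
        m = self._matrix(X)
        return np.stack([t.predict(m) for t in self.model_.estimators_])


def predict_map(
    model: AGBRandomForest,
    layers: dict,
    grid: Grid,
    cv_epsilon: float = CV_EPSILON,
) -> dict:
    """Per-pixel ensemble-mean AGB and coefficient-of-variation rasters.

    Every model predictor must be present as a layer (error names the missing
    one); pixels with any no-data predictor propagate no-data, and the CV is
    no-data where the mean falls below ``cv_epsilon`` Mg/ha.
    """
    missing = [f for f in model.feature_names_in_ if f not in layers]
    if missing:
        raise ValueError(f"missing predictor layer(s): {missing}")
    mats = [np.asarray(layers[f], dtype=float).ravel() for f in model.feature_names_in_]
    x = np.column_stack(mats)
    ok = np.isfinite(x).all(axis=1)
    mean = np.full(x.shape[0], np.nan)
    cv = np.full(x.shape[0], np.nan)
    if ok.any():
        per_tree = np.stack([t.predict(x[ok]) for t in model.model_.estimators_])
        mu = per_tree.mean(axis=0)
        sd = per_tree.std(axis=0)
        mean[ok] = mu
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sd / mu
        ratio[mu < cv_epsilon] = np.nan
        cv[ok] = ratio
    return {"agb_mean": mean.reshape(grid.shape), "agb_cv": cv.reshape(grid.shape)}


def run_approach(
    approach: str,
    field_cal: pd.DataFrame,
    field_val: pd.DataFrame,
    feature_cols: list,
    lidar_plots: pd.DataFrame | None = None,
    response_col: str = "agb",
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[AGBRandomForest, ValidationReport]:
    """Fit one modelling approach and validate it on the shared field set.

    approach 'field' trains on the corrected field calibration plots,
    'lidar' on LiDAR plots only, 'combined' on their unweighted union; all
    three are scored against the same held-out field validation plots.
    Raises :class:`LeakageError` if any validation unit appears in training.
    """
    if approach == "field":
        train = field_cal
    elif approach == "lidar":
        if lidar_plots is None or lidar_plots.empty:
            raise ValueError("lidar approach requires LiDAR plots")
        train = lidar_plots
    elif approach == "combined":
        if lidar_plots is None or lidar_plots.empty:
            raise ValueError("combined approach requires LiDAR plots")
        train = pd.concat([field_cal, lidar_plots], ignore_index=True)
    else:
        raise ValueError(f"unknown approach {approach!r}")
    overlap = set(train["unit_id"]) & set(field_val["unit_id"])
    if overlap:
        raise LeakageError(f"validation units present in training: {sorted(overlap)[:5]}")
    model = AGBRandomForest(n_trees=n_trees, random_state=seed).fit(
        train[feature_cols], train[response_col].to_numpy()
    )
    pred = model.predict(field_val[feature_cols])
    report = compute_metrics(field_val[response_col].to_numpy(), pred)
    report.meta.update({"approach": approach, "n_train": len(train), "seed": seed})
    if {"x", "y"}.issubset(field_val.columns) and len(field_val) >= 10:
        resid = pred - field_val[response_col].to_numpy()
        xy = field_val[["x", "y"]].to_numpy(dtype=float)
        if len(np.unique(xy, axis=0)) == len(xy):
            report.morans_i = morans_i_test(resid, xy)
    return model, report
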