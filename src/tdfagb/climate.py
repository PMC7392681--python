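"""Climatic water deficit (CWD) predictor from monthly station records.

Monthly precipitation and temperature from climate stations are interpolated
to the analysis grid by ordinary kriging with an exponential variogram;
potential evapotranspiration (PET) comes from the Priestley-Taylor equation
(alpha = 1.26) driven by temperature and clear-sky radiation for the site
latitude; the deficit is

    CWD = sum_i min(0, P_i - ET_i),   i = 1..12 (or a configured subset)

which is non-positive everywhere: 0 means no water deficit, increasingly
negative values mean stronger dry-season drought stress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grids import Grid

logger = logging.getLogger(__name__)

__all__ = [
    "filter_stations",
    "ExponentialVariogram",
    "fit_variogram",
    "krige",
    "interpolate_climate",
    "priestley_taylor_pet",
    "extraterrestrial_radiation",
    "compute_cwd",
    "cwd_from_stations",
]

_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)

#: Priestley-Taylor coefficient
PT_ALPHA = 1.26
#: psychrometric constant at standard sea-level pressure, kPa / degC
PSYCHROMETRIC_GAMMA = 0.0665
#: fraction of extraterrestrial radiation reaching the surface as net
#: radiation under the clear-sky dry-season conditions assumed here
NET_RADIATION_FRACTION = 0.5


def filter_stations(stations: pd.DataFrame) -> pd.DataFrame:
    """Retain only stations with complete 12-month records.

    ``stations`` is long-format with columns station_id, x, y, month,
    precip_mm, temp_c.  Stations missing any month or any value are removed
    (logged).  Raises if no station survives.
    """
    complete = []
    removed = []
    for sid, g in stations.groupby("station_id"):
        months = set(g.loc[g[["precip_mm", "temp_c"]].notna().all(axis=1), "month"])
        if months >= set(range(1, 13)):
            complete.append(sid)
        else:
            removed.append(sid)
    if removed:
        logger.info("removed %d stations with incomplete records", len(removed))
    if not complete:
        raise ValueError("no station has a complete 12-month record")
    return stations.loc[stations["station_id"].isin(complete)].copy()


@dataclass(frozen=True)
class ExponentialVariogram:
    """gamma(h) = sill * (1 - exp(-3 h / range)); nugget fixed at 0 so the
    kriging interpolator honours the data exactly."""

    sill: float
    range_: float

    def __call__(self, h):
        return self.sill * (1.0 - np.exp(-3.0 * np.asarray(h, dtype=float) / self.range_))


def fit_variogram(xy: np.ndarray, values: np.ndarray, n_bins: int = 12) -> ExponentialVariogram:
    """Weighted least-squares fit of an exponential model to the binned
    empirical semivariogram (weights = pair counts)."""
    xy = np.asarray(xy, dtype=float)
    v = np.asarray(values, dtype=float)
    d = cdist(xy, xy)
    iu = np.triu_indices(len(v), k=1)
    h = d[iu]
    sv = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    hmax = h.max() * 0.6
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (h > lo) & (h <= hi)
        if m.sum() > 0:
            centers.append(h[m].mean())
            gammas.append(sv[m].mean())
            counts.append(m.sum())
    centers = np.asarray(centers)
    gammas = np.asarray(gammas)
    counts = np.asarray(counts, dtype=float)
    sill0 = max(v.var(), 1e-12)
    rng0 = max(hmax / 2.0, 1e-6)

    def resid(p):
        model = p[0] * (1.0 - np.exp(-3.0 * centers / p[1]))
        return np.sqrt(counts) * (model - gammas)

    fit = least_squares(
        resid, x0=[sill0, rng0],
        bounds=([1e-12, 1e-6], [np.inf, np.inf]),
    )
    return ExponentialVariogram(sill=float(fit.x[0]), range_=float(fit.x[1]))


def _dedupe(xy: np.ndarray, values: np.ndarray):
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "v": values})
    g = df.groupby(["x", "y"], as_index=False)["v"].mean()
    if len(g) < len(df):
        logger.info("averaged %d duplicate station locations", len(df) - len(g))
    return g[["x", "y"]].to_numpy(), g["v"].to_numpy()


def krige(
    xy: np.ndarray,
    values: np.ndarray,
    targets_xy: np.ndarray,
    variogram: ExponentialVariogram | None = None,
) -> np.ndarray:
    """Ordinary kriging predictions at target locations.

    Exact interpolator: predictions at station locations reproduce the
    observations.  Duplicate station coordinates are averaged.  A constant
    field short-circuits to that constant.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    targets_xy = np.asarray(targets_xy, dtype=float)
    if len(values) < 2:
        raise ValueError("kriging needs at least two stations")
    xy, values = _dedupe(xy, values)
    n = len(values)
    if np.ptp(values) == 0 or n < 3:
        return np.full(len(targets_xy), values.mean())
    if variogram is None:
        variogram = fit_variogram(xy, values)
    if variogram.sill <= 1e-10:
        return np.full(len(targets_xy), values.mean())
    d = cdist(xy, xy)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram(d)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    # dual form: A is symmetric, so w^T v = b^T (A^{-1} [v; 0])
    alpha = np.linalg.solve(a, np.append(values, 0.0))
    preds = np.empty(len(targets_xy))
    chunk = 200_000
    for s in range(0, len(targets_xy), chunk):
        t = targets_xy[s : s + chunk]
        b = np.empty((n + 1, len(t)))
        b[:n] = variogram(cdist(xy, t))
        b[n] = 1.0
        preds[s : s + chunk] = alpha @ b
    return preds


def interpolate_climate(
    stations: pd.DataFrame, grid: Grid, variables=("precip_mm", "temp_c")
) -> dict:
    """Ordinary-kriged monthly rasters per variable.

    Returns ``{variable: {month: raster}}`` plus a ``"variograms"`` entry
    with the fitted model per (variable, month).
    """
    if stations["station_id"].nunique() < 5:
        raise ValueError("need at least 5 stations for interpolation")
    xs, ys = grid.coord_mesh()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    out: dict = {v: {} for v in variables}
    out["variograms"] = {}
    for var in variables:
        for month in range(1, 13):
            g = stations.loc[stations["month"] == month]
            xy = g[["x", "y"]].to_numpy(dtype=float)
            vals = g[var].to_numpy(dtype=float)
            xy2, vals2 = _dedupe(xy, vals)
            vario = fit_variogram(xy2, vals2) if np.ptp(vals2) > 0 and len(vals2) > 2 else None
            pred = krige(xy2, vals2, targets, vario)
            out[var][month] = pred.reshape(grid.shape)
            out["variograms"][(var, month)] = vario
    return out


def extraterrestrial_radiation(latitude_deg: float, month: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m^-2 day^-1) at mid-month,
    from standard solar-geometry/day-length formulas."""
    if abs(latitude_deg) > 66.5:
        raise ValueError("latitudes beyond the polar circles are unsupported")
    doy = _MID_MONTH_DOY[month - 1]
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    gsc = 0.0820  # MJ m^-2 min^-1
    return float(
        (24 * 60 / np.pi)
        * gsc
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )


def priestley_taylor_pet(
    temp_c: np.ndarray,
    latitude_deg: float,
    month: int,
    net_radiation: float | None = None,
) -> np.ndarray:
    """Monthly Priestley-Taylor PET (mm month^-1).

    PET = alpha * Delta/(Delta + gamma) * Rn / lambda, scaled by the days in
    the month.  Rn defaults to a fixed clear-sky fraction of the
    extraterrestrial radiation for the latitude and month; pass
    ``net_radiation`` (MJ m^-2 day^-1) to override.  PET is non-negative and
    increases with temperature at fixed radiation.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.nanmin(t) <= -10 or np.nanmax(t) >= 45:
        raise ValueError("temperature outside the supported (-10, 45) degC range")
    if net_radiation is None:
        net_radiation = NET_RADIATION_FRACTION * extraterrestrial_radiation(latitude_deg, month)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    delta = 4098.0 * es / (t + 237.3) ** 2  # kPa / degC
    lam = 2.501 - 0.002361 * t  # MJ / kg
    pet_day = PT_ALPHA * delta / (delta + PSYCHROMETRIC_GAMMA) * net_radiation / lam
    return np.maximum(pet_day, 0.0) * _DAYS_IN_MONTH[month - 1]


def compute_cwd(p_by_month: dict, et_by_month: dict, months=None) -> np.ndarray:
    """CWD raster: per-pixel sum over months of min(0, P_i - ET_i)."""
    months = tuple(months) if months is not None else tuple(range(1, 13))
    if set(months) - set(p_by_month) or set(months) - set(et_by_month):
        raise ValueError("requested months missing from P or ET inputs")
    cwd = None
    for m in months:
        deficit = np.minimum(0.0, np.asarray(p_by_month[m], dtype=float) - et_by_month[m])
        cwd = deficit if cwd is None else cwd + deficit
    return cwd


def cwd_from_stations(
    stations: pd.DataFrame,
    grid: Grid,
    latitude_deg: float,
    months=None,
) -> dict:
    """Station records to a CWD raster: filter, krige, PET, deficit sum.

    Returns ``{"cwd": raster, "p": {month: raster}, "et": {month: raster},
    "variograms": ...}``.
    """
    kept = filter_stations(stations)
    interp = interpolate_climate(kept, grid)
    et = {
        m: priestley_taylor_pet(interp["temp_c"][m], latitude_deg, m)
        for m in range(1, 13)
    }
    cwd = compute_cwd(interp["precip_mm"], et, months)
    return {"cwd": cwd, "p": interp["precip_mm"], "et": et, "variograms": interp["variograms"]}
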