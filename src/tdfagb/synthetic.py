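"""Synthetic study systems for the AGB-mapping pipeline.

Generates, from a single seed, a complete landscape with the statistical
structure the analysis assumes, so every downstream stage can be exercised
offline: a smooth stand-age surface over three forest-type bands (deciduous,
semi-deciduous, semi-evergreen, drier to wetter west to east), per-unit tree
lists realised to match chronosequence AGB truths, dual-pol L-band
digital-number rasters whose mean backscatter saturates near 150 Mg/ha with
multiplicative gamma speckle, monthly climate stations on smooth spatial
gradients, LiDAR canopy metrics over a small covered fraction of the extent,
and noisy chronosequence observations to refit the growth curves from.

Key emulated study conditions: NFI-like units record only stems >= 7.5 cm
DBH and were measured over 2009-2014; ICM-like units add the nested 80 m^2
small-stem subplot and a fixed 2015 measurement year; the small-stem AGB
share declines with stand age; LiDAR covers well under 1% of the extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.stats import rankdata

from . import allometry
from .allometry import FOREST_TYPES
from .corrections import Chronosequence, chrono_group
from .grids import Grid
from .sar import PLOT_RADIUS_M, extract_plot_features, gamma0_to_dn

__all__ = [
    "ScenarioConfig",
    "SyntheticLandscape",
    "ConfigurationError",
    "generate_landscape",
    "generate_tree_list",
    "simulate_backscatter",
    "small_tree_fraction",
    "default_scenario",
    "saturation_scenario",
]


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


#: monthly precipitation profile (mm), dry season November-April
_P_PROFILE = (25.0, 20.0, 15.0, 30.0, 95.0, 185.0, 205.0, 195.0, 215.0, 165.0, 70.0, 30.0)
#: monthly mean temperature profile (degC)
_T_PROFILE = (23.0, 24.0, 26.0, 28.0, 29.0, 29.0, 28.5, 28.5, 28.0, 26.5, 25.0, 23.5)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic landscape.

    ``n_units`` maps source ('NFI' | 'ICM') to per-forest-type unit counts
    *including* the units that will be flagged deforested
    (``n_deforested``).  ``chrono_params`` holds (asymptote Mg/ha, rate 1/yr)
    per chronosequence group; ``small_tree_curve`` = (mature share, juvenile
    extra share, e-folding age in years) parameterizes the declining
    small-stem AGB fraction f(age) = base + amp * exp(-age / tau);
    ``backscatter_params`` maps polarization to (floor dB, gain dB).
    """

    n_units: dict
    n_deforested: dict = field(default_factory=lambda: {"NFI": 0, "ICM": 0})
    age_range: tuple = (2.0, 80.0)
    chrono_params: dict = field(
        default_factory=lambda: {"deciduous_group": (200.0, 0.06), "semi_evergreen": (300.0, 0.05)}
    )
    small_tree_curve: tuple = (0.05, 0.40, 20.0)
    backscatter_params: dict = field(
        default_factory=lambda: {"HH": (-11.0, 4.0), "HV": (-20.0, 8.0)}
    )
    saturation_agb: float = 150.0
    speckle_looks: float | None = 9.0
    nfi_years: tuple = (2009, 2014)
    icm_year: int = 2015
    grid: Grid = field(default_factory=lambda: Grid(400, 400, px=25.0))
    latitude_deg: float = 20.0
    n_stations: int = 70
    n_incomplete_stations: int = 10
    lidar_coverage_fraction: float = 0.009
    lidar_placement: str = "spanning"  # 'spanning' | 'high_agb'
    lidar_metric_noise: float = 0.03
    unit_agb_cv: float = 0.10
    n_chrono_obs: int = 40
    chrono_obs_noise: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        for src, per_type in self.n_units.items():
            for ft, k in per_type.items():
                if ft not in FOREST_TYPES:
                    raise ConfigurationError(f"n_units: unknown forest type {ft!r}")
                if k < 0:
                    raise ConfigurationError(f"n_units[{src}][{ft}] must be >= 0")
        if sum(sum(v.values()) for v in self.n_units.values()) <= 0:
            raise ConfigurationError("n_units: at least one unit is required")
        if self.saturation_agb <= 0:
            raise ConfigurationError("saturation_agb must be positive")
        base, amp, tau = self.small_tree_curve
        if base < 0 or amp < 0 or base + amp >= 1 or tau <= 0:
            raise ConfigurationError(
                "small_tree_curve must give fractions in [0, 1) non-increasing with age"
            )
        if self.speckle_looks is not None and self.speckle_looks <= 0:
            raise ConfigurationError("speckle_looks must be positive (or None to disable)")
        if self.lidar_coverage_fraction < 0 or self.lidar_coverage_fraction >= 0.05:
            raise ConfigurationError("lidar_coverage_fraction must be small and non-negative")
        if self.lidar_placement not in ("spanning", "high_agb"):
            raise ConfigurationError(f"unknown lidar_placement {self.lidar_placement!r}")
        if self.nfi_years[0] > self.nfi_years[1] or self.nfi_years[1] > self.icm_year:
            raise ConfigurationError("nfi_years must precede (or reach) the ICM year")


@dataclass
class SyntheticLandscape:
    """One realised study system plus its generating configuration."""

    config: ScenarioConfig
    grid: Grid
    forest_type_raster: np.ndarray  # int codes indexing FOREST_TYPES
    age_raster: np.ndarray
    agb_truth_raster: np.ndarray  # 2015 baseline truth, Mg/ha
    units: pd.DataFrame
    trees: pd.DataFrame  # observed records (NFI lists lack small stems)
    trees_full: pd.DataFrame  # including the unobserved small stems
    sar_dn: dict
    stations: pd.DataFrame
    lidar_mask: np.ndarray
    lidar_metric_rasters: dict
    lidar_unit_metrics: pd.DataFrame
    chrono_obs: pd.DataFrame

    @property
    def chrono_models(self) -> dict:
        """The generating (true) chronosequence curves."""
        return {
            grp: Chronosequence(asymptote=a, rate=r)
            for grp, (a, r) in self.config.chrono_params.items()
        }


def small_tree_fraction(age, curve) -> np.ndarray:
    """Share of plot AGB in stems below the 7.5 cm inventory threshold."""
    base, amp, tau = curve
    return base + amp * np.exp(-np.asarray(age, dtype=float) / tau)


# --- tree-list realisation -------------------------------------------------


def _height_from_dbh(dbh):
    return np.minimum(35.0, 1.3 + 1.6 * np.asarray(dbh, dtype=float) ** 0.58)


_CLOSING_DENSITY = 0.62


def _stem_kg(dbh, forest_type, life_form="tree", density=_CLOSING_DENSITY):
    eq = allometry.select_equation(life_form, forest_type, dbh)
    return float(
        allometry.compute_tree_agb(
            eq, dbh=dbh, height=float(_height_from_dbh(dbh)), density=density
        )
    )


def _closing_stem(rem_kg, forest_type, lo, hi):
    """DBH in [lo, hi] whose deterministic-height biomass equals rem_kg."""
    f = lambda d: _stem_kg(d, forest_type) - rem_kg
    if f(lo) > 0 or f(hi) < 0:
        return None
    return brentq(f, lo, hi, xtol=1e-10)


def _sample_stem_pool(
    rng, forest_type, target_kg, dbh_sampler, dbh_bounds, tol_kg,
    typical_dbh, close_dbh_max=None, liana_p=0.0, palm_p=0.0,
):
    """Sample stems until their biomass hits target_kg within tol_kg.

    Stems are drawn from the pool's size distribution; once the remainder
    is small enough, a final 'closing' stem's DBH is solved by bisection so
    the pool total lands on target without distorting the size distribution
    with outsized stems.
    """
    lo, hi = dbh_bounds
    close_hi = min(close_dbh_max or hi, hi)
    stems = []  # (dbh, height, density, life_form, kg)
    total = 0.0
    if target_kg <= tol_kg:
        return stems
    kg_close_hi = _stem_kg(close_hi, forest_type)
    kg_lo = _stem_kg(lo, forest_type)
    guard = 0
    while True:
        guard += 1
        if guard > 20000:
            raise GenerationError("tree-list realisation failed to converge")
        rem = target_kg - total
        if rem <= tol_kg:
            break
        if rem <= kg_close_hi:
            close = _closing_stem(rem, forest_type, lo, close_hi)
            if close is not None:
                stems.append(
                    (close, float(_height_from_dbh(close)), _CLOSING_DENSITY, "tree",
                     _stem_kg(close, forest_type))
                )
                break
            # remainder in an unreachable gap or below the smallest stem
            if not stems:
                break  # accept the shortfall on a near-zero target
            d, h, dens, lf, kg = stems.pop(rng.integers(len(stems)))
            total -= kg
            continue
        n_draw = max(4, int(rem / max(_stem_kg(typical_dbh, forest_type), 1.0)))
        dbh = dbh_sampler(rng, n_draw)
        u = rng.random(n_draw)
        life = np.where(u < liana_p, "liana", np.where(u < liana_p + palm_p, "palm", "tree"))
        height = _height_from_dbh(dbh) * np.exp(rng.normal(0, 0.08, n_draw))
        height = np.clip(height, 1.5, 35.0)
        dens = np.clip(rng.normal(0.62, 0.10, n_draw), 0.25, 1.05)
        for d, h, rho, lf in zip(dbh, height, dens, life):
            if lf == "palm" and d < 10.0:
                lf = "tree"
            eq = allometry.select_equation(lf, forest_type, float(d))
            kg = float(allometry.compute_tree_agb(eq, dbh=float(d), height=float(h), density=float(rho)))
            if total + kg > target_kg:
                continue  # would overshoot; leave room for the closing stem
            stems.append((float(d), float(h), float(rho), lf, kg))
            total += kg
            if target_kg - total <= kg_lo:
                break
    return stems


def generate_tree_list(
    target_agb: float,
    forest_type: str,
    small_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tree records of one sampling unit realising a plot-level AGB target.

    The summed allometric plot AGB of the list matches ``target_agb``
    (Mg/ha) within 1%, with the configured share coming from nested-subplot
    stems below 7.5 cm DBH (within 0.02).  Large stems live in the four
    400 m^2 plots (subplot_id p1-p4), small stems in the 80 m^2 nested
    subplot.
    """
    if target_agb < 0:
        raise GenerationError("target AGB must be non-negative")
    if not 0 <= small_fraction < 1:
        raise GenerationError("small_fraction must be in [0, 1)")
    if target_agb == 0:
        if small_fraction > 0:
            raise GenerationError("cannot realise a small-stem share of zero biomass")
        return _empty_tree_frame()

    large_kg = target_agb * (1.0 - small_fraction) * 1000.0 * allometry.AREA_LARGE_M2 / 1e4
    small_kg = target_agb * small_fraction * 1000.0 * allometry.AREA_NESTED_M2 / 1e4
    tol = 0.004 * (large_kg + small_kg * (allometry.AREA_LARGE_M2 / allometry.AREA_NESTED_M2))

    large = _sample_stem_pool(
        rng, forest_type, large_kg,
        dbh_sampler=lambda r, n: np.minimum(7.5 + r.exponential(9.0, n), 119.0),
        dbh_bounds=(7.5, 119.0),
        tol_kg=max(tol * 0.5, 1e-6),
        typical_dbh=16.0,
        close_dbh_max=35.0,
        palm_p=0.02,
    )
    small = _sample_stem_pool(
        rng, forest_type, small_kg,
        dbh_sampler=lambda r, n: np.minimum(2.5 + r.exponential(1.5, n), 7.49),
        dbh_bounds=(2.5, 7.49),
        tol_kg=max(tol * 0.5 * allometry.AREA_NESTED_M2 / allometry.AREA_LARGE_M2, 1e-6),
        typical_dbh=4.0,
        liana_p=0.10,
    )
    rows = []
    for d, h, rho, lf, kg in large:
        rows.append((f"p{rng.integers(1, 5)}", d, h, rho, lf))
    for d, h, rho, lf, kg in small:
        rows.append(("nested", d, h, rho, lf))
    if not rows:
        return _empty_tree_frame()
    df = pd.DataFrame(rows, columns=["subplot_id", "dbh_cm", "height_m", "wood_density", "life_form"])
    k = rng.integers(0, 400, len(df))
    df["species"] = [f"sp{v:03d}" for v in k]
    df["genus"] = [f"gen{v // 8:02d}" for v in k]
    return df


def _empty_tree_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["subplot_id", "dbh_cm", "height_m", "wood_density", "life_form", "species", "genus"]
    )


# --- rasters ---------------------------------------------------------------


def simulate_backscatter(
    agb_raster: np.ndarray,
    params: dict,
    saturation_agb: float,
    speckle_looks: float | None,
    rng: np.random.Generator | None = None,
) -> dict:
    """HH/HV digital-number rasters from an AGB truth raster.

    Mean backscatter follows gamma0 = floor + gain * (1 - exp(-AGB /
    saturation)); multiplicative speckle is drawn per pixel from a gamma
    distribution with the stated equivalent number of looks on the linear
    power scale; digital numbers invert the calibration equation.
    """
    agb = np.asarray(agb_raster, dtype=float)
    if np.nanmin(agb) < 0:
        raise ValueError("AGB raster must be non-negative")
    if speckle_looks is not None and speckle_looks <= 0:
        raise ConfigurationError("speckle_looks must be positive")
    out = {}
    for pol, (floor, gain) in params.items():
        g_db = floor + gain * (1.0 - np.exp(-agb / saturation_agb))
        if speckle_looks is not None:
            if rng is None:
                raise ValueError("speckle requires a random generator")
            power = 10.0 ** (g_db / 10.0)
            power = power * rng.gamma(speckle_looks, 1.0 / speckle_looks, size=agb.shape)
            g_db = 10.0 * np.log10(power)
        out[pol] = gamma0_to_dn(g_db)
    return out


def _forest_type_raster(grid: Grid) -> np.ndarray:
    codes = np.zeros(grid.shape, dtype=int)
    third = grid.ncols // 3
    codes[:, third : 2 * third] = 1
    codes[:, 2 * third :] = 2
    return codes


def _age_raster(grid: Grid, age_range, rng) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=10.0, mode="nearest")
    grad = np.linspace(0.0, 1.5, grid.ncols)[None, :] * np.std(noise) * 2.0
    fld = noise + grad
    ranks = rankdata(fld.ravel(), method="average") / (fld.size + 1)
    lo, hi = age_range
    return (lo + ranks * (hi - lo)).reshape(grid.shape)


def _lidar_mask(grid: Grid, cfg: ScenarioConfig, age: np.ndarray, types: np.ndarray) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    target_px = int(round(cfg.lidar_coverage_fraction * grid.nrows * grid.ncols))
    if target_px == 0:
        return mask
    strip_h = 10  # rows per strip: tall enough that the regular 1-ha plot
    # grid of the upscaling stage always intersects it
    strip_rows = np.arange(4, grid.nrows - 4 - strip_h, strip_h + 4)
    if cfg.lidar_placement == "spanning":
        # one transect per forest-type band, at staggered rows
        per_band = int(np.ceil(target_px / 3))
        for i in range(3):
            cols = np.where((types == i).any(axis=0))[0]
            lo, hi = cols.min() + 2, cols.max() - 2
            w = int(np.clip(np.ceil(per_band / strip_h), strip_h, hi - lo))
            r = strip_rows[(2 * i + 1) * len(strip_rows) // 6]
            mask[r : r + strip_h, lo : lo + w] = True
    else:  # transects confined to the oldest semi-evergreen stands
        cols = np.where((types == 2).any(axis=0))[0]
        lo, hi = cols.min() + 2, cols.max() - 2
        strip_age = np.array([age[r : r + strip_h, lo:hi].mean() for r in strip_rows])
        for r in strip_rows[np.argsort(-strip_age)]:
            placed = int(mask.sum())
            if placed >= target_px:
                break
            w = int(np.clip(np.ceil((target_px - placed) / strip_h), strip_h, hi - lo))
            mask[r : r + strip_h, lo : lo + w] = True
    return mask


#: height percentiles, in rank order, as fractions of top-canopy height
_LIDAR_PERCENTILES = (("h_p25", 0.35), ("h_p50", 0.55), ("h_p75", 0.75),
                      ("h_p95", 0.95), ("h_max", 1.0))


def _lidar_metric_rasters(agb: np.ndarray, mask: np.ndarray, noise: float, rng) -> dict:
    """Noisy monotone transforms of the true canopy state inside the mask."""
    top = 1.5 + 33.0 * agb / (agb + 150.0)
    stack = [top * s * np.exp(rng.normal(0.0, noise, agb.shape)) for _, s in _LIDAR_PERCENTILES]
    stack = np.sort(np.stack(stack), axis=0)  # keep percentiles ordered per pixel
    out = {name: np.where(mask, r, np.nan) for (name, _), r in zip(_LIDAR_PERCENTILES, stack)}
    out["h_mean"] = np.where(mask, 0.60 * top * np.exp(rng.normal(0.0, noise, agb.shape)), np.nan)
    out["h_var"] = np.where(mask, (0.22 * top) ** 2 * np.exp(rng.normal(0.0, noise, agb.shape)), np.nan)
    cover = agb / (agb + 40.0) * np.exp(rng.normal(0.0, noise, agb.shape))
    out["cover"] = np.where(mask, np.clip(cover, 0.0, 1.0), np.nan)
    return out


# --- landscape assembly ----------------------------------------------------


def _place_units(cfg: ScenarioConfig, grid: Grid, types: np.ndarray, lidar: np.ndarray, rng):
    """Choose distinct unit pixels per source and forest type.

    ICM units go inside the LiDAR-covered part of their forest-type band when
    that intersection exists (the monitoring plots sit where the LiDAR flew);
    otherwise anywhere in the band.  A 3-pixel margin keeps 1-ha footprints
    complete.
    """
    margin = 3
    rows_ok = np.zeros(grid.shape, dtype=bool)
    rows_ok[margin:-margin, margin:-margin] = True
    taken = np.zeros(grid.shape, dtype=bool)
    recs = []
    for src in ("NFI", "ICM"):
        per_type = cfg.n_units.get(src, {})
        for code, ftype in enumerate(FOREST_TYPES):
            k = per_type.get(ftype, 0)
            if k == 0:
                continue
            band = (types == code) & rows_ok
            pool = band & lidar if src == "ICM" and (band & lidar).sum() >= k else band
            cand = np.flatnonzero(pool & ~taken)
            if len(cand) < k:
                raise GenerationError(f"not enough room for {k} {src} units in {ftype}")
            chosen = rng.choice(cand, size=k, replace=False)
            taken.ravel()[chosen] = True
            for flat in chosen:
                r, c = np.unravel_index(flat, grid.shape)
                recs.append({"source": src, "forest_type": ftype, "row": r, "col": c})
    return pd.DataFrame(recs)


def _station_table(cfg: ScenarioConfig, grid: Grid, rng) -> pd.DataFrame:
    w = grid.ncols * grid.px
    h = grid.nrows * grid.px
    sx = grid.x0 + rng.random(cfg.n_stations) * w
    sy = grid.y0 + rng.random(cfg.n_stations) * h
    rows = []
    incomplete = rng.choice(cfg.n_stations, size=cfg.n_incomplete_stations, replace=False)
    for i in range(cfg.n_stations):
        drop_month = rng.integers(1, 13) if i in incomplete else None
        for m in range(1, 13):
            if m == drop_month:
                continue
            frac = (sx[i] - grid.x0) / w
            p = _P_PROFILE[m - 1] * (0.75 + 0.5 * frac) + rng.normal(0.0, 4.0)
            t = _T_PROFILE[m - 1] - 1.5 * frac + rng.normal(0.0, 0.25)
            rows.append(
                {"station_id": f"st{i:03d}", "x": sx[i], "y": sy[i], "month": m,
                 "precip_mm": max(p, 0.0), "temp_c": t}
            )
    return pd.DataFrame(rows)


def climate_field(cfg: ScenarioConfig, grid: Grid, variable: str, month: int) -> np.ndarray:
    """Noise-free climate surface the stations sample (for oracle checks)."""
    xs, _ = grid.coord_mesh()
    frac = (xs - grid.x0) / (grid.ncols * grid.px)
    if variable == "precip_mm":
        return _P_PROFILE[month - 1] * (0.75 + 0.5 * frac)
    if variable == "temp_c":
        return _T_PROFILE[month - 1] - 1.5 * frac
    raise ValueError(f"unknown variable {variable!r}")


def generate_landscape(config: ScenarioConfig) -> SyntheticLandscape:
    """Realise one synthetic study system; fully determined by config.seed."""
    config.validate()
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    r_age, r_units, r_trees, r_sar, r_clim, r_lidar, r_chrono = rng.spawn(7)

    types = _forest_type_raster(grid)
    age = _age_raster(grid, config.age_range, r_age)
    chrono = {
        grp: Chronosequence(asymptote=a, rate=r) for grp, (a, r) in config.chrono_params.items()
    }
    group_of = {ft: chrono_group(ft) for ft in FOREST_TYPES}
    truth = np.empty(grid.shape)
    for code, ftype in enumerate(FOREST_TYPES):
        m = types == code
        truth[m] = chrono[group_of[ftype]].predict(age[m])

    lidar_mask = _lidar_mask(grid, config, age, types)
    placed = _place_units(config, grid, types, lidar_mask, r_units)

    unit_rows, obs_trees, full_trees = [], [], []
    for src in ("NFI", "ICM"):
        sub = placed.loc[placed["source"] == src].reset_index(drop=True)
        n_def = config.n_deforested.get(src, 0)
        deforested_idx = set(
            r_units.choice(len(sub), size=min(n_def, len(sub)), replace=False).tolist()
        ) if n_def else set()
        for i, row in sub.iterrows():
            uid = f"{src}_{i:04d}"
            r, c = int(row["row"]), int(row["col"])
            x, y = grid.xy(r, c)
            age15 = float(age[r, c])
            model = chrono[group_of[row["forest_type"]]]
            # microsite factor: the 1-ha stand deviates from the landscape
            # age-AGB pattern its pixel follows (plot/pixel mismatch)
            microsite = float(np.exp(r_units.normal(0.0, config.unit_agb_cv)))
            truth15 = float(model.predict(age15)) * microsite
            if src == "NFI":
                year = int(r_units.integers(config.nfi_years[0], config.nfi_years[1] + 1))
            else:
                year = config.icm_year
            age_meas = max(age15 - (config.icm_year - year), 0.5)
            truth_meas = float(model.predict(age_meas)) * microsite
            frac = float(small_tree_fraction(age_meas, config.small_tree_curve))
            deforested = i in deforested_idx
            unit_rows.append(
                {"unit_id": uid, "source": src, "forest_type": row["forest_type"],
                 "year_measured": year, "x": float(x), "y": float(y),
                 "deforested": deforested, "age_2015": age15,
                 "truth_agb_2015": truth15, "truth_agb_meas": truth_meas,
                 "small_fraction": frac}
            )
            if deforested:
                continue
            tl = generate_tree_list(truth_meas, row["forest_type"], frac, r_trees)
            tl.insert(0, "unit_id", uid)
            full_trees.append(tl)
            obs = tl if src == "ICM" else tl.loc[tl["subplot_id"] != "nested"]
            obs_trees.append(obs)

    units = pd.DataFrame(unit_rows)
    trees = pd.concat(obs_trees, ignore_index=True) if obs_trees else _empty_tree_frame()
    trees_full = pd.concat(full_trees, ignore_index=True) if full_trees else _empty_tree_frame()

    sar_dn = simulate_backscatter(
        truth, config.backscatter_params, config.saturation_agb, config.speckle_looks, r_sar
    )
    stations = _station_table(config, grid, r_clim)

    metric_rasters = _lidar_metric_rasters(truth, lidar_mask, config.lidar_metric_noise, r_lidar)
    in_lidar = units.loc[~units["deforested"]].copy()
    if len(in_lidar):
        rr, cc = grid.rowcol(in_lidar["x"].to_numpy(), in_lidar["y"].to_numpy())
        in_lidar = in_lidar.loc[lidar_mask[rr, cc]]
    if len(in_lidar):
        unit_metrics = extract_plot_features(metric_rasters, grid, in_lidar, PLOT_RADIUS_M)
    else:
        unit_metrics = pd.DataFrame(columns=["unit_id"])

    chrono_rows = []
    for grp, model in chrono.items():
        ages = r_chrono.uniform(1.0, config.age_range[1] * 1.1, config.n_chrono_obs)
        vals = np.maximum(
            model.predict(ages) + r_chrono.normal(0.0, config.chrono_obs_noise, ages.size), 0.0
        )
        for a, v in zip(ages, vals):
            chrono_rows.append({"group": grp, "age": float(a), "agb": float(v)})

    return SyntheticLandscape(
        config=config, grid=grid, forest_type_raster=types, age_raster=age,
        agb_truth_raster=truth, units=units, trees=trees, trees_full=trees_full,
        sar_dn=sar_dn, stations=stations, lidar_mask=lidar_mask,
        lidar_metric_rasters=metric_rasters, lidar_unit_metrics=unit_metrics,
        chrono_obs=pd.DataFrame(chrono_rows),
    )


# --- preset scenarios ------------------------------------------------------


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """Mirrors the study's inventory: 232 NFI units (deciduous forest with a
    quarter the samples of the other types) of which 14 are deforested by the
    2015 baseline, plus 80 ICM units of which 11 are deforested, leaving
    218 + 69 = 287 retained units."""
    return ScenarioConfig(
        n_units={
            "NFI": {"deciduous": 40, "semi_deciduous": 96, "semi_evergreen": 96},
            "ICM": {"deciduous": 27, "semi_deciduous": 27, "semi_evergreen": 26},
        },
        n_deforested={"NFI": 14, "ICM": 11},
        seed=seed,
    )


def saturation_scenario(seed: int = 0, lidar_placement: str = "high_agb") -> ScenarioConfig:
    """A denser sampling campaign (520 field units) over the same landscape,
    with LiDAR strips confined to high-biomass semi-evergreen stands, used to
    probe backscatter saturation and the LiDAR-upscaling distribution shift."""
    return ScenarioConfig(
        n_units={
            "NFI": {"deciduous": 80, "semi_deciduous": 180, "semi_evergreen": 180},
            "ICM": {"deciduous": 10, "semi_deciduous": 10, "semi_evergreen": 60},
        },
        n_deforested={"NFI": 0, "ICM": 0},
        lidar_placement=lidar_placement,
        seed=seed,
    )
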