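"""End-to-end orchestration of the AGB-mapping analysis.

These helpers chain the library stages in the order the analysis prescribes:
plot AGB from allometry -> small-tree and stand-age corrections -> SAR/CWD
predictor layers -> plot-footprint feature extraction -> optional LiDAR
two-stage upscaling -> stratified split -> random-forest mapping approaches
validated on a shared held-out field set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allometry
from .climate import cwd_from_stations
from .corrections import assign_stratum, build_strata, correct_plots, fit_chronosequences
from .lidar import BestSubsetRegressor, loocv_validate, sample_lidar_plots
from .mapping import run_approach, stratified_split
from .sar import build_sar_stack, extract_plot_features
from .synthetic import SyntheticLandscape

__all__ = [
    "observed_plot_agb",
    "corrected_field_plots",
    "predictor_layers",
    "feature_matrix",
    "lidar_upscaling_stage",
    "mapping_experiment",
    "BACKSCATTER_FEATURES",
]

#: the backscatter-only predictor set (no textures, no climate)
BACKSCATTER_FEATURES = ["HH", "HV", "NDBI"]


def observed_plot_agb(landscape: SyntheticLandscape) -> pd.DataFrame:
    """Plot-level AGB of the retained (non-deforested) units, as observed:
    NFI units carry only large-stem AGB, ICM units both components."""
    return allometry.compute_plot_agb(landscape.units, landscape.trees)


def corrected_field_plots(
    landscape: SyntheticLandscape,
    small_tree: bool = True,
    age: bool = True,
    refit_chronosequence: bool = True,
) -> pd.DataFrame:
    """Field-plot table with corrections applied and strata assigned.

    NFI plots receive the small-tree and/or stand-age corrections; ICM plots
    (measured at the baseline year with the nested subplot) pass through.
    The returned frame carries an ``agb`` response column, the stratum of
    each plot, and the unit coordinates.
    """
    plots = observed_plot_agb(landscape)
    nfi = plots.loc[plots["source"] == "NFI"].copy()
    icm = plots.loc[plots["source"] == "ICM"].copy()
    strata = build_strata(pd.concat([nfi, icm], ignore_index=True))
    if (small_tree or age) and len(nfi):
        models = (
            fit_chronosequences(landscape.chrono_obs)
            if refit_chronosequence
            else landscape.chrono_models
        )
        nfi = correct_plots(nfi, icm, models, small_tree=small_tree, age=age, strata=strata)
    out = pd.concat([nfi, icm], ignore_index=True)
    out["stratum"] = 0
    for ft, bp in strata.items():
        m = out["forest_type"] == ft
        out.loc[m, "stratum"] = assign_stratum(out.loc[m, "agb_large"], bp)
    out["agb"] = out["agb_total"]
    out["provenance"] = "field"
    return out


def predictor_layers(
    landscape: SyntheticLandscape,
    with_textures: bool = True,
    cwd_months=None,
    lee_noise_sd: float = 1.0,
) -> dict:
    """All predictor rasters: calibrated/despeckled backscatter, NDBI, the
    texture layers, and the kriged-climate CWD surface."""
    stack = build_sar_stack(
        landscape.sar_dn["HH"],
        landscape.sar_dn["HV"],
        landscape.grid,
        lee_noise_sd=lee_noise_sd,
        compute_textures=with_textures,
    )
    layers = stack.layers()
    clim = cwd_from_stations(
        landscape.stations, landscape.grid, landscape.config.latitude_deg, cwd_months
    )
    layers["CWD"] = clim["cwd"]
    return layers


def feature_matrix(
    landscape: SyntheticLandscape, plots: pd.DataFrame, layers: dict
) -> pd.DataFrame:
    """Join plot rows with their footprint-mean predictor values."""
    feats = extract_plot_features(layers, landscape.grid, plots)
    return plots.merge(feats.drop(columns=["footprint_coverage"]), on="unit_id")


def lidar_upscaling_stage(
    landscape: SyntheticLandscape,
    plots: pd.DataFrame,
    max_size: int = 5,
):
    """Stage-1 subset regression on the units inside the LiDAR coverage and
    stage-2 sampling of predicted-AGB plots over the covered area.

    Returns (model, loocv_report, lidar_plots).
    """
    metric_cols = list(landscape.lidar_metric_rasters)
    dat = landscape.lidar_unit_metrics.merge(plots[["unit_id", "agb"]], on="unit_id")
    if len(dat) < 10:
        raise ValueError("too few units inside the LiDAR coverage for stage 1")
    model = BestSubsetRegressor(max_size=max_size).fit(dat[metric_cols], dat["agb"].to_numpy())
    report = loocv_validate(model, dat[metric_cols], dat["agb"].to_numpy())
    lidar_plots = sample_lidar_plots(
        model, landscape.lidar_metric_rasters, landscape.grid, landscape.lidar_mask
    )
    return model, report, lidar_plots


def mapping_experiment(
    landscape: SyntheticLandscape,
    seed: int = 0,
    approaches=("field",),
    feature_sets: dict | None = None,
    with_textures: bool = True,
    n_trees: int = 500,
    split_fraction: float = 0.70,
) -> dict:
    """Run mapping approaches x predictor sets on one landscape.

    Returns a dict with the calibration/validation tables, the stage-1
    report when a LiDAR approach is requested, and
    ``results[(feature_set, approach)] = (model, ValidationReport)``.
    """
    plots = corrected_field_plots(landscape)
    layers = predictor_layers(landscape, with_textures=with_textures)
    fm = feature_matrix(landscape, plots, layers)
    cal, val = stratified_split(fm, split_fraction, seed)
    full = [c for c in fm.columns if c in layers]
    if feature_sets is None:
        feature_sets = {"full": None}
    feature_sets = {k: (full if v is None else v) for k, v in feature_sets.items()}
    out = {"calibration": cal, "validation": val, "results": {}}
    lidar_fm = None
    if any(a in ("lidar", "combined") for a in approaches):
        st1_model, st1_report, lidar_plots = lidar_upscaling_stage(landscape, fm)
        lidar_feats = extract_plot_features(layers, landscape.grid, lidar_plots)
        lidar_fm = lidar_plots.merge(
            lidar_feats.drop(columns=["footprint_coverage"]), on="unit_id"
        )
        out["stage1_model"] = st1_model
        out["stage1_report"] = st1_report
        out["lidar_plots"] = lidar_fm
    for fs_name, cols in feature_sets.items():
        for approach in approaches:
            model, report = run_approach(
                approach, cal, val, cols, lidar_plots=lidar_fm, n_trees=n_trees, seed=seed
            )
            out["results"][(fs_name, approach)] = (model, report)
    return out


def pipeline_recovery_run(seed: int, n_trees: int = 500) -> dict:
    """One replicate of the saturation-scenario recovery study.

    On the dense saturation scenario (LiDAR confined to high-AGB stands) it
    contrasts (i) the full predictor set against backscatter-only and
    (ii) the field- against the LiDAR-plots approach on the shared
    validation set; on the spanning-transect variant it evaluates the
    stage-1 LiDAR model by LOOCV.  Returns the summary quantities.
    """
    from .synthetic import generate_landscape, saturation_scenario

    ls = generate_landscape(saturation_scenario(seed=seed))
    exp = mapping_experiment(
        ls,
        seed=seed,
        approaches=("field", "lidar"),
        feature_sets={"full": None, "backscatter": BACKSCATTER_FEATURES},
        n_trees=n_trees,
    )
    model_full, rep_full = exp["results"][("full", "field")]
    rep_bs = exp["results"][("backscatter", "field")][1]
    rep_lidar = exp["results"][("full", "lidar")][1]
    imp = model_full.importances_

    ls_span = generate_landscape(saturation_scenario(seed=seed, lidar_placement="spanning"))
    plots = corrected_field_plots(ls_span)
    _, stage1, _ = lidar_upscaling_stage(ls_span, plots)

    return {
        "seed": seed,
        "rmse_field_full": rep_full.rmse,
        "rmse_field_backscatter": rep_bs.rmse,
        "bias_field": rep_full.bias,
        "bias_lidar": rep_lidar.bias,
        "r2_field_full": rep_full.r_squared,
        "pct_rmse_field_full": rep_full.pct_rmse,
        "stage1_loocv_r2": stage1.r_squared,
        "n_lidar_stage1": stage1.n,
        "importance_cwd": float(imp["CWD"]),
        "importance_hh": float(imp["HH"]),
    }
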