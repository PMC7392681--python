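"""Tree- and plot-level aboveground biomass (AGB) from allometric equations.

Six published allometric equations are used, routed by life form, forest type
and stem diameter (DBH, cm):

==================  =====================  ==========================
equation id         applies to             form
==================  =====================  ==========================
``ramirez_small``   deciduous / semi-      exp(-4.1392 + 0.99 ln(D^2 H) + 1.2268 rho)
                    deciduous tree, D<10
``chave_tree``      deciduous / semi-      rho exp(-0.667 + 1.784 lnD + 0.207 lnD^2
                    deciduous tree, D>=10          - 0.0281 lnD^3)
``guyot_small``     semi-evergreen tree,   exp(1.3636 lnD + 1.615 lnH - 2.9267)
                    D<10
``cairns_tree``     semi-evergreen tree,   exp(-2.12605 + 0.868 ln(D^2 H)
                    D>=10                      + 0.0939/2) (rho/0.7)
``chave_liana``     liana, D>=2.5          exp(0.049 + 2.053 lnD)
``frangi_palm``     palm                   -4.51 + 7.7 H
==================  =====================  ==========================

with D = DBH (cm), H = measured total height (m), rho = wood density
(g cm^-3).  All equations return kg of dry biomass per stem.

Plot-level AGB is expressed in Mg ha^-1.  A sampling unit consists of four
circular 400 m^2 plots (1600 m^2 total) in which stems with DBH >= 7.5 cm are
measured; intensive carbon-monitoring (ICM) units add one nested 80 m^2
subplot holding stems of 2.5-7.5 cm DBH.  National forest inventory (NFI)
units have no nested subplot, so their small-stem AGB is zero by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FOREST_TYPES",
    "DECIDUOUS_GROUP",
    "WoodDensityTable",
    "assign_wood_density",
    "select_equation",
    "compute_tree_agb",
    "tree_agb_frame",
    "compute_plot_agb",
    "AllometryError",
]

FOREST_TYPES = ("deciduous", "semi_deciduous", "semi_evergreen")
#: forest types sharing the deciduous-group tree equations and chronosequence
DECIDUOUS_GROUP = ("deciduous", "semi_deciduous")

#: inventory inclusion threshold of the main 400 m^2 plots (cm)
INVENTORY_DBH_MIN = 7.5
#: lower DBH bound of the nested 80 m^2 subplot (cm)
NESTED_DBH_MIN = 2.5
#: DBH threshold switching between small- and large-tree equations (cm)
EQ_DBH_SWITCH = 10.0

AREA_LARGE_M2 = 4 * 400.0
AREA_NESTED_M2 = 80.0


class AllometryError(ValueError):
    """Raised for unroutable records or unresolvable covariates."""


# --- tree-level equations (kg per stem) -----------------------------------


def _ramirez_small(dbh, height, dens):
    return np.exp(-4.1392 + 0.99 * np.log(dbh**2 * height) + 1.2268 * dens)


def _chave_tree(dbh, height, dens):
    ln = np.log(dbh)
    return dens * np.exp(-0.667 + 1.784 * ln + 0.207 * ln**2 - 0.0281 * ln**3)


def _guyot_small(dbh, height, dens):
    return np.exp(1.3636 * np.log(dbh) + 1.615 * np.log(height) - 2.9267)


def _cairns_tree(dbh, height, dens):
    return np.exp(-2.12605 + 0.868 * np.log(dbh**2 * height) + 0.0939 / 2.0) * (dens / 0.7)


def _chave_liana(dbh, height, dens):
    return np.exp(0.049 + 2.053 * np.log(dbh))


def _frangi_palm(dbh, height, dens):
    # linear in height; floored at zero for very short stems
    return np.maximum(-4.51 + 7.7 * height, 0.0)


EQUATIONS = {
    "ramirez_small": (_ramirez_small, ("dbh", "height", "density")),
    "chave_tree": (_chave_tree, ("dbh", "density")),
    "guyot_small": (_guyot_small, ("dbh", "height")),
    "cairns_tree": (_cairns_tree, ("dbh", "height", "density")),
    "chave_liana": (_chave_liana, ("dbh",)),
    "frangi_palm": (_frangi_palm, ("height",)),
}


def select_equation(life_form: str, forest_type: str, dbh: float) -> str:
    """Route a stem to its allometric equation.

    Lianas with DBH >= 2.5 cm always use the liana equation; palms use the
    palm equation (palms below the nominal 10 cm threshold are routed there
    anyway, since the formula only needs height, and logged).  Trees route by
    forest type and the 10 cm DBH switch.
    """
    if forest_type not in FOREST_TYPES:
        raise AllometryError(f"unknown forest type {forest_type!r}")
    if life_form == "liana":
        if dbh < NESTED_DBH_MIN:
            raise AllometryError(f"liana below {NESTED_DBH_MIN} cm DBH is unroutable")
        return "chave_liana"
    if life_form == "palm":
        if dbh < EQ_DBH_SWITCH:
            logger.debug("palm with DBH %.1f < 10 cm routed to palm equation", dbh)
        return "frangi_palm"
    if life_form == "tree":
        small = dbh < EQ_DBH_SWITCH
        if forest_type in DECIDUOUS_GROUP:
            return "ramirez_small" if small else "chave_tree"
        return "guyot_small" if small else "cairns_tree"
    raise AllometryError(f"unknown life form {life_form!r}")


def compute_tree_agb(equation_id: str, dbh=None, height=None, density=None):
    """Biomass (kg) of one stem or an array of stems for a given equation.

    Raises :class:`AllometryError` if a covariate the formula needs is
    missing (NaN).
    """
    fn, needs = EQUATIONS[equation_id]
    cov = {"dbh": dbh, "height": height, "density": density}
    for name in needs:
        v = cov[name]
        if v is None or np.any(np.isnan(np.asarray(v, dtype=float))):
            raise AllometryError(f"equation {equation_id} requires {name}")
    return fn(
        np.asarray(dbh, dtype=float) if dbh is not None else None,
        np.asarray(height, dtype=float) if height is not None else None,
        np.asarray(density, dtype=float) if density is not None else None,
    )


def tree_agb_frame(trees: pd.DataFrame, forest_type: str) -> pd.DataFrame:
    """Per-stem biomass for a tree table.

    ``trees`` needs columns ``dbh_cm``, ``height_m``, ``wood_density``,
    ``life_form``.  Returns a copy with ``equation`` and ``agb_kg`` columns.
    """
    out = trees.copy()
    eq = [
        select_equation(lf, forest_type, d)
        for lf, d in zip(out["life_form"], out["dbh_cm"])
    ]
    out["equation"] = eq
    agb = np.empty(len(out))
    for eq_id in set(eq):
        m = out["equation"] == eq_id
        agb[m.to_numpy()] = compute_tree_agb(
            eq_id,
            dbh=out.loc[m, "dbh_cm"].to_numpy(),
            height=out.loc[m, "height_m"].to_numpy(),
            density=out.loc[m, "wood_density"].to_numpy(),
        )
    out["agb_kg"] = agb
    return out


# --- wood density ----------------------------------------------------------


@dataclass
class WoodDensityTable:
    """Species/genus wood-density lookup (g cm^-3) with fallback hierarchy.

    Missing species resolve to the genus mean, then to the mean of the
    sampling unit's resolvable trees.
    """

    species: dict = field(default_factory=dict)
    genus_means: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = [s for s, d in self.species.items() if not 0 < d < 1.5]
        if bad:
            raise AllometryError(f"wood densities out of (0, 1.5): {bad[:5]}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WoodDensityTable":
        """Build from a table with columns species, genus, density_g_cm3."""
        sp = dict(zip(df["species"], df["density_g_cm3"]))
        gm = df.groupby("genus")["density_g_cm3"].mean().to_dict()
        return cls(species=sp, genus_means=gm)

    @classmethod
    def from_csv(cls, path) -> "WoodDensityTable":
        return cls.from_frame(pd.read_csv(path))


def assign_wood_density(trees: pd.DataFrame, table: WoodDensityTable) -> pd.DataFrame:
    """Fill the ``wood_density`` column via the species > genus > unit hierarchy.

    Returns a copy with ``wood_density`` completed and a ``density_source``
    column in {'measured', 'species', 'genus', 'unit'}.  A unit none of whose
    trees resolves at any level is a data error.
    """
    if not table.species and not table.genus_means:
        raise AllometryError("empty wood-density table")
    out = trees.copy()
    if "wood_density" not in out:
        out["wood_density"] = np.nan
    dens = out["wood_density"].to_numpy(dtype=float).copy()
    source = np.where(np.isnan(dens), "", "measured").astype(object)

    miss = np.isnan(dens)
    sp_val = out["species"].map(table.species).to_numpy(dtype=float)
    take = miss & ~np.isnan(sp_val)
    dens[take] = sp_val[take]
    source[take] = "species"

    miss = np.isnan(dens)
    gn_val = out["genus"].map(table.genus_means).to_numpy(dtype=float)
    take = miss & ~np.isnan(gn_val)
    dens[take] = gn_val[take]
    source[take] = "genus"

    out["wood_density"] = dens
    out["density_source"] = source
    # unit-level fallback: mean of the unit's trees resolved so far
    if np.isnan(dens).any():
        for uid, idx in out.groupby("unit_id").groups.items():
            vals = out.loc[idx, "wood_density"]
            if vals.isna().any():
                known = vals.dropna()
                if known.empty:
                    raise AllometryError(f"no wood density resolvable for unit {uid!r}")
                fill = known.mean()
                sel = idx[vals.isna().to_numpy()]
                out.loc[sel, "wood_density"] = fill
                out.loc[sel, "density_source"] = "unit"
    return out


# --- plot aggregation ------------------------------------------------------


def compute_plot_agb(
    units: pd.DataFrame,
    trees: pd.DataFrame,
    table: WoodDensityTable | None = None,
    check_design: bool = True,
) -> pd.DataFrame:
    """Plot-level AGB (Mg ha^-1) per sampling unit.

    ``units`` needs columns unit_id, source ('NFI'|'ICM'), forest_type and
    optionally deforested (bool); ``trees`` the tree-table columns keyed by
    unit_id, with ``subplot_id == 'nested'`` marking the 80 m^2 subplot.
    Deforested units are excluded (logged).  Returns a frame indexed like the
    retained units with columns agb_large, agb_small, agb_total.
    """
    units = units.copy()
    if "deforested" in units:
        dropped = units.loc[units["deforested"], "unit_id"].tolist()
        if dropped:
            logger.info("excluding %d deforested units: %s", len(dropped), dropped[:8])
        units = units.loc[~units["deforested"]]
    if table is not None:
        trees = assign_wood_density(trees, table)

    rows = []
    tree_groups = dict(iter(trees.groupby("unit_id"))) if len(trees) else {}
    for _, u in units.iterrows():
        tr = tree_groups.get(u["unit_id"])
        large_mg = small_mg = 0.0
        if tr is not None and len(tr):
            scored = tree_agb_frame(tr, u["forest_type"])
            nested = scored["subplot_id"] == "nested"
            if check_design and u["source"] == "NFI" and nested.any():
                raise AllometryError(
                    f"NFI unit {u['unit_id']!r} carries nested-subplot records"
                )
            big = scored.loc[~nested & (scored["dbh_cm"] >= INVENTORY_DBH_MIN)]
            sml = scored.loc[nested & (scored["dbh_cm"] < INVENTORY_DBH_MIN)]
            large_mg = big["agb_kg"].sum() / 1000.0 * (1e4 / AREA_LARGE_M2)
            small_mg = sml["agb_kg"].sum() / 1000.0 * (1e4 / AREA_NESTED_M2)
        rows.append(
            {
                "unit_id": u["unit_id"],
                "source": u["source"],
                "forest_type": u["forest_type"],
                "agb_large": large_mg,
                "agb_small": small_mg,
                "agb_total": large_mg + small_mg,
            }
        )
    out = pd.DataFrame(rows)
    for extra in ("year_measured", "x", "y"):
        if extra in units.columns:
            out[extra] = units[extra].to_numpy()
    return out
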