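"""Tree- and plot-level allometry against hand-evaluated oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdfagb import allometry
from tdfagb.allometry import (
    AllometryError,
    WoodDensityTable,
    assign_wood_density,
    compute_plot_agb,
    compute_tree_agb,
    select_equation,
)

# hand evaluations of the printed formulas, written before the implementation
HAND_CASES = [
    # (equation, kwargs, expected kg)
    ("chave_liana", dict(dbh=10.0), math.exp(0.049 + 2.053 * math.log(10.0))),
    ("frangi_palm", dict(height=1.0), -4.51 + 7.7 * 1.0),
    (
        "chave_tree",
        dict(dbh=20.0, density=0.7),
        0.7
        * math.exp(
            -0.667
            + 1.784 * math.log(20.0)
            + 0.207 * math.log(20.0) ** 2
            - 0.0281 * math.log(20.0) ** 3
        ),
    ),
    (
        "ramirez_small",
        dict(dbh=8.0, height=7.0, density=0.65),
        math.exp(-4.1392 + 0.99 * math.log(8.0**2 * 7.0) + 1.2268 * 0.65),
    ),
    (
        "guyot_small",
        dict(dbh=9.0, height=8.0),
        math.exp(1.3636 * math.log(9.0) + 1.615 * math.log(8.0) - 2.9267),
    ),
    (
        "cairns_tree",
        dict(dbh=25.0, height=14.0, density=0.6),
        math.exp(-2.12605 + 0.868 * math.log(25.0**2 * 14.0) + 0.0939 / 2) * (0.6 / 0.7),
    ),
]


@pytest.mark.parametrize("eq,kwargs,expected", HAND_CASES)
def test_equations_match_hand_evaluation(eq, kwargs, expected):
    got = float(compute_tree_agb(eq, **kwargs))
    assert got == pytest.approx(expected, rel=1e-6)
    assert got > 0


def test_liana_example_value():
    """A 10 cm liana weighs about 118.6 kg."""
    assert float(compute_tree_agb("chave_liana", dbh=10.0)) == pytest.approx(118.65, abs=0.01)


@pytest.mark.parametrize(
    "life_form,forest_type,dbh,expected",
    [
        ("tree", "semi_evergreen", 9.0, "guyot_small"),
        ("tree", "semi_evergreen", 10.0, "cairns_tree"),
        ("tree", "deciduous", 9.99, "ramirez_small"),
        ("tree", "deciduous", 10.0, "chave_tree"),  # threshold inclusive on >= 10
        ("tree", "semi_deciduous", 15.0, "chave_tree"),
        ("liana", "deciduous", 5.0, "chave_liana"),
        ("liana", "semi_evergreen", 50.0, "chave_liana"),
        ("palm", "deciduous", 12.0, "frangi_palm"),
        ("palm", "semi_deciduous", 5.0, "frangi_palm"),  # routed anyway, logged
    ],
)
def test_equation_routing(life_form, forest_type, dbh, expected):
    assert select_equation(life_form, forest_type, dbh) == expected


def test_missing_covariate_is_an_error():
    with pytest.raises(AllometryError, match="height"):
        compute_tree_agb("guyot_small", dbh=9.0, height=None)


def test_wood_density_hierarchy():
    table = WoodDensityTable.from_frame(
        pd.DataFrame(
            {
                "species": ["a1", "b1", "b2"],
                "genus": ["A", "B", "B"],
                "density_g_cm3": [0.5, 0.6, 0.8],
            }
        )
    )
    trees = pd.DataFrame(
        {
            "unit_id": ["u"] * 4,
            "species": ["a1", "b9", "zz", "zz2"],
            "genus": ["A", "B", "Z", "Z"],
            "wood_density": [np.nan, np.nan, np.nan, 0.9],
        }
    )
    out = assign_wood_density(trees, table)
    assert out.loc[0, "wood_density"] == 0.5  # species match
    assert out.loc[1, "wood_density"] == pytest.approx(0.7)  # genus mean of {0.6, 0.8}
    assert out.loc[3, "wood_density"] == 0.9 and out.loc[3, "density_source"] == "measured"
    # unit fallback: mean of the unit's resolved densities {0.5, 0.7, 0.9}
    assert out.loc[2, "wood_density"] == pytest.approx(0.7)
    assert out.loc[2, "density_source"] == "unit"


def test_wood_density_unresolvable_names_unit():
    table = WoodDensityTable(species={"x": 0.5}, genus_means={})
    trees = pd.DataFrame(
        {"unit_id": ["bad_unit"], "species": ["q"], "genus": ["Q"], "wood_density": [np.nan]}
    )
    with pytest.raises(AllometryError, match="bad_unit"):
        assign_wood_density(trees, table)


def test_plot_agb_area_scaling(simple_unit_tables):
    """One 10 cm liana in a 400 m^2 plot -> 118.65 kg over 1600 m^2 -> 0.7416 Mg/ha."""
    units, trees = simple_unit_tables
    est = compute_plot_agb(units, trees)
    expected = math.exp(0.049 + 2.053 * math.log(10.0)) / 1000.0 * (1e4 / 1600.0)
    assert est.loc[0, "agb_large"] == pytest.approx(expected, rel=1e-9)
    assert est.loc[0, "agb_small"] == 0.0
    assert expected == pytest.approx(0.7416, abs=5e-4)


def test_empty_unit_is_zero():
    units = pd.DataFrame(
        [{"unit_id": "e", "source": "NFI", "forest_type": "deciduous", "deforested": False}]
    )
    est = compute_plot_agb(units, pd.DataFrame(columns=["unit_id", "subplot_id", "dbh_cm"]))
    assert est.loc[0, "agb_total"] == 0.0


def test_nested_small_stem_scaling():
    """An ICM nested-subplot stem scales by 10000/80, not 10000/1600."""
    units = pd.DataFrame(
        [{"unit_id": "u", "source": "ICM", "forest_type": "semi_evergreen", "deforested": False}]
    )
    trees = pd.DataFrame(
        [
            {"unit_id": "u", "subplot_id": "nested", "species": "s", "genus": "g",
             "dbh_cm": 5.0, "height_m": 5.0, "wood_density": 0.6, "life_form": "tree"}
        ]
    )
    est = compute_plot_agb(units, trees)
    kg = math.exp(1.3636 * math.log(5.0) + 1.615 * math.log(5.0) - 2.9267)
    assert est.loc[0, "agb_small"] == pytest.approx(kg / 1000.0 * 125.0, rel=1e-9)
    assert est.loc[0, "agb_large"] == 0.0
    assert est.loc[0, "agb_total"] == est.loc[0, "agb_small"] + est.loc[0, "agb_large"]


def test_deforested_units_are_excluded():
    units = pd.DataFrame(
        [
            {"unit_id": "keep", "source": "NFI", "forest_type": "deciduous", "deforested": False},
            {"unit_id": "gone", "source": "NFI", "forest_type": "deciduous", "deforested": True},
        ]
    )
    est = compute_plot_agb(units, pd.DataFrame(columns=["unit_id", "subplot_id", "dbh_cm"]))
    assert list(est["unit_id"]) == ["keep"]


def test_nfi_with_nested_records_rejected(simple_unit_tables):
    units, trees = simple_unit_tables
    units = units.assign(source="NFI")
    trees = trees.assign(subplot_id="nested", dbh_cm=5.0)
    with pytest.raises(AllometryError, match="nested"):
        compute_plot_agb(units, trees)


@settings(deadline=None, max_examples=25)
@given(
    dbh=st.floats(2.5, 119.0),
    bump=st.floats(0.1, 20.0),
    eq=st.sampled_from(["chave_liana", "chave_tree", "ramirez_small", "guyot_small", "cairns_tree"]),
)
def test_tree_equations_monotone_in_dbh(dbh, bump, eq):
    """Bigger stems never weigh less (tree and liana equations)."""
    kw = dict(height=10.0, density=0.6)
    assert compute_tree_agb(eq, dbh=dbh + bump, **kw) >= compute_tree_agb(eq, dbh=dbh, **kw)


def test_plot_agb_additivity_and_doubling(tiny_landscape):
    """Plot AGB is additive over stems: doubling the stem list doubles it."""
    units = tiny_landscape.units.head(3)
    trees = tiny_landscape.trees[tiny_landscape.trees.unit_id.isin(units.unit_id)]
    one = compute_plot_agb(units, trees)
    two = compute_plot_agb(units, pd.concat([trees, trees], ignore_index=True))
    assert np.allclose(two["agb_total"], 2 * one["agb_total"])
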