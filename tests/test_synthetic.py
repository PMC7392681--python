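"""Synthetic study-system generator: determinism, realised targets,
backscatter model and configuration validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tdfagb import allometry
from tdfagb.sar import dn_to_gamma0
from tdfagb.synthetic import (
    ConfigurationError,
    GenerationError,
    generate_landscape,
    generate_tree_list,
    simulate_backscatter,
    small_tree_fraction,
)

from conftest import tiny_scenario


class TestDeterminism:
    def test_same_seed_identical_landscapes(self):
        a = generate_landscape(tiny_scenario(seed=42))
        b = generate_landscape(tiny_scenario(seed=42))
        pd.testing.assert_frame_equal(a.units, b.units)
        pd.testing.assert_frame_equal(a.trees, b.trees)
        pd.testing.assert_frame_equal(a.stations, b.stations)
        assert np.array_equal(a.sar_dn["HH"], b.sar_dn["HH"])
        assert np.array_equal(a.agb_truth_raster, b.agb_truth_raster)

    def test_different_seed_differs(self):
        a = generate_landscape(tiny_scenario(seed=1))
        b = generate_landscape(tiny_scenario(seed=2))
        assert not np.array_equal(a.sar_dn["HH"], b.sar_dn["HH"])

    def test_tree_list_reproducible_from_rng_state(self):
        a = generate_tree_list(120.0, "semi_evergreen", 0.15, np.random.default_rng(5))
        b = generate_tree_list(120.0, "semi_evergreen", 0.15, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)


class TestTreeLists:
    def _plot_agb(self, trees, ftype):
        units = pd.DataFrame(
            [{"unit_id": "u", "source": "ICM", "forest_type": ftype, "deforested": False}]
        )
        t = trees.copy()
        t.insert(0, "unit_id", "u")
        return allometry.compute_plot_agb(units, t).iloc[0]

    @pytest.mark.parametrize("ftype", ["deciduous", "semi_evergreen"])
    def test_target_and_small_share_realised(self, rng, ftype):
        """Recomputing AGB through the allometry module lands on the target
        within 1% with the configured small-stem share within 0.02."""
        trees = generate_tree_list(100.0, ftype, 0.2, rng)
        est = self._plot_agb(trees, ftype)
        assert 99.0 <= est["agb_total"] <= 101.0
        assert 0.18 <= est["agb_small"] / est["agb_total"] <= 0.22

    def test_zero_target_empty(self, rng):
        assert generate_tree_list(0.0, "deciduous", 0.0, rng).empty

    def test_zero_target_with_small_share_infeasible(self, rng):
        with pytest.raises(GenerationError):
            generate_tree_list(0.0, "deciduous", 0.3, rng)

    def test_biological_plausibility(self, rng):
        trees = generate_tree_list(180.0, "semi_deciduous", 0.25, rng)
        assert trees["dbh_cm"].between(2.5, 120.0).all()
        assert trees["height_m"].between(1.5, 35.0).all()
        assert trees["wood_density"].between(0.2, 1.1).all()
        nested = trees["subplot_id"] == "nested"
        assert trees.loc[nested, "dbh_cm"].max() < 7.5
        assert trees.loc[~nested, "dbh_cm"].min() >= 7.5


class TestBackscatterModel:
    params = {"HH": (-11.0, 4.0)}

    def test_zero_agb_is_floor(self):
        dn = simulate_backscatter(np.zeros((4, 4)), self.params, 150.0, None)
        assert np.allclose(dn_to_gamma0(dn["HH"]), -11.0, atol=1e-9)

    def test_saturation_point_closed_form(self):
        agb = np.full((2, 2), 150.0)
        dn = simulate_backscatter(agb, self.params, 150.0, None)
        assert np.allclose(dn_to_gamma0(dn["HH"]), -11.0 + 4.0 * (1 - np.exp(-1.0)))

    def test_asymptote(self):
        dn = simulate_backscatter(np.full((2, 2), 1e9), self.params, 150.0, None)
        assert np.allclose(dn_to_gamma0(dn["HH"]), -7.0)

    def test_roundtrip_without_speckle(self, rng):
        agb = rng.uniform(0, 300, (10, 10))
        dn = simulate_backscatter(agb, self.params, 150.0, None)
        expected = -11.0 + 4.0 * (1 - np.exp(-agb / 150.0))
        assert np.allclose(dn_to_gamma0(dn["HH"]), expected, atol=1e-6)

    def test_monotone_in_agb_without_speckle(self):
        agb = np.linspace(0, 400, 50).reshape(1, -1)
        g = dn_to_gamma0(simulate_backscatter(agb, self.params, 150.0, None)["HH"])
        assert np.all(np.diff(g[0]) >= 0)

    def test_invalid_looks(self, rng):
        with pytest.raises(ConfigurationError):
            simulate_backscatter(np.ones((2, 2)), self.params, 150.0, -1.0, rng)


class TestLandscapeStructure:
    def test_tree_lists_match_unit_truth(self, tiny_landscape):
        """Full tree lists reproduce each unit's AGB truth within 1%."""
        est = allometry.compute_plot_agb(
            tiny_landscape.units, tiny_landscape.trees_full, check_design=False
        )
        m = est.merge(tiny_landscape.units, on="unit_id")
        rel = (m["agb_total"] - m["truth_agb_meas"]).abs() / m["truth_agb_meas"]
        assert rel.max() < 0.01

    def test_nfi_units_have_no_nested_records(self, tiny_landscape):
        nfi = tiny_landscape.units.loc[tiny_landscape.units["source"] == "NFI", "unit_id"]
        obs = tiny_landscape.trees[tiny_landscape.trees["unit_id"].isin(nfi)]
        assert (obs["subplot_id"] != "nested").all()

    def test_lidar_coverage_below_one_percent(self, default_landscape):
        assert 0 < default_landscape.lidar_mask.mean() < 0.01

    def test_lidar_percentile_ordering(self, default_landscape):
        r = default_landscape.lidar_metric_rasters
        m = default_landscape.lidar_mask
        assert np.all(r["h_p25"][m] <= r["h_p50"][m])
        assert np.all(r["h_p50"][m] <= r["h_p75"][m])
        assert np.all(r["h_p75"][m] <= r["h_p95"][m])
        assert np.all(r["h_p95"][m] <= r["h_max"][m])

    def test_zero_small_fraction_curve(self):
        cfg = tiny_scenario(seed=3, small_tree_curve=(0.0, 0.0, 20.0))
        ls = generate_landscape(cfg)
        assert (ls.trees_full["subplot_id"] != "nested").all()

    def test_small_stem_share_tracks_configured_curve(self, default_landscape):
        """Measured small-stem shares follow the age curve within 0.03 on
        average across the retained units."""
        est = allometry.compute_plot_agb(
            default_landscape.units, default_landscape.trees_full, check_design=False
        )
        m = est.merge(default_landscape.units, on="unit_id")
        m = m[m["agb_total"] > 0]
        share = m["agb_small"] / m["agb_total"]
        expected = m["small_fraction"]
        assert len(m) >= 100
        assert (share - expected).abs().mean() < 0.03

    def test_truth_raster_follows_chronosequence(self, tiny_landscape):
        models = tiny_landscape.chrono_models
        types = tiny_landscape.forest_type_raster
        sel = types == 2  # semi-evergreen band
        expected = models["semi_evergreen"].predict(tiny_landscape.age_raster[sel])
        assert np.allclose(tiny_landscape.agb_truth_raster[sel], expected)


class TestConfigValidation:
    def test_bad_saturation(self):
        with pytest.raises(ConfigurationError, match="saturation"):
            tiny_scenario(saturation_agb=-5.0).validate()

    def test_bad_small_tree_curve(self):
        with pytest.raises(ConfigurationError, match="small_tree_curve"):
            tiny_scenario(small_tree_curve=(0.6, 0.5, 10.0)).validate()

    def test_bad_unit_counts(self):
        with pytest.raises(ConfigurationError, match="n_units"):
            tiny_scenario(n_units={"NFI": {"deciduous": -1}}).validate()

    def test_small_tree_fraction_non_increasing(self):
        ages = np.linspace(0, 100, 50)
        f = small_tree_fraction(ages, (0.05, 0.4, 20.0))
        assert np.all(np.diff(f) <= 0)
        assert np.all((f >= 0) & (f < 1))


def test_landscape_roundtrips_to_text(tmp_path, tiny_landscape):
    from tdfagb.grids import read_ascii_grid
    from tdfagb.io import write_landscape

    write_landscape(tiny_landscape, tmp_path)
    arr, grid = read_ascii_grid(tmp_path / "agb_truth.asc")
    assert np.allclose(arr, tiny_landscape.agb_truth_raster, atol=1e-5)
    assert grid.shape == tiny_landscape.grid.shape
    assert (tmp_path / "units.geojson").exists()
    assert (tmp_path / "scenario.json").exists()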