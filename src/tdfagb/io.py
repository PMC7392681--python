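"""Plain-text serialization of synthetic study systems.

Units round-trip as GeoJSON point features, tree lists and stations as CSV,
rasters as ESRI ASCII grids, and the scenario configuration as JSON —
everything re-readable by standard GIS / data tooling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .grids import Grid, write_ascii_grid
from .synthetic import SyntheticLandscape

__all__ = ["write_units_geojson", "write_landscape"]


def write_units_geojson(units, path) -> None:
    feats = []
    for _, u in units.iterrows():
        props = {k: (v.item() if hasattr(v, "item") else v) for k, v in u.items()
                 if k not in ("x", "y")}
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(u["x"]), float(u["y"])]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def _config_dict(config) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, Grid):
            v = dataclasses.asdict(v)
        out[f.name] = v
    return out


def write_landscape(landscape: SyntheticLandscape, out_dir) -> None:
    """Write a landscape's text artifacts into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_units_geojson(landscape.units, out / "units.geojson")
    landscape.trees.to_csv(out / "trees.csv", index=False)
    landscape.stations.to_csv(out / "stations.csv", index=False)
    landscape.chrono_obs.to_csv(out / "chronosequence_observations.csv", index=False)
    for pol, dn in landscape.sar_dn.items():
        write_ascii_grid(out / f"sar_dn_{pol.lower()}.asc", dn, landscape.grid)
    write_ascii_grid(out / "agb_truth.asc", landscape.agb_truth_raster, landscape.grid)
    write_ascii_grid(out / "lidar_mask.asc", landscape.lidar_mask.astype(float), landscape.grid)
    with open(out / "scenario.json", "w") as fh:
        json.dump(_config_dict(landscape.config), fh, indent=1, default=str)
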