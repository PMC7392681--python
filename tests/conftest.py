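import numpy as np
import pandas as pd
import pytest

from tdfagb.grids import Grid
from tdfagb.synthetic import ScenarioConfig, default_scenario, generate_landscape


def tiny_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """A miniature study system for fast structural tests."""
    base = dict(
        n_units={
            "NFI": {"deciduous": 6, "semi_deciduous": 6, "semi_evergreen": 6},
            "ICM": {"deciduous": 5, "semi_deciduous": 5, "semi_evergreen": 5},
        },
        n_deforested={"NFI": 2, "ICM": 1},
        grid=Grid(80, 80, px=25.0),
        n_stations=15,
        n_incomplete_stations=3,
        n_chrono_obs=25,
        seed=seed,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def tiny_landscape():
    return generate_landscape(tiny_scenario(seed=11))


@pytest.fixture(scope="session")
def default_landscape():
    """Full-size default study system (232 + 80 units, 25 deforested)."""
    return generate_landscape(default_scenario(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_unit_tables():
    """One ICM unit with one large liana-bearing plot and no small stems."""
    units = pd.DataFrame(
        [{"unit_id": "u1", "source": "ICM", "forest_type": "deciduous", "deforested": False}]
    )
    trees = pd.DataFrame(
        [
            {
                "unit_id": "u1",
                "subplot_id": "p1",
                "species": "spX",
                "genus": "genX",
                "dbh_cm": 10.0,
                "height_m": 8.0,
                "wood_density": 0.6,
                "life_form": "liana",
            }
        ]
    )
    return units, trees
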