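"""Shared synthetic fixtures: a small three-group landscape run end-to-end."""

import numpy as np
import pandas as pd
import pytest

import nestclust as nc
from nestclust import fixtures

EXTENT = (0.0, 0.0, 60_000.0, 60_000.0)
CELL = 1000.0


@pytest.fixture(scope="session")
def scenario():
    return fixtures.SyntheticScenario(
        seed=11,
        n_groups=3,
        sites_per_group=8,
        group_separation=30_000.0,
        covariate_effect=10.0,
        covariate_noise=0.5,
    )


@pytest.fixture(scope="session")
def landscape(scenario):
    resistance, rasters = fixtures.make_landscape(scenario, EXTENT, CELL)
    return resistance, rasters


@pytest.fixture(scope="session")
def sites(scenario):
    return fixtures.make_sites(scenario, EXTENT)


@pytest.fixture(scope="session")
def structure(sites, landscape):
    resistance, _ = landscape
    mst = nc.build_lcp_mst(sites, resistance)
    tiers = nc.decompose_tiers(mst, [15_000.0, None])
    return mst, tiers


@pytest.fixture(scope="session")
def features(sites, landscape):
    _, rasters = landscape
    return nc.feature_table(rasters, sites, radii=(0.0, 2000.0), statistics=("mean",))


@pytest.fixture(scope="session")
def level_configs():
    return [
        nc.LevelConfig(level_index=1, tier_index=1, size_range=(2, 4), mode="select"),
        nc.LevelConfig(level_index=2, tier_index=1, size_range=(2, 8), mode="inherit"),
        nc.LevelConfig(level_index=3, tier_index=2, size_range=(3, 3), mode="select"),
    ]


@pytest.fixture(scope="session")
def multilevel(sites, structure, features, level_configs):
    mst, tiers = structure
    levels = nc.run_hierarchy(
        sites, mst, tiers, features, level_configs, stop_count=1, max_combo=1
    )
    return levels


@pytest.fixture(scope="session")
def partitions(sites, multilevel):
    return nc.partition_levels(sites, multilevel)


def uniform_surface(n: int = 20, cell: float = 100.0) -> nc.Raster:
    return nc.Raster(np.ones((n, n)), (0.0, 0.0), cell)


def site_table(coords, **extra) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "site_id": list(range(len(coords))),
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
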