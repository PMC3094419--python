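import numpy as np
import pandas as pd
import pytest

from airlur.synth import CampaignConfig, RegionConfig, generate_region, place_sites
from airlur.types import LandUseGrid, PopulationGrid, Region, RoadNetwork, RoadSegment


@pytest.fixture(scope="session")
def small_region_config():
    """A compact region for unit tests; full-size runs live in acceptance tests."""
    return RegionConfig(
        width=3000.0,
        height=3000.0,
        road_density={"national": 0.2, "provincial": 0.4, "municipal": 1.2},
        cell_size=20.0,
        coarse_factor=5,
        population_total=30000.0,
    )


@pytest.fixture(scope="session")
def small_region(small_region_config):
    return generate_region(small_region_config, seed=7)


@pytest.fixture(scope="session")
def small_campaign_config():
    return CampaignConfig(
        site_counts={"traffic": 6, "urban_background": 10, "rural": 4, "rural_external": 4},
        n_periods=4,
        missing_rate=0.1,
        rural_min_road_distance=150.0,
    )


@pytest.fixture(scope="session")
def small_sites(small_region, small_campaign_config):
    return place_sites(small_region, small_campaign_config, "facade", seed=3)


def single_road_region(flow: float = 10000.0, size: float = 2000.0) -> Region:
    """Hand-built region: one straight west-east road through the middle."""
    seg = RoadSegment(
        id="r0",
        vertices=np.array([[0.0, size / 2], [size, size / 2]]),
        flow=flow,
        heavy_fraction=0.1,
        authority="provincial",
        has_count_data=True,
    )
    n = int(size / 100)
    landuse = LandUseGrid((0, 0), 100.0, np.ones((n, n), dtype=np.int32), {1: "residential"})
    population = PopulationGrid((0, 0), 100.0, np.zeros((n, n)))
    return Region(
        roads=RoadNetwork([seg]),
        landuse=landuse,
        landuse_coarse=landuse,
        population=population,
        extent=(0.0, 0.0, size, size),
    )


@pytest.fixture()
def one_road_region():
    return single_road_region()


def make_site_table(xy, site_types, observations=None, protocol="facade", prefix="S"):
    """Small helper to build site tables for direct unit tests."""
    df = pd.DataFrame(
        {
            "site_id": [f"{prefix}{i:02d}" for i in range(len(xy))],
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "site_type": site_types,
            "protocol": protocol,
        }
    )
    if observations is not None:
        obs = np.asarray(observations, dtype=float)
        for j in range(obs.shape[1]):
            df[f"period_{j + 1}"] = obs[:, j]
    return df
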