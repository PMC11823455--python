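import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from nh3ineq import GridSpec, SceneConfig
from nh3ineq.inequality import BlockGroups
from nh3ineq.oversampling import PIXEL_COLUMNS


def make_pixels(
    lat,
    lon,
    column,
    uncertainty=1.0,
    semi_major=6.0,
    semi_minor=6.0,
    orientation=0.0,
    cloud=0.0,
    sensitivity=True,
    platform="A",
):
    """Assemble a pixel table from broadcastable per-field values."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = len(lat)

    def full(x):
        return np.broadcast_to(np.asarray(x), (n,)).copy()

    return pd.DataFrame(
        {
            "time": pd.Timestamp("2016-06-01 09:30"),
            "lat": lat,
            "lon": full(lon).astype(float),
            "semi_major_km": full(semi_major).astype(float),
            "semi_minor_km": full(semi_minor).astype(float),
            "orientation_deg": full(orientation).astype(float),
            "column": full(column).astype(float),
            "uncertainty": full(uncertainty).astype(float),
            "cloud_fraction": full(cloud).astype(float),
            "sensitivity_ok": full(sensitivity).astype(bool),
            "platform": platform,
        }
    )[PIXEL_COLUMNS]


@pytest.fixture
def small_grid():
    return GridSpec(lat0=35.005, lon0=-78.995, n_lat=40, n_lon=40, spacing_deg=0.01)


@pytest.fixture
def small_scene_config():
    """A compact scene for fast unit tests."""
    return SceneConfig(
        region_bounds=(35.0, 35.4, -79.0, -78.6),
        n_facilities=5,
        n_facility_clusters=2,
        blockgroup_grid_n=8,
        seed=0,
    )


def square_blockgroups(lat_min, lon_min, n, size_deg):
    """n x n square tessellation starting at the lower-left corner."""
    ids, polys = [], []
    for i in range(n):
        for j in range(n):
            ids.append(f"bg_{i}_{j}")
            polys.append(
                box(
                    lon_min + j * size_deg,
                    lat_min + i * size_deg,
                    lon_min + (j + 1) * size_deg,
                    lat_min + (i + 1) * size_deg,
                )
            )
    return BlockGroups(ids, polys)


def demographics_from_counts(counts: dict) -> pd.DataFrame:
    """counts: {blockgroup_id: {group: population}} -> long table."""
    rows = [
        {"blockgroup_id": bg, "group": g, "population": p}
        for bg, by_group in counts.items()
        for g, p in by_group.items()
    ]
    return pd.DataFrame(rows)
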