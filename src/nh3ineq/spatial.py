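"""Meteorological stratification and facility-distance analyses.

Observation days are split at the median of the morning (8 am-12 pm local
time) station wind speed or air temperature into calm/windy and cool/hot
strata. Block-group enhancements are profiled against the haversine distance
from the block-group centre point to the nearest permitted swine facility;
the profile's spatial extent is where the binned mean signal last stays above
twice a far-field noise level (SNR = 2), with noise taken as the 2-sigma
spread of enhancements 15-20 km from any facility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km
from .inequality import eligible_subset


def median_split(met: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Label days below-or-equal / above the median of a met variable.

    ``variable`` is ``"wind"`` (labels calm/windy) or ``"temp"``
    (cool/hot). Days at the median go to the lower stratum. Raises on fewer
    than two distinct values (the split is undefined).
    """
    col = {"wind": "wind", "temp": "temp"}[variable]
    lower, upper = {"wind": ("calm", "windy"), "temp": ("cool", "hot")}[variable]
    x = met[col].to_numpy(dtype=float)
    if len(x) < 2 or np.unique(x).size < 2:
        raise ValueError(f"median split on {variable!r} needs >= 2 distinct values")
    med = float(np.median(x))
    return pd.DataFrame(
        {"date": met["date"].to_numpy(), "stratum": np.where(x <= med, lower, upper)}
    )


def nearest_facility_distance(
    points: pd.DataFrame, facilities: pd.DataFrame, type_filter: str | None = "swine"
) -> pd.Series:
    """Haversine distance (km) from each point to its nearest facility.

    ``points`` has columns id, lat, lon; ``facilities`` has lat, lon, type.
    """
    fac = facilities if type_filter is None else facilities.loc[facilities["type"] == type_filter]
    if fac.empty:
        raise ValueError(f"no facilities of type {type_filter!r}")
    d = haversine_km(
        points["lat"].to_numpy()[:, None],
        points["lon"].to_numpy()[:, None],
        fac["lat"].to_numpy()[None, :],
        fac["lon"].to_numpy()[None, :],
    )
    return pd.Series(d.min(axis=1), index=points["id"].to_numpy(), name="distance_km")


@dataclass
class DistanceProfile:
    """Binned mean enhancement vs distance to the nearest facility."""

    bin_edges: np.ndarray  # km, half-open [lo, hi)
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    noise_2sigma: float
    extent_km: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
                "noise_2sigma": self.noise_2sigma,
                "extent_km": self.extent_km,
            }
        )


def distance_profile(
    bg_table: pd.DataFrame,
    distances: pd.Series,
    bin_width_km: float = 1.0,
    max_km: float = 20.0,
    noise_band_km: tuple[float, float] = (15.0, 20.0),
    noise_2sigma: float | None = None,
) -> DistanceProfile:
    """Profile block-group enhancements against nearest-facility distance.

    Bins are half-open ``[lo, hi)`` of width ``bin_width_km`` from zero (the
    first bin is the near-source bin). The noise level is twice the standard
    deviation of values in the far-field ``noise_band_km``; stratified
    profiles should pass the all-days level through ``noise_2sigma`` (the
    noise band is defined over all days with observations, so strata share a
    threshold). The profile's SNR=2 extent is derived with
    :func:`spatial_extent`.
    """
    if bin_width_km <= 0:
        raise ValueError("bin width must be positive")
    t = bg_table.loc[bg_table["has_value"]]
    d = distances.reindex(t["blockgroup_id"]).to_numpy(dtype=float)
    x = t["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("missing distances for some block groups")

    if noise_2sigma is None:
        band = (d >= noise_band_km[0]) & (d < noise_band_km[1])
        if band.sum() < 2:
            raise ValueError("no block groups in the far-field noise band")
        noise = 2.0 * float(np.std(x[band], ddof=1))
    else:
        noise = float(noise_2sigma)

    edges = np.arange(0.0, max_km + bin_width_km, bin_width_km)
    means = np.full(len(edges) - 1, np.nan)
    sems = np.full(len(edges) - 1, np.nan)
    ns = np.zeros(len(edges) - 1, dtype=int)
    idx = np.digitize(d, edges) - 1
    for b in range(len(edges) - 1):
        xb = x[idx == b]
        ns[b] = xb.size
        if xb.size:
            means[b] = xb.mean()
            sems[b] = xb.std(ddof=1) / np.sqrt(xb.size) if xb.size > 1 else 0.0
    prof = DistanceProfile(bin_edges=edges, mean=means, sem=sems, n=ns, noise_2sigma=noise)
    prof.extent_km = spatial_extent(prof)
    return prof


def spatial_extent(profile: DistanceProfile) -> float:
    """Outer edge of the contiguous-from-source run of bins with SNR >= 2.

    Scans outward from the first bin and stops at the first bin whose mean
    falls below ``2 * noise_2sigma`` (empty bins also stop the scan); returns
    0 when the first bin already fails.
    """
    if not profile.noise_2sigma > 0:
        raise ValueError("noise level must be positive")
    threshold = 2.0 * profile.noise_2sigma
    extent = 0.0
    for b, m in enumerate(profile.mean):
        if not np.isfinite(m) or m < threshold:
            break
        extent = float(profile.bin_edges[b + 1])
    return extent


def population_weighted_distance(
    distances: pd.Series, demographics: pd.DataFrame, group: str
) -> float:
    """Population-weighted nearest-facility distance (km) for a group.

    Uses the same eligibility rule as the inequality metrics: block groups
    with group population share at or above the regional mean share.
    """
    subset, _ = eligible_subset(demographics, group)
    pops = (
        demographics.loc[demographics["group"] == group]
        .groupby("blockgroup_id")["population"]
        .sum()
    )
    ids = [i for i in distances.index if i in subset]
    p = pops.reindex(ids).to_numpy(dtype=float)
    d = distances.reindex(ids).to_numpy(dtype=float)
    if p.sum() <= 0:
        raise ValueError(f"zero population for group {group!r} on eligible subset")
    return float(np.sum(p * d) / np.sum(p))
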