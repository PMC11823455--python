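"""Block-group aggregation and population-weighted inequality metrics.

Enhancement grids are aggregated to census-block-group polygons by exact
polygon-cell intersection (area weighting), then summarized per demographic
group as population-weighted means

    x_bar_w = sum_i p_i x_i / sum_i p_i

over the *eligible* block groups for that group — those whose group
population share is at least the unweighted mean share across all block
groups in the region. Inequalities are reported against a designated
reference group as absolute (difference of population-weighted means) and
relative (percent of the reference mean) gaps, with uncertainties as
weighted standard mean errors,

    SEM = sqrt( sum_i w_i^2 (x_i - x_bar_w)^2 ),  w_i = p_i / sum p.

Demographics are a long-format table with columns ``blockgroup_id``,
``group``, ``population``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape

from .geo import KM_PER_DEG_LAT, km_per_deg_lon
from .oversampling import GridSpec


class BlockGroups:
    """Block-group polygons (WGS84) keyed by id."""

    def __init__(self, ids, polygons):
        if len(ids) != len(polygons):
            raise ValueError("ids and polygons must align")
        for p in polygons:
            if p.is_empty or not p.is_valid:
                raise ValueError("block-group polygons must be valid and non-empty")
        self.ids = list(ids)
        self.polygons = list(polygons)

    def __len__(self):
        return len(self.ids)

    @property
    def centroids(self) -> pd.DataFrame:
        """Representative centre points (polygon centroids)."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "lat": [p.centroid.y for p in self.polygons],
                "lon": [p.centroid.x for p in self.polygons],
            }
        )

    @property
    def areas_km2(self) -> pd.Series:
        out = []
        for p in self.polygons:
            out.append(p.area * KM_PER_DEG_LAT * km_per_deg_lon(p.centroid.y))
        return pd.Series(out, index=self.ids, name="area_km2")

    def to_geojson(self, path):
        features = [
            {
                "type": "Feature",
                "properties": {"id": i},
                "geometry": mapping(p),
            }
            for i, p in zip(self.ids, self.polygons)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path):
        with open(path) as fh:
            fc = json.load(fh)
        ids, polys = [], []
        for feat in fc["features"]:
            ids.append(feat["properties"]["id"])
            polys.append(shape(feat["geometry"]))
        return cls(ids, polys)


def area_weighted_table(
    values: np.ndarray,
    include_mask: np.ndarray,
    grid: GridSpec,
    blockgroups: BlockGroups,
) -> pd.DataFrame:
    """Area-weighted mean of gridded values within each polygon.

    Only cells in ``include_mask`` contribute. Intersection areas are exact
    polygon-cell clips (shapely), converted to km^2 with the cosine of the
    cell latitude. Returns one row per block group with columns ``value``
    (NaN when nothing is covered), ``coverage`` (included intersected area
    over polygon area) and ``has_value``.
    """
    half = grid.spacing_deg / 2.0
    lats, lons = grid.lats, grid.lons
    rows = []
    for bg_id, poly in zip(blockgroups.ids, blockgroups.polygons):
        lon_min, lat_min, lon_max, lat_max = poly.bounds
        i0 = max(int(np.searchsorted(lats, lat_min - half, side="left")), 0)
        i1 = min(int(np.searchsorted(lats, lat_max + half, side="right")), grid.n_lat)
        j0 = max(int(np.searchsorted(lons, lon_min - half, side="left")), 0)
        j1 = min(int(np.searchsorted(lons, lon_max + half, side="right")), grid.n_lon)
        poly_area_km2 = poly.area * KM_PER_DEG_LAT * km_per_deg_lon(poly.centroid.y)
        if i0 >= i1 or j0 >= j1 or poly_area_km2 <= 0:
            rows.append((bg_id, np.nan, 0.0, False))
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        boxes = shapely.box(
            lons[jj] - half, lats[ii] - half, lons[jj] + half, lats[ii] + half
        )
        inter_deg2 = shapely.area(shapely.intersection(boxes, poly))
        area_km2 = inter_deg2 * KM_PER_DEG_LAT * km_per_deg_lon(lats[ii])
        inc = include_mask[ii, jj] & (area_km2 > 0)
        if not inc.any():
            rows.append((bg_id, np.nan, 0.0, False))
            continue
        w = area_km2[inc]
        v = values[ii[inc], jj[inc]]
        rows.append(
            (bg_id, float(np.sum(w * v) / np.sum(w)), float(np.sum(w) / poly_area_km2), True)
        )
    out = pd.DataFrame(rows, columns=["blockgroup_id", "value", "coverage", "has_value"])
    out["coverage"] = out["coverage"].clip(upper=1.0)
    return out


def aggregate_blockgroups(enh, blockgroups: BlockGroups) -> pd.DataFrame:
    """Block-group table of area-weighted mean enhancements.

    Only enhanced (above-background) valid cells contribute; a block group
    with zero enhanced coverage gets ``has_value = False`` ("block groups
    with enhancements" downstream are those with any enhanced coverage).
    """
    return area_weighted_table(enh.delta, enh.enhanced_mask, enh.grid, blockgroups)


def area_weighted_mean(values, include_mask, grid, polygon) -> tuple[float, float]:
    """Area-weighted mean of included cells within one polygon.

    Convenience wrapper returning ``(value, coverage)``; value is NaN when
    coverage is zero.
    """
    table = area_weighted_table(values, include_mask, grid, BlockGroups(["_"], [polygon]))
    return float(table["value"].iloc[0]), float(table["coverage"].iloc[0])


def _shares(demographics: pd.DataFrame) -> pd.DataFrame:
    pivot = demographics.pivot_table(
        index="blockgroup_id", columns="group", values="population", aggfunc="sum"
    ).fillna(0.0)
    totals = pivot.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("block groups with zero total population")
    return pivot.div(totals, axis=0)


def eligible_subset(
    demographics: pd.DataFrame, group: str, by_count: bool = False
) -> tuple[set, float]:
    """Block groups whose group population is at or above the regional mean.

    The threshold is the unweighted mean population *share* across all block
    groups (``by_count=True`` switches to raw counts). Returns the eligible
    id set and the threshold used.
    """
    if group not in set(demographics["group"]):
        raise KeyError(f"group {group!r} not in demographics")
    if by_count:
        counts = (
            demographics.loc[demographics["group"] == group]
            .groupby("blockgroup_id")["population"]
            .sum()
        )
        thr = float(counts.mean())
        eligible = counts >= thr * (1.0 - 1e-12)
        return set(counts.index[eligible]), thr
    shares = _shares(demographics)[group]
    thr = float(shares.mean())
    # tolerance keeps exactly-at-threshold shares eligible despite summation
    # rounding in the mean
    eligible = shares >= thr * (1.0 - 1e-12)
    return set(shares.index[eligible]), thr


def population_weighted_mean(
    table: pd.DataFrame, demographics: pd.DataFrame, group: str, subset
) -> tuple[float, float, int]:
    """Population-weighted mean and weighted SEM over a block-group subset.

    Weights are the group's population counts; only block groups in
    ``subset`` that carry a value are used. Returns (mean, sem, n).
    """
    pops = (
        demographics.loc[demographics["group"] == group]
        .groupby("blockgroup_id")["population"]
        .sum()
    )
    t = table.loc[table["has_value"] & table["blockgroup_id"].isin(set(subset))]
    t = t.loc[t["blockgroup_id"].isin(pops.index)]
    p = pops.reindex(t["blockgroup_id"]).to_numpy(dtype=float)
    x = t["value"].to_numpy(dtype=float)
    if p.sum() <= 0:
        raise ValueError(f"zero total population for group {group!r} on subset")
    w = p / p.sum()
    mean = float(np.sum(w * x))
    sem = float(np.sqrt(np.sum(w**2 * (x - mean) ** 2)))
    return mean, sem, len(t)


@dataclass
class InequalityResult:
    """Population-weighted exposure gap of one group against the reference."""

    group: str
    reference: str
    pw_mean_group: float
    pw_mean_ref: float
    absolute: float
    relative: float  # percent; NaN when the reference mean is not positive
    sem_abs: float
    n_bg_group: int
    n_bg_ref: int
    eligibility_threshold_share: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_inequality(
    table: pd.DataFrame,
    demographics: pd.DataFrame,
    group: str,
    reference: str,
    by_count: bool = False,
) -> InequalityResult:
    """Absolute and relative population-weighted inequality vs the reference.

    Each group's mean is taken over its own eligible block-group subset; the
    combined uncertainty is ``sqrt(sem_group^2 + sem_ref^2)``.
    """
    subset_g, thr_g = eligible_subset(demographics, group, by_count=by_count)
    subset_r, _ = eligible_subset(demographics, reference, by_count=by_count)
    mg, sg, ng = population_weighted_mean(table, demographics, group, subset_g)
    mr, sr, nr = population_weighted_mean(table, demographics, reference, subset_r)
    absolute = mg - mr
    relative = 100.0 * absolute / mr if mr > 0 else float("nan")
    return InequalityResult(
        group=group,
        reference=reference,
        pw_mean_group=mg,
        pw_mean_ref=mr,
        absolute=absolute,
        relative=relative,
        sem_abs=float(np.hypot(sg, sr)),
        n_bg_group=ng,
        n_bg_ref=nr,
        eligibility_threshold_share=thr_g,
    )


def inequality_table(
    table: pd.DataFrame, demographics: pd.DataFrame, groups, reference: str
) -> pd.DataFrame:
    """One :func:`compute_inequality` row per non-reference group."""
    rows = [
        compute_inequality(table, demographics, g, reference).as_dict()
        for g in groups
        if g != reference
    ]
    return pd.DataFrame(rows)


def decompose_trend(
    tables: dict,
    demographics_a: pd.DataFrame,
    demographics_b: pd.DataFrame,
    groups,
    reference: str,
) -> pd.DataFrame:
    """Recompute per-period inequalities under each demographic vintage.

    ``tables`` maps period label -> block-group table. Each period is
    evaluated twice, holding demographics at vintage ``a`` and then ``b``,
    separating column-driven change (across periods at fixed vintage) from
    composition-driven change (across vintages at fixed period).
    """
    if len(tables) < 2:
        raise ValueError("need at least two periods")
    ids_a = set(demographics_a["blockgroup_id"])
    ids_b = set(demographics_b["blockgroup_id"])
    if ids_a != ids_b:
        raise ValueError("block-group ids differ between demographic vintages")
    rows = []
    for period, table in tables.items():
        for vintage, demo in (("a", demographics_a), ("b", demographics_b)):
            for g in groups:
                if g == reference:
                    continue
                r = compute_inequality(table, demo, g, reference)
                rows.append(
                    {
                        "period": period,
                        "vintage": vintage,
                        "group": g,
                        "absolute": r.absolute,
                        "relative": r.relative,
                        "sem_abs": r.sem_abs,
                    }
                )
    out = pd.DataFrame(rows)
    # composition effect: vintage swap at fixed period; column effect: period
    # change at fixed vintage (first period as baseline)
    piv = out.pivot_table(index=["period", "group"], columns="vintage", values="absolute")
    out = out.merge(
        (piv["b"] - piv["a"]).rename("composition_effect_abs").reset_index(),
        on=["period", "group"],
        how="left",
    )
    first = min(tables)
    base = piv["a"].xs(first, level="period")
    col_eff = (piv["a"] - base.reindex(piv.index.get_level_values("group")).to_numpy()).rename(
        "column_effect_abs"
    )
    out = out.merge(col_eff.reset_index(), on=["period", "group"], how="left")
    return out
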