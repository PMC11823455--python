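"""Area-weighted aggregation and population-weighted inequality metrics."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from nh3ineq import (
    GridSpec,
    area_weighted_mean,
    area_weighted_table,
    compute_inequality,
    decompose_trend,
    eligible_subset,
    population_weighted_mean,
)
from nh3ineq.inequality import BlockGroups

from conftest import demographics_from_counts, square_blockgroups


@pytest.fixture
def unit_grid():
    # 4x4 cells of 0.01 deg starting at (35.0, -79.0)
    return GridSpec(lat0=35.005, lon0=-78.995, n_lat=4, n_lon=4, spacing_deg=0.01)


def test_polygon_inside_one_cell(unit_grid):
    values = np.full((4, 4), np.nan)
    values[1, 1] = 7.0
    include = np.zeros((4, 4), dtype=bool)
    include[1, 1] = True
    poly = box(-78.988, 35.012, -78.983, 35.017)  # strictly inside cell (1,1)
    value, coverage = area_weighted_mean(values, include, unit_grid, poly)
    assert value == pytest.approx(7.0)
    assert coverage == pytest.approx(1.0, rel=1e-3)


def test_uniform_grid_any_polygon(unit_grid):
    values = np.full((4, 4), 3.3)
    include = np.ones((4, 4), dtype=bool)
    poly = Polygon(
        [(-78.995, 35.005), (-78.97, 35.01), (-78.98, 35.03), (-78.99, 35.02)]
    )
    value, coverage = area_weighted_mean(values, include, unit_grid, poly)
    assert value == pytest.approx(3.3)
    assert coverage == pytest.approx(1.0)


def test_fifty_fifty_split_between_two_cells(unit_grid):
    # polygon straddling the boundary between cells (1,1) and (1,2) equally
    values = np.zeros((4, 4))
    values[1, 1] = 1.0
    values[1, 2] = 3.0
    include = np.zeros((4, 4), dtype=bool)
    include[1, [1, 2]] = True
    poly = box(-78.986, 35.012, -78.974, 35.018)  # centred on lon -78.98
    value, coverage = area_weighted_mean(values, include, unit_grid, poly)
    assert value == pytest.approx(2.0, rel=1e-9)
    assert coverage == pytest.approx(1.0, rel=1e-9)


def test_zero_coverage_flagged(unit_grid):
    values = np.full((4, 4), 1.0)
    include = np.zeros((4, 4), dtype=bool)
    poly = box(-78.99, 35.01, -78.98, 35.02)
    value, coverage = area_weighted_mean(values, include, unit_grid, poly)
    assert np.isnan(value)
    assert coverage == 0.0


def test_area_weighted_table_matches_manual_clip(unit_grid):
    rng = np.random.default_rng(7)
    values = rng.uniform(1, 5, (4, 4))
    include = rng.uniform(size=(4, 4)) < 0.7
    bgs = square_blockgroups(35.0, -79.0, 2, 0.02)  # 2x2 BGs of 2x2 cells
    table = area_weighted_table(values, include, unit_grid, bgs)
    # manual oracle: equal-area cells within each square BG (cos factor is
    # constant to ~1e-6 across one cell row, so a plain mean over included
    # cells of the BG agrees to that tolerance)
    for bi in range(2):
        for bj in range(2):
            sel = include[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
            vals = values[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
            row = table.loc[table["blockgroup_id"] == f"bg_{bi}_{bj}"].iloc[0]
            if sel.any():
                assert row["value"] == pytest.approx(vals[sel].mean(), rel=1e-4)
                assert row["coverage"] == pytest.approx(sel.mean(), rel=1e-3)
            else:
                assert not row["has_value"]


class TestEligibility:
    def test_equal_shares_all_eligible(self):
        demo = demographics_from_counts(
            {f"b{i}": {"g": 10, "ref": 30} for i in range(5)}
        )
        subset, thr = eligible_subset(demo, "g")
        assert subset == {f"b{i}" for i in range(5)}
        assert thr == pytest.approx(0.25)

    def test_above_mean_share_selected(self):
        shares = {"b0": 10, "b1": 20, "b2": 30, "b3": 40}
        demo = demographics_from_counts(
            {b: {"g": s, "ref": 100 - s} for b, s in shares.items()}
        )
        subset, thr = eligible_subset(demo, "g")
        assert thr == pytest.approx(0.25)
        assert subset == {"b2", "b3"}

    def test_absent_group_raises(self):
        demo = demographics_from_counts({"b0": {"g": 1}})
        with pytest.raises(KeyError):
            eligible_subset(demo, "nope")


class TestPopulationWeightedMean:
    def make_table(self, values):
        return pd.DataFrame(
            {
                "blockgroup_id": [f"b{i}" for i in range(len(values))],
                "value": values,
                "coverage": 1.0,
                "has_value": True,
            }
        )

    def test_uniform_population_is_arithmetic_mean(self):
        table = self.make_table([1.0, 2.0, 6.0])
        demo = demographics_from_counts(
            {f"b{i}": {"g": 100} for i in range(3)}
        )
        mean, sem, n = population_weighted_mean(table, demo, "g", {"b0", "b1", "b2"})
        assert mean == pytest.approx(3.0)
        assert n == 3

    def test_weighted_hand_computation(self):
        table = self.make_table([1e15, 2e15, 3e15])
        demo = demographics_from_counts(
            {"b0": {"g": 100}, "b1": {"g": 200}, "b2": {"g": 700}}
        )
        mean, sem, _ = population_weighted_mean(table, demo, "g", {"b0", "b1", "b2"})
        assert mean == pytest.approx(2.6e15)
        # sem oracle: sqrt(sum w_i^2 (x_i - mean)^2)
        w = np.array([0.1, 0.2, 0.7])
        x = np.array([1e15, 2e15, 3e15])
        assert sem == pytest.approx(np.sqrt(np.sum(w**2 * (x - 2.6e15) ** 2)))

    def test_single_blockgroup_sem_zero(self):
        table = self.make_table([5.0])
        demo = demographics_from_counts({"b0": {"g": 10}})
        mean, sem, n = population_weighted_mean(table, demo, "g", {"b0"})
        assert (mean, sem, n) == (5.0, 0.0, 1)

    def test_scale_invariance_of_populations(self):
        table = self.make_table([1.0, 4.0, 9.0])
        demo1 = demographics_from_counts(
            {"b0": {"g": 10}, "b1": {"g": 20}, "b2": {"g": 30}}
        )
        demo2 = demographics_from_counts(
            {"b0": {"g": 50}, "b1": {"g": 100}, "b2": {"g": 150}}
        )
        subset = {"b0", "b1", "b2"}
        assert population_weighted_mean(table, demo1, "g", subset) == pytest.approx(
            population_weighted_mean(table, demo2, "g", subset)
        )

    def test_zero_population_raises(self):
        table = self.make_table([1.0])
        demo = demographics_from_counts({"b0": {"g": 0}})
        with pytest.raises(ValueError):
            population_weighted_mean(table, demo, "g", {"b0"})


class TestComputeInequality:
    def two_group_setup(self, values, pops_g, pops_ref):
        ids = [f"b{i}" for i in range(len(values))]
        table = pd.DataFrame(
            {"blockgroup_id": ids, "value": values, "coverage": 1.0, "has_value": True}
        )
        demo = demographics_from_counts(
            {i: {"g": pg, "ref": pr} for i, pg, pr in zip(ids, pops_g, pops_ref)}
        )
        return table, demo

    def test_identical_distributions_zero_gap(self):
        table, demo = self.two_group_setup([2.0, 3.0, 4.0], [10, 10, 10], [10, 10, 10])
        r = compute_inequality(table, demo, "g", "ref")
        assert r.absolute == pytest.approx(0.0, abs=1e-12)
        assert r.relative == pytest.approx(0.0, abs=1e-9)

    def test_thirty_percent_gap_arithmetic(self):
        # group pw mean 2.6e15 vs reference 2.0e15 -> +6e14 absolute, +30%
        ids = ["b0", "b1", "b2", "b3"]
        table = pd.DataFrame(
            {
                "blockgroup_id": ids,
                "value": [1e15, 2e15, 3e15, 2e15],
                "coverage": 1.0,
                "has_value": True,
            }
        )
        demo = demographics_from_counts(
            {
                "b0": {"g": 100, "ref": 1},
                "b1": {"g": 200, "ref": 1},
                "b2": {"g": 700, "ref": 1},
                "b3": {"g": 1, "ref": 1000},
            }
        )
        r = compute_inequality(table, demo, "g", "ref")
        assert r.absolute == pytest.approx(6e14, rel=1e-2)
        assert r.relative == pytest.approx(30.0, rel=1e-2)
        assert r.sem_abs >= 0

    def test_absolute_shift_invariant_relative_not(self):
        values = np.array([2.0, 3.0, 5.0, 4.0])
        table, demo = self.two_group_setup(
            values, [10, 20, 5, 1], [1, 2, 10, 30]
        )
        r0 = compute_inequality(table, demo, "g", "ref")
        table2 = table.copy()
        table2["value"] = values + 10.0
        r1 = compute_inequality(table2, demo, "g", "ref")
        assert r1.absolute == pytest.approx(r0.absolute, rel=1e-12)
        assert r1.relative != pytest.approx(r0.relative, rel=1e-3)


class TestDecomposeTrend:
    def setup_tables(self):
        ids = ["b0", "b1"]
        tables = {
            "p1": pd.DataFrame(
                {"blockgroup_id": ids, "value": [1.0, 2.0], "coverage": 1.0, "has_value": True}
            ),
            "p2": pd.DataFrame(
                {"blockgroup_id": ids, "value": [1.0, 4.0], "coverage": 1.0, "has_value": True}
            ),
        }
        demo = demographics_from_counts(
            {"b0": {"g": 10, "ref": 90}, "b1": {"g": 90, "ref": 10}}
        )
        return tables, demo

    def test_identical_vintages_coincide(self):
        tables, demo = self.setup_tables()
        out = decompose_trend(tables, demo, demo.copy(), ["g", "ref"], "ref")
        piv = out.pivot_table(index=["period", "group"], columns="vintage", values="absolute")
        np.testing.assert_allclose(piv["a"], piv["b"])
        np.testing.assert_allclose(out["composition_effect_abs"], 0.0, atol=1e-15)

    def test_uniformly_scaled_counts_are_equivalent(self):
        tables, demo = self.setup_tables()
        doubled = demo.copy()
        doubled["population"] *= 2
        out = decompose_trend(tables, demo, doubled, ["g", "ref"], "ref")
        np.testing.assert_allclose(out["composition_effect_abs"], 0.0, atol=1e-12)

    def test_shifted_shares_sign_matches_two_run_oracle(self):
        tables, demo = self.setup_tables()
        demo_b = demographics_from_counts(
            {"b0": {"g": 50, "ref": 50}, "b1": {"g": 50, "ref": 50}}
        )
        out = decompose_trend(tables, demo, demo_b, ["g", "ref"], "ref")
        for period in ("p1", "p2"):
            ra = compute_inequality(tables[period], demo, "g", "ref")
            rb = compute_inequality(tables[period], demo_b, "g", "ref")
            row = out.loc[
                (out["period"] == period) & (out["vintage"] == "a"), "composition_effect_abs"
            ].iloc[0]
            assert np.sign(row) == np.sign(rb.absolute - ra.absolute)

    def test_mismatched_ids_rejected(self):
        tables, demo = self.setup_tables()
        demo_b = demographics_from_counts({"zz": {"g": 1, "ref": 1}})
        with pytest.raises(ValueError):
            decompose_trend(tables, demo, demo_b, ["g", "ref"], "ref")

    def test_single_period_rejected(self):
        tables, demo = self.setup_tables()
        with pytest.raises(ValueError):
            decompose_trend({"p1": tables["p1"]}, demo, demo, ["g", "ref"], "ref")


def test_blockgroups_geojson_roundtrip(tmp_path):
    bgs = square_blockgroups(35.0, -79.0, 3, 0.05)
    path = tmp_path / "bg.geojson"
    bgs.to_geojson(path)
    back = BlockGroups.from_geojson(path)
    assert back.ids == bgs.ids
    for p, q in zip(back.polygons, bgs.polygons):
        assert p.equals(q)
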