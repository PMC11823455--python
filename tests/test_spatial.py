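"""Median splits, nearest-facility distances, decay profiles, extents."""

import numpy as np
import pandas as pd
import pytest

from nh3ineq import (
    DistanceProfile,
    distance_profile,
    median_split,
    nearest_facility_distance,
    population_weighted_distance,
    spatial_extent,
)

from conftest import demographics_from_counts


def met_from_winds(winds, temps=None):
    n = len(winds)
    return pd.DataFrame(
        {
            "date": pd.date_range("2016-04-01", periods=n, freq="D"),
            "wind": winds,
            "temp": temps if temps is not None else np.linspace(20, 28, n),
            "precip": 0.0,
        }
    )


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(met_from_winds([1.0, 2.0, 3.0, 4.0]), "wind")
        assert list(labels["stratum"]) == ["calm", "calm", "windy", "windy"]

    def test_tie_rule_at_median(self):
        labels = median_split(met_from_winds([1.0, 1.0, 5.0, 5.0]), "wind")
        assert sorted(labels["stratum"]) == ["calm", "calm", "windy", "windy"]
        # values equal to the median go to the lower stratum
        labels2 = median_split(met_from_winds([1.0, 2.0, 3.0]), "wind")
        assert list(labels2["stratum"]) == ["calm", "calm", "windy"]

    def test_temperature_labels(self):
        labels = median_split(met_from_winds([1, 2, 3, 4], temps=[10.0, 30.0, 20.0, 25.0]), "temp")
        assert set(labels["stratum"]) == {"cool", "hot"}

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            median_split(met_from_winds([3.0]), "wind")
        with pytest.raises(ValueError):
            median_split(met_from_winds([3.0, 3.0, 3.0]), "wind")


def facilities(rows):
    return pd.DataFrame(rows, columns=["id", "lat", "lon", "type"])


class TestNearestFacilityDistance:
    def test_coincident_point_zero(self):
        fac = facilities([("f0", 35.0, -78.0, "swine")])
        pts = pd.DataFrame({"id": ["p0"], "lat": [35.0], "lon": [-78.0]})
        assert nearest_facility_distance(pts, fac).iloc[0] == pytest.approx(0.0)

    def test_great_circle_oracle(self):
        # 0.1 deg of longitude at 35 N: R*cos(35)*0.1*pi/180 = 9.1 km
        fac = facilities([("f0", 35.0, -77.9, "swine")])
        pts = pd.DataFrame({"id": ["p0"], "lat": [35.0], "lon": [-78.0]})
        d = nearest_facility_distance(pts, fac).iloc[0]
        expected = 6371.0088 * np.cos(np.deg2rad(35.0)) * np.deg2rad(0.1)
        assert d == pytest.approx(expected, rel=1e-4)
        assert d == pytest.approx(9.1, abs=0.05)

    def test_adding_farther_facility_never_increases(self):
        rng = np.random.default_rng(8)
        pts = pd.DataFrame(
            {"id": range(20), "lat": rng.uniform(34, 36, 20), "lon": rng.uniform(-79, -77, 20)}
        )
        fac1 = facilities([("f0", 35.0, -78.0, "swine")])
        fac2 = pd.concat(
            [fac1, facilities([("f1", 35.5, -78.5, "swine")])], ignore_index=True
        )
        d1 = nearest_facility_distance(pts, fac1)
        d2 = nearest_facility_distance(pts, fac2)
        assert (d2 <= d1 + 1e-12).all()

    def test_type_filter(self):
        fac = facilities([("f0", 35.0, -78.0, "other")])
        pts = pd.DataFrame({"id": ["p0"], "lat": [35.0], "lon": [-78.0]})
        with pytest.raises(ValueError):
            nearest_facility_distance(pts, fac, type_filter="swine")


def bg_table(ids, values):
    return pd.DataFrame(
        {"blockgroup_id": ids, "value": values, "coverage": 1.0, "has_value": True}
    )


class TestDistanceProfile:
    def exponential_setup(self, rng, n=400, decay=5.0, amplitude=10.0):
        d = rng.uniform(0, 20, n)
        values = amplitude * np.exp(-d / decay)
        ids = [f"b{i}" for i in range(n)]
        return bg_table(ids, values), pd.Series(d, index=ids)

    def test_structureless_field_has_zero_extent(self):
        # enhancements that are pure zero-mean scatter: every bin mean sits
        # far below twice the far-field 2-sigma level
        rng = np.random.default_rng(9)
        n = 300
        d = rng.uniform(0, 20, n)
        ids = [f"b{i}" for i in range(n)]
        table = bg_table(ids, 0.1 * rng.standard_normal(n))
        prof = distance_profile(table, pd.Series(d, index=ids), bin_width_km=2.0)
        assert prof.extent_km == 0.0

    def test_binned_means_match_closed_form(self):
        rng = np.random.default_rng(10)
        table, distances = self.exponential_setup(rng, n=4000)
        prof = distance_profile(table, distances, bin_width_km=2.0)
        # closed-form bin average of A exp(-d/L) over [lo, hi)
        for b in range(len(prof.bin_edges) - 1):
            lo, hi = prof.bin_edges[b], prof.bin_edges[b + 1]
            expected = 10.0 * 5.0 * (np.exp(-lo / 5.0) - np.exp(-hi / 5.0)) / (hi - lo)
            assert prof.mean[b] == pytest.approx(expected, rel=0.12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        table, distances = self.exponential_setup(rng)
        prof1 = distance_profile(table, distances, bin_width_km=2.0)
        perm = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        prof2 = distance_profile(perm, distances, bin_width_km=2.0)
        np.testing.assert_allclose(prof1.mean, prof2.mean)
        assert prof1.extent_km == prof2.extent_km

    def test_empty_noise_band_rejected(self):
        ids = ["b0", "b1", "b2"]
        table = bg_table(ids, [1.0, 2.0, 3.0])
        distances = pd.Series([0.5, 1.5, 2.5], index=ids)
        with pytest.raises(ValueError):
            distance_profile(table, distances)

    def test_fixed_noise_level_is_used(self):
        rng = np.random.default_rng(12)
        table, distances = self.exponential_setup(rng)
        prof = distance_profile(table, distances, bin_width_km=2.0, noise_2sigma=0.25)
        assert prof.noise_2sigma == 0.25


class TestSpatialExtent:
    def make_profile(self, means, noise):
        edges = np.arange(0.0, len(means) + 1.0)
        return DistanceProfile(
            bin_edges=edges,
            mean=np.asarray(means, dtype=float),
            sem=np.zeros(len(means)),
            n=np.ones(len(means), dtype=int),
            noise_2sigma=noise,
        )

    def test_all_below_threshold(self):
        assert spatial_extent(self.make_profile([1.0, 1.5, 0.5], 1.0)) == 0.0

    def test_contiguous_scan(self):
        # means 10,6,3,1 x noise with threshold 2 x noise -> extent 3 km
        assert spatial_extent(self.make_profile([10.0, 6.0, 3.0, 1.0], 1.0)) == 3.0

    def test_noncontiguous_exceedance_ignored(self):
        assert spatial_extent(self.make_profile([10.0, 1.0, 10.0], 1.0)) == 1.0

    def test_scale_invariance(self):
        p1 = self.make_profile([10.0, 6.0, 3.0, 1.0], 1.0)
        p2 = self.make_profile([20.0, 12.0, 6.0, 2.0], 2.0)
        assert spatial_extent(p1) == spatial_extent(p2)

    def test_empty_bin_stops_scan(self):
        prof = self.make_profile([10.0, np.nan, 10.0], 1.0)
        assert spatial_extent(prof) == 1.0

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            spatial_extent(self.make_profile([1.0], 0.0))


class TestPopulationWeightedDistance:
    def test_uniform_population_arithmetic_mean(self):
        demo = demographics_from_counts(
            {"b0": {"g": 10, "ref": 10}, "b1": {"g": 10, "ref": 10}}
        )
        d = pd.Series([4.0, 8.0], index=["b0", "b1"])
        assert population_weighted_distance(d, demo, "g") == pytest.approx(6.0)

    def test_weighted_hand_computation(self):
        # pops (1, 3), distances (4, 8) -> (4 + 24) / 4 = 7 km
        demo = demographics_from_counts(
            {"b0": {"g": 1, "ref": 1}, "b1": {"g": 3, "ref": 3}}
        )
        d = pd.Series([4.0, 8.0], index=["b0", "b1"])
        assert population_weighted_distance(d, demo, "g") == pytest.approx(7.0)
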