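"""Spatial indicators: hand-checked values, identities, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull, Delaunay

from stockdist.geo import to_xy
from stockdist.indicators import (
    annual_indicators,
    annual_series,
    center_of_gravity,
    inertia,
    positive_area,
    sample_location_cg,
    weighted_depth,
)
from stockdist.influence import dissolve_boundary, voronoi_weights


class TestCenterOfGravity:
    def test_single_mass_point(self):
        assert center_of_gravity([10.0], [20.0], [3.0], [2.0]) == (10.0, 20.0)

    def test_symmetry(self):
        assert center_of_gravity([0, 10], [0, 0], [1, 1], [2, 2]) == (5.0, 0.0)

    def test_hand_example(self, three_station):
        s = three_station
        assert center_of_gravity(s["x"], s["y"], s["w"], s["z"]) == (2.5, 2.5)

    def test_zero_mass_is_undefined_not_an_error(self):
        xcg, ycg = center_of_gravity([0, 1], [0, 1], [1, 1], [0, 0])
        assert np.isnan(xcg) and np.isnan(ycg)


class TestInertia:
    def test_point_mass_zero(self):
        cg = (5.0, 5.0)
        i, smax, smin, _ = inertia([5.0], [5.0], [1.0], [1.0], cg)
        assert (i, smax, smin) == (0.0, 0.0, 0.0)

    def test_two_point_variance(self):
        # equal masses d apart: inertia (d/2)^2, all on the max axis
        cg = center_of_gravity([0, 10], [0, 0], [1, 1], [1, 1])
        i, smax, smin, bearing = inertia([0, 10], [0, 0], [1, 1], [1, 1], cg)
        assert i == pytest.approx(25.0)
        assert smax == pytest.approx(5.0)
        assert smin == pytest.approx(0.0)
        assert bearing == pytest.approx(0.0)

    def test_trace_equals_direct_weighted_mean_square_distance(self, three_station):
        s = three_station
        cg = center_of_gravity(s["x"], s["y"], s["w"], s["z"])
        i, smax, smin, _ = inertia(s["x"], s["y"], s["w"], s["z"], cg)
        m = s["w"] * s["z"]
        direct = np.sum(m * ((s["x"] - cg[0]) ** 2 + (s["y"] - cg[1]) ** 2)) / m.sum()
        assert i == pytest.approx(direct)
        assert smax**2 + smin**2 == pytest.approx(i, rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_axis_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x, y = rng.normal(size=(2, n)) * 10
        w = rng.uniform(0.1, 5, n)
        z = rng.uniform(0, 3, n)
        z[0] = 1.0  # guarantee positive mass
        cg = center_of_gravity(x, y, w, z)
        i, smax, smin, _ = inertia(x, y, w, z, cg)
        assert smax >= smin >= 0
        assert smax**2 + smin**2 == pytest.approx(i, rel=1e-9)


class TestDepthAndPositiveArea:
    def test_uniform_depth(self):
        assert weighted_depth([100, 100, 100], [1, 2, 3], [1, 1, 1]) == 100.0

    def test_equal_mass_two_depths(self):
        assert weighted_depth([50, 150], [1, 1], [1, 1]) == 100.0

    def test_hand_example(self, three_station):
        s = three_station
        assert weighted_depth(s["depth"], s["w"], s["z"]) == pytest.approx(20.0)

    def test_positive_area_cases(self):
        assert positive_area([2, 3, 5], [0, 0, 0]) == 0.0
        assert positive_area([2, 3, 5], [1, 2, 3]) == 10.0
        assert positive_area([2, 3, 5], [0, 1, 4]) == 8.0

    def test_positive_area_strict_inequality(self):
        assert positive_area([2.0, 3.0], [0.0, 1e-300]) == 3.0


class TestSampleLocationCG:
    def test_single_station(self):
        assert sample_location_cg([3.0], [4.0], [2.0]) == (3.0, 4.0)

    def test_equal_weights(self):
        assert sample_location_cg([0, 10], [0, 10], [1, 1]) == (5.0, 5.0)

    def test_hand_example_ignores_biomass(self, three_station):
        s = three_station
        assert sample_location_cg(s["x"], s["y"], s["w"]) == (5.0, 2.5)


class TestInvariances:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.x, self.y = rng.uniform(0, 50, (2, 25))
        self.w = rng.uniform(0.5, 4, 25)
        self.z = np.where(rng.uniform(size=25) > 0.3, rng.gamma(2, 2, 25), 0.0)
        self.depth = rng.uniform(20, 200, 25)

    def test_biomass_scaling_leaves_cg_inertia_depth_pa(self):
        a = annual_indicators(self.x, self.y, self.w, self.z, self.depth, 2000)
        b = annual_indicators(self.x, self.y, self.w, 7.3 * self.z, self.depth, 2000)
        for f in ("xcg", "ycg", "inertia", "depth_cg", "positive_area"):
            assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-12)

    def test_weight_scaling_scales_only_positive_area(self):
        a = annual_indicators(self.x, self.y, self.w, self.z, self.depth, 2000)
        b = annual_indicators(self.x, self.y, 3.0 * self.w, self.z, self.depth, 2000)
        for f in ("xcg", "ycg", "inertia", "depth_cg"):
            assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-12)
        assert b.positive_area == pytest.approx(3.0 * a.positive_area)

    def test_cg_inside_positive_biomass_hull(self):
        a = annual_indicators(self.x, self.y, self.w, self.z, self.depth, 2000)
        pos = self.z > 0
        hull = Delaunay(np.column_stack([self.x[pos], self.y[pos]]))
        assert hull.find_simplex([a.xcg, a.ycg]) >= 0

    def test_equal_weights_and_biomass_give_centroid(self):
        a = annual_indicators(self.x, self.y, np.ones(25), np.ones(25), self.depth, 2000)
        assert a.xcg == pytest.approx(self.x.mean())
        assert a.ycg == pytest.approx(self.y.mean())


class TestAnnualSeries:
    def test_single_year_series(self, small_survey, small_stock):
        one = small_survey[small_survey["year"] == 2000]
        out = annual_series(one, small_stock, "SPRING")
        assert len(out) == 1 and out["year"].iloc[0] == 2000

    def test_matches_direct_per_year_computation(self, small_survey, small_stock):
        out = annual_series(small_survey, small_stock, "SPRING")
        assert list(out["year"]) == list(range(2000, 2005))
        strata = small_stock.strata["SPRING"]
        frame = strata.frame()
        boundary = dissolve_boundary(strata.km_strata(frame))
        for _, row in out.iterrows():
            st_rows = small_survey[small_survey["year"] == row["year"]]
            x, y = to_xy(st_rows["lon"].to_numpy(), st_rows["lat"].to_numpy(), frame)
            w = voronoi_weights(x, y, boundary).weights
            direct = annual_indicators(
                x, y, w, st_rows["COD"].to_numpy(), st_rows["depth_m"].to_numpy(), row["year"]
            )
            assert row["xcg"] == pytest.approx(direct.xcg)
            assert row["inertia"] == pytest.approx(direct.inertia)
            assert row["positive_area"] == pytest.approx(direct.positive_area)
            assert row["depth_cg"] == pytest.approx(direct.depth_cg)

    def test_incomplete_years_omitted(self, small_survey, small_stock):
        holey = small_survey[
            ~((small_survey["year"] == 2002) & (small_survey["stratum"] == "B"))
        ]
        out = annual_series(holey, small_stock, "SPRING")
        assert 2002 not in set(out["year"])
        out_all = annual_series(holey, small_stock, "SPRING", require_complete=False)
        assert 2002 in set(out_all["year"])
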