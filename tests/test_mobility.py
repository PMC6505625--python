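"""Gyradius, expected location, CCDF and spatial autocorrelation statistics."""

import numpy as np
import pytest

from mobsent import mobility
from mobsent.geo import haversine_m, unproject_local


def scatter_latlon(rng, n, scale_m, lat0=40.0, lon0=-74.0):
    xy = rng.uniform(-scale_m, scale_m, (n, 2))
    return unproject_local(xy[:, 0], xy[:, 1], lat0, lon0)


class TestExpectedLocation:
    def test_single_point(self):
        assert mobility.expected_location(40.0, -74.0) == pytest.approx((40.0, -74.0))

    def test_two_points_midpoint(self):
        lat, lon = mobility.expected_location([40.0, 40.01], [-74.0, -74.0])
        assert lat == pytest.approx(40.005, abs=1e-6)
        assert lon == pytest.approx(-74.0, abs=1e-9)

    def test_matches_brute_force_planar_mean(self, rng):
        lats, lons = scatter_latlon(rng, 100, 5_000)
        elat, elon = mobility.expected_location(lats, lons)
        # oracle: planar mean in a frame centered on the estimate itself
        from mobsent.geo import project_local

        x, y = project_local(lats, lons, elat, elon)
        assert abs(x.mean()) < 1.0
        assert abs(y.mean()) < 1.0

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            mobility.expected_location([], [])


class TestGyradius:
    def test_coincident_points_zero(self):
        assert mobility.gyradius([40.0] * 5, [-74.0] * 5) == 0.0

    def test_two_points_symmetric(self):
        # two points 200 m apart -> every distance from the midpoint is 100 m
        lat2, _ = unproject_local(0.0, 200.0, 40.0, -74.0)
        rg = mobility.gyradius([40.0, float(lat2)], [-74.0, -74.0])
        assert rg == pytest.approx(100.0, rel=1e-6)

    def test_matches_haversine_rms_oracle(self, rng):
        lats, lons = scatter_latlon(rng, 500, 10_000)
        s = mobility.trajectory_summary_from_positions("u", lats, lons)
        d_oracle = haversine_m(s.expected_lat, s.expected_lon, lats, lons)
        rg_oracle = np.sqrt(np.mean(d_oracle**2))
        assert s.gyradius_m == pytest.approx(rg_oracle, rel=1e-3)

    def test_gyradius_is_rms_of_distances(self, rng):
        lats, lons = scatter_latlon(rng, 50, 2_000)
        s = mobility.trajectory_summary_from_positions("u", lats, lons)
        assert s.gyradius_m == pytest.approx(
            np.sqrt(np.mean(s.distances_m**2)), rel=1e-12
        )

    def test_translation_invariance(self, rng):
        # same planar offsets re-anchored 5 degrees away give the same gyradius
        from mobsent.geo import project_local

        lats, lons = scatter_latlon(rng, 80, 3_000)
        rg1 = mobility.gyradius(lats, lons)
        x, y = project_local(lats, lons, 40.0, -74.0)
        lats3, lons3 = unproject_local(x, y, 45.0, -69.0)
        rg3 = mobility.gyradius(lats3, lons3)
        assert rg3 == pytest.approx(rg1, rel=1e-4)

    def test_linear_scaling(self, rng):
        from mobsent.geo import project_local

        lats, lons = scatter_latlon(rng, 60, 1_000)
        x, y = project_local(lats, lons, 40.0, -74.0)
        lats2, lons2 = unproject_local(3 * x, 3 * y, 40.0, -74.0)
        assert mobility.gyradius(lats2, lons2) == pytest.approx(
            3 * mobility.gyradius(lats, lons), rel=1e-4
        )


class TestCCDF:
    def test_single_value(self):
        out = mobility.gyradius_ccdf([5.0])
        assert out["value"].tolist() == [5.0]
        assert out["ccdf"].tolist() == [1.0]

    def test_counting(self):
        out = mobility.gyradius_ccdf([1.0, 2.0, 3.0])
        assert dict(zip(out["value"], out["ccdf"]))[2.0] == pytest.approx(2 / 3)

    def test_matches_counting_oracle_and_monotone(self, rng):
        vals = rng.exponential(10.0, 200)
        out = mobility.gyradius_ccdf(vals)
        for v, f in zip(out["value"], out["ccdf"]):
            assert f == pytest.approx(np.mean(vals >= v))
        assert (np.diff(out["ccdf"]) <= 0).all()
        assert out["ccdf"].iloc[0] == 1.0
        assert out["ccdf"].iloc[-1] >= 1 / len(vals) - 1e-12


def checkerboard(n=4):
    xx, yy = np.meshgrid(np.arange(n), np.arange(n))
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    values = ((xx + yy) % 2).ravel().astype(float)
    return values, coords


def rook_weights(coords):
    """Independent row-standardized rook-contiguity weights for the oracle."""
    n = len(coords)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.isclose(np.abs(coords[i] - coords[j]).sum(), 1.0):
                w[i, j] = 1.0
    return w / w.sum(axis=1, keepdims=True)


class TestSpatialAutocorrelation:
    def test_morans_checkerboard_negative_and_matches_double_sum(self):
        values, coords = checkerboard()
        w = rook_weights(coords)
        got = mobility.morans_i(values, coords, weights=w)
        # brute-force double sum
        z = values - values.mean()
        num = sum(
            w[i, j] * z[i] * z[j] for i in range(len(z)) for j in range(len(z))
        )
        expected = len(z) / w.sum() * num / (z @ z)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0

    def test_gearys_checkerboard_above_one_and_matches_double_sum(self):
        values, coords = checkerboard()
        w = rook_weights(coords)
        got = mobility.gearys_c(values, coords, weights=w)
        z = values - values.mean()
        num = sum(
            w[i, j] * (values[i] - values[j]) ** 2
            for i in range(len(values))
            for j in range(len(values))
        )
        expected = (len(values) - 1) / (2 * w.sum()) * num / (z @ z)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 1

    def test_permutation_null_expectations(self, rng):
        coords = rng.uniform(0, 10, (30, 2))
        values = rng.normal(0, 1, 30)
        eye = np.arange(30)
        i_vals, c_vals = [], []
        for _ in range(400):
            perm = rng.permutation(eye)
            i_vals.append(mobility.morans_i(values[perm], coords, k=4))
            c_vals.append(mobility.gearys_c(values[perm], coords, k=4))
        assert np.mean(i_vals) == pytest.approx(-1 / 29, abs=0.02)
        assert np.mean(c_vals) == pytest.approx(1.0, abs=0.05)

    def test_constant_values_fatal(self):
        coords = np.random.default_rng(0).uniform(0, 1, (10, 2))
        with pytest.raises(ValueError, match="constant"):
            mobility.morans_i(np.ones(10), coords)
        with pytest.raises(ValueError, match="constant"):
            mobility.gearys_c(np.ones(10), coords)
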