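"""Covariate derivation, land-aware bilinear sampling and table assembly."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from lostyears import covariates as cov
from lostyears import pseudo_absence as pa
from tests.conftest import make_segment


def grid_stack(values, lons=None, lats=None, dates=1, mask=None, var="sst"):
    """Small helper stack from a raw array (time, lat, lon) or (lat, lon)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    nt, ny, nx = values.shape
    lons = np.asarray(lons) if lons is not None else -30 + 0.25 * np.arange(nx)
    lats = np.asarray(lats) if lats is not None else 30 + 0.25 * np.arange(ny)
    times = pd.date_range("2001-01-01", periods=nt, freq="D")
    ds = xr.Dataset({var: (("time", "lat", "lon"), values)},
                    coords={"time": times, "lat": lats, "lon": lons})
    if mask is None:
        mask = np.ones((ny, nx), bool)
    return cov.CovariateStack(ds=ds, sea_mask=mask)


class TestSampleField:
    def test_cell_center_identity(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        st = grid_stack(vals)
        assert cov.sample_field(st, "sst", st.lons[2], st.lats[1], st.dates[0]) == vals[1, 2]

    def test_midpoint_of_equal_cells(self):
        vals = np.full((3, 4), 7.25)
        st = grid_stack(vals)
        lon = 0.5 * (st.lons[1] + st.lons[2])
        assert cov.sample_field(st, "sst", lon, st.lats[1], st.dates[0]) == pytest.approx(7.25)

    def test_constant_field_anywhere(self):
        st = grid_stack(np.full((5, 5), 3.5))
        rng = np.random.default_rng(1)
        lon = rng.uniform(st.lons[0], st.lons[-1], 20)
        lat = rng.uniform(st.lats[0], st.lats[-1], 20)
        np.testing.assert_allclose(
            cov.sample_field(st, "sst", lon, lat, [st.dates[0]] * 20), 3.5)

    def test_land_cells_excluded_and_renormalized(self):
        vals = np.array([[1.0, 1.0], [9.0, 1.0]])
        mask = np.array([[True, True], [False, True]])  # the 9.0 cell is land
        st = grid_stack(vals, mask=mask)
        mid_lon = 0.5 * (st.lons[0] + st.lons[1])
        mid_lat = 0.5 * (st.lats[0] + st.lats[1])
        assert cov.sample_field(st, "sst", mid_lon, mid_lat, st.dates[0]) == pytest.approx(1.0)

    def test_all_land_stencil_missing(self):
        st = grid_stack(np.ones((2, 2)), mask=np.zeros((2, 2), bool))
        assert np.isnan(cov.sample_field(st, "sst", st.lons[0], st.lats[0], st.dates[0]))

    def test_outside_grid_warns_missing(self):
        st = grid_stack(np.ones((3, 3)))
        with pytest.warns(UserWarning, match="outside grid"):
            out = cov.sample_field(st, "sst", st.lons[-1] + 5.0, st.lats[0], st.dates[0])
        assert np.isnan(out)

    def test_oracle_brute_force_bilinear(self, small_stack):
        """Vectorized sampler equals the direct bilinear formula with land-
        weight renormalization on 1,000 random queries."""
        rng = np.random.default_rng(2)
        lons = rng.uniform(small_stack.lons[0], small_stack.lons[-1], 1000)
        lats = rng.uniform(small_stack.lats[0], small_stack.lats[-1], 1000)
        tidx = rng.integers(0, len(small_stack.dates), 1000)
        dates = small_stack.dates[tidx]
        got = cov.sample_field(small_stack, "sst", lons, lats, dates)
        grid = small_stack.values("sst")
        step = small_stack.grid_step
        scale = float(np.nanstd(grid))
        for q in range(1000):
            fx = (lons[q] - small_stack.lons[0]) / step
            fy = (lats[q] - small_stack.lats[0]) / step
            ix = min(int(np.floor(fx)), len(small_stack.lons) - 2)
            iy = min(int(np.floor(fy)), len(small_stack.lats) - 2)
            tx, ty = fx - ix, fy - iy
            num = den = 0.0
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                w = (ty if dy else 1 - ty) * (tx if dx else 1 - tx)
                if small_stack.sea_mask[iy + dy, ix + dx]:
                    num += w * grid[tidx[q], iy + dy, ix + dx]
                    den += w
            expected = num / den if den > 0 else np.nan
            if np.isnan(expected):
                assert np.isnan(got[q])
            else:
                assert abs(got[q] - expected) < 1e-9 * max(scale, 1.0)


class TestRugosity:
    def test_flat_is_zero(self):
        assert np.all(cov.derive_rugosity(np.full((6, 6), -4000.0)) == 0)

    def test_single_spike_center_sd(self):
        b = np.zeros((5, 5))
        b[2, 2] = 9.0
        r = cov.derive_rugosity(b, window=3)
        assert r[2, 2] == pytest.approx(2.8284271, abs=1e-6)

    def test_degenerate_window(self):
        b = np.random.default_rng(0).normal(size=(4, 4))
        assert np.all(cov.derive_rugosity(b, window=1) == 0)

    def test_edges_use_available_neighbors(self):
        b = np.zeros((4, 4))
        b[0, 0] = 4.0
        r = cov.derive_rugosity(b, window=3)
        # corner window has 4 cells {4,0,0,0}: mean 1, sd = sqrt(3)
        assert r[0, 0] == pytest.approx(np.sqrt(3.0), abs=1e-9)


class TestEKE:
    def test_steady_flow_zero(self):
        u = np.full((10, 3, 3), 0.4)
        v = np.full((10, 3, 3), -0.2)
        assert np.allclose(cov.derive_eke(u, v), 0.0)

    def test_pointwise_value(self):
        u = np.zeros((2, 1, 1))
        v = np.zeros((2, 1, 1))
        u[:, 0, 0] = [-0.3, 0.3]  # anomalies +/- 0.3
        v[:, 0, 0] = [-0.4, 0.4]
        eke = cov.derive_eke(u, v)
        assert eke[0, 0, 0] == pytest.approx(0.125)

    def test_homogeneity(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(8, 4, 4))
        v = rng.normal(size=(8, 4, 4))
        np.testing.assert_allclose(cov.derive_eke(2 * u, 2 * v), 4 * cov.derive_eke(u, v))


class TestTemporalSD:
    def test_constant_zero(self):
        x = np.full((20, 2, 2), 5.0)
        assert np.allclose(cov.derive_temporal_sd(x, 5), 0.0)

    def test_alternating_series_limit(self):
        x = np.empty((400, 1, 1))
        x[:, 0, 0] = np.where(np.arange(400) % 2 == 0, 1.0, -1.0)
        sd = cov.derive_temporal_sd(x, 300)
        assert sd[-1, 0, 0] == pytest.approx(1.0, abs=1e-2)

    def test_window_two_definition(self):
        x = np.zeros((2, 1, 1))
        a, b = 3.0, 7.0
        x[:, 0, 0] = [a, b]
        sd = cov.derive_temporal_sd(x, 2)
        assert sd[1, 0, 0] == pytest.approx(np.std([a, b]))  # ddof=0
        assert sd[0, 0, 0] == 0.0  # single-day history

    def test_window_validation(self):
        with pytest.raises(ValueError):
            cov.derive_temporal_sd(np.zeros((5, 1, 1)), 1)


def eddy_catalog(rows):
    return pd.DataFrame(rows, columns=["id", "date", "polarity", "lon", "lat",
                                       "radius_km", "lifetime_days"]).assign(
        date=lambda d: pd.to_datetime(d["date"]))


class TestEddyDistance:
    DAY = "2001-01-05"

    def test_at_center_zero(self):
        cat = eddy_catalog([(0, self.DAY, "cyclonic", -25.0, 35.0, 80.0, 30)])
        assert cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, cat, "cyclonic") == 0.0

    def test_half_radius(self):
        cat = eddy_catalog([(0, self.DAY, "anticyclonic", -25.0, 35.0, 100.0, 30)])
        from lostyears._geo import destination
        lon, lat = destination(-25.0, 35.0, 90.0, 50.0)
        d = cov.normalized_eddy_distance(lon, lat, self.DAY, cat, "anticyclonic")
        assert d == pytest.approx(0.5, abs=1e-6)

    def test_lifetime_filter(self):
        cat = eddy_catalog([(0, self.DAY, "cyclonic", -25.0, 35.0, 80.0, 10),
                            (1, self.DAY, "cyclonic", -24.0, 35.0, 80.0, 9)])
        assert np.isnan(cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, cat, "cyclonic"))

    def test_wrong_polarity_missing(self):
        cat = eddy_catalog([(0, self.DAY, "cyclonic", -25.0, 35.0, 80.0, 30)])
        assert np.isnan(cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, cat, "anticyclonic"))

    def test_monotonicity_equal_radius(self):
        """With equal radii: adding a farther eddy changes nothing, adding a
        nearer one never increases the value."""
        base = eddy_catalog([(0, self.DAY, "cyclonic", -24.0, 35.0, 80.0, 30)])
        d0 = cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, base, "cyclonic")
        farther = pd.concat([base, eddy_catalog(
            [(1, self.DAY, "cyclonic", -20.0, 38.0, 80.0, 30)])])
        assert cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, farther, "cyclonic") == d0
        nearer = pd.concat([base, eddy_catalog(
            [(2, self.DAY, "cyclonic", -24.9, 35.0, 80.0, 30)])])
        assert cov.normalized_eddy_distance(-25.0, 35.0, self.DAY, nearer, "cyclonic") <= d0

    def test_bulk_matches_scalar(self, small_stack):
        rng = np.random.default_rng(4)
        lons = rng.uniform(small_stack.lons[0], small_stack.lons[-1], 40)
        lats = rng.uniform(small_stack.lats[0], small_stack.lats[-1], 40)
        dates = small_stack.dates[rng.integers(0, len(small_stack.dates), 40)]
        bulk = cov.eddy_distances_bulk(lons, lats, dates, small_stack.eddies)
        for i in range(40):
            for pol, colname in (("cyclonic", "dist_cyclonic"),
                                 ("anticyclonic", "dist_anticyclonic")):
                one = cov.normalized_eddy_distance(lons[i], lats[i], dates[i],
                                                   small_stack.eddies, pol)
                if np.isnan(one):
                    assert np.isnan(bulk[colname][i])
                else:
                    assert bulk[colname][i] == pytest.approx(one, rel=1e-12)


class TestObservationTable:
    def test_all_rows_kept_on_covered_domain(self, observation_table, small_segments):
        t = observation_table
        assert set(t["label"]) == {0, 1}
        assert not t[list(cov.MODEL_VARIABLES)].isna().any().any()
        assert (t["label"] == 1).sum() == sum(len(s) for s in small_segments)

    def test_eddy_free_catalog_raises(self, small_segments, small_pseudo, small_stack):
        empty = cov.CovariateStack(ds=small_stack.ds, sea_mask=small_stack.sea_mask)
        with pytest.raises(ValueError, match="dropped"):
            cov.build_observation_table(small_segments, small_pseudo, empty)

    def test_no_inputs_rejected(self, small_stack):
        with pytest.raises(ValueError):
            cov.build_observation_table([], [], small_stack)

    def test_units_manifest(self, small_stack):
        for v in cov.MODEL_VARIABLES:
            if v in cov.EDDY_VARS:
                continue
            assert small_stack.units.get(v), f"missing units for {v}"
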