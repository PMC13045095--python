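"""Raw-fix filtering, CTCRW smoothing, segmentation and migration exclusion."""

import numpy as np
import pandas as pd
import pytest

from lostyears import _geo
from lostyears import synthetic_data as sd
from lostyears import track_processing as tp
from tests.conftest import make_daily_track, make_segment


class TestPrefilterSpeed:
    def test_slow_track_unchanged(self):
        raw = make_daily_track(n_days=3, dlon=0.2)
        out = tp.prefilter_speed(raw)
        pd.testing.assert_frame_equal(out.fixes, raw.fixes)

    def test_spike_removed(self):
        """A displaced middle fix implying ~10 m/s on both legs is dropped."""
        times = pd.to_datetime(["2001-02-01", "2001-02-02", "2001-02-03"])
        # 10 m/s over 1 day = 864 km ~ 7.8 deg of latitude
        fixes = pd.DataFrame({"time": times, "lon": [-25.0, -25.0, -25.0],
                              "lat": [35.0, 42.8, 35.2], "loc_class": "3"})
        sp = _geo.implied_speeds_mps(fixes["lon"], fixes["lat"], fixes["time"])
        assert np.all(sp > 9)  # hand check of the construction
        out = tp.prefilter_speed(tp.RawTrack("t", fixes))
        assert len(out.fixes) == 2
        assert list(out.fixes["lat"]) == [35.0, 35.2]
        sp = _geo.implied_speeds_mps(out.fixes["lon"], out.fixes["lat"], out.fixes["time"])
        assert np.all(sp <= 2.5)

    def test_duplicate_timestamps_rejected(self):
        times = pd.to_datetime(["2001-02-01", "2001-02-01", "2001-02-03"])
        fixes = pd.DataFrame({"time": times, "lon": [-25.0] * 3,
                              "lat": [35.0, 35.1, 35.2], "loc_class": "3"})
        with pytest.raises(ValueError, match="strictly increasing"):
            tp.RawTrack("t", fixes)

    def test_too_few_fixes(self):
        raw = make_daily_track(n_days=1)
        with pytest.raises(ValueError):
            tp.prefilter_speed(raw)


class TestRegularize:
    def test_noise_free_daily_input_reproduced(self):
        raw = make_daily_track(n_days=20, dlon=0.15, dlat=0.05)
        cls = dict(tp.DEFAULT_CLASS_ERRORS_DEG, **{"3": (0.0, 0.0)})
        reg = tp.regularize(raw, class_errors=cls)
        assert len(reg.data) == 20
        np.testing.assert_allclose(reg.data["lon"], raw.fixes["lon"], atol=1e-6)
        np.testing.assert_allclose(reg.data["lat"], raw.fixes["lat"], atol=1e-6)

    def test_smoothing_beats_raw_observations(self):
        """RMSE(smoothed, true) < RMSE(observed, true) on a noisy track."""
        rng = np.random.default_rng(5)
        n = 60
        dates = pd.date_range("2001-03-01", periods=n, freq="D")
        true_lon = -25 + np.cumsum(rng.normal(0.08, 0.05, n))
        true_lat = 35 + np.cumsum(rng.normal(0.0, 0.06, n))
        noise = 0.15
        fixes = pd.DataFrame({"time": dates,
                              "lon": true_lon + rng.normal(0, noise, n),
                              "lat": true_lat + rng.normal(0, noise, n),
                              "loc_class": "B"})
        cls = dict(tp.DEFAULT_CLASS_ERRORS_DEG, **{"B": (noise, noise)})
        reg = tp.regularize(tp.RawTrack("t", fixes), class_errors=cls)
        rmse_obs = np.sqrt(np.mean((fixes["lon"] - true_lon) ** 2 + (fixes["lat"] - true_lat) ** 2))
        rmse_sm = np.sqrt(np.mean((reg.data["lon"] - true_lon) ** 2 + (reg.data["lat"] - true_lat) ** 2))
        assert rmse_sm < rmse_obs

    def test_gap_interior_has_larger_se(self):
        raw = make_daily_track(n_days=12, dlon=0.1)
        fixes = raw.fixes[~raw.fixes["time"].dt.day.isin([5, 6, 7])].reset_index(drop=True)
        reg = tp.regularize(tp.RawTrack("t", fixes))
        d = reg.data.set_index("date")
        gap_se = d.loc["2001-02-06", "lon_se"]  # middle of the 3-day hole
        obs_se = d.loc["2001-02-03", "lon_se"]
        assert len(reg.data) == 12  # interpolated days are present
        assert gap_se > obs_se

    def test_speed_cap_invariant(self):
        """No adjacent-day implied speed above 2.5 m/s, even for a raw track
        regularized from wildly noisy geolocator fixes."""
        raw = make_daily_track(n_days=40, dlon=0.1, noise_sd=1.2, loc_class="GL", seed=7)
        raw = tp.RawTrack("t", raw.fixes, tag_type="geolocator")
        reg = tp.regularize(raw)
        sp = _geo.implied_speeds_mps(reg.data["lon"], reg.data["lat"], reg.data["date"])
        assert np.all(sp <= 2.5)

    def test_constant_track_degenerate(self):
        raw = make_daily_track(n_days=10, dlon=0.0, dlat=0.0)
        reg = tp.regularize(raw)
        np.testing.assert_allclose(reg.data["lon"], -25.0, atol=1e-5)

    def test_nonfinite_error_sd_rejected(self):
        raw = make_daily_track(n_days=5)
        with pytest.raises(ValueError, match="non-finite"):
            tp.regularize(raw, class_errors={"3": (np.nan, 0.01)})


class TestReroute:
    def test_all_sea_identity(self, small_stack):
        reg = tp.RegularTrack("t", pd.DataFrame({
            "date": pd.date_range("2001-01-05", periods=3),
            "lon": [-25.0, -24.8, -24.6], "lat": [35.0, 35.0, 35.0],
            "lon_se": 0.01, "lat_se": 0.01}))
        assert small_stack.is_sea(-25.0, 35.0)
        out = tp.reroute_on_land(reg, small_stack)
        pd.testing.assert_frame_equal(out.data, reg.data)

    def test_land_position_moved_to_nearest_sea_cell(self, small_stack):
        iy, ix = np.nonzero(~small_stack.sea_mask)
        k = len(iy) // 2
        llon, llat = small_stack.lons[ix[k]], small_stack.lats[iy[k]]
        reg = tp.RegularTrack("t", pd.DataFrame({
            "date": pd.date_range("2001-01-05", periods=1),
            "lon": [llon], "lat": [llat], "lon_se": 0.01, "lat_se": 0.01}))
        out = tp.reroute_on_land(reg, small_stack)
        nlon, nlat = out.data["lon"].iloc[0], out.data["lat"].iloc[0]
        assert small_stack.is_sea(nlon, nlat)
        # oracle: brute-force nearest sea cell
        siy, six = np.nonzero(small_stack.sea_mask)
        d = _geo.haversine_km(llon, llat, small_stack.lons[six], small_stack.lats[siy])
        j = np.argmin(d)
        assert nlon == small_stack.lons[six[j]] and nlat == small_stack.lats[siy[j]]

    def test_far_from_sea_rejected(self, small_stack):
        reg = tp.RegularTrack("t", pd.DataFrame({
            "date": pd.date_range("2001-01-05", periods=1),
            "lon": [small_stack.lons[-1]], "lat": [small_stack.lats[0]],
            "lon_se": 0.01, "lat_se": 0.01}))
        if small_stack.is_sea(small_stack.lons[-1], small_stack.lats[0]):
            pytest.skip("corner happens to be sea")
        with pytest.raises(ValueError, match="km"):
            tp.reroute_on_land(reg, small_stack, max_displacement_km=1.0)


def _regular_from_daily(raw):
    data = pd.DataFrame({"date": raw.fixes["time"], "lon": raw.fixes["lon"],
                         "lat": raw.fixes["lat"], "lon_se": 0.01, "lat_se": 0.01})
    return tp.RegularTrack(raw.track_id, data)


def _drop_days(raw, days):
    fixes = raw.fixes[~raw.fixes["time"].dt.normalize().isin(pd.to_datetime(days))]
    return tp.RawTrack(raw.track_id, fixes.reset_index(drop=True))


class TestSegment:
    def test_no_gap_single_segment(self):
        raw = make_daily_track(n_days=20, dlon=0.1)
        segs = tp.segment(_regular_from_daily(raw), raw)
        assert len(segs) == 1 and len(segs[0]) == 20

    def test_11_day_gap_two_segments(self):
        raw = make_daily_track(n_days=30, dlon=0.1)
        gap_days = pd.date_range("2001-02-11", "2001-02-20")  # 11-day raw gap
        raw2 = _drop_days(raw, gap_days)
        reg = _regular_from_daily(raw)  # interpolated days still present
        segs = tp.segment(reg, raw2)
        assert len(segs) == 2
        assert len(segs[0]) == 10 and len(segs[1]) == 10

    def test_exactly_10_day_gap_not_split(self):
        raw = make_daily_track(n_days=30, dlon=0.1)
        raw2 = _drop_days(raw, pd.date_range("2001-02-11", "2001-02-19"))  # 10.0-day gap
        segs = tp.segment(_regular_from_daily(raw), raw2)
        assert len(segs) == 1 and len(segs[0]) == 30

    def test_short_tail_discarded(self):
        raw = make_daily_track(n_days=26, dlon=0.1)  # 1..26 Feb
        # keep days 1-10, drop 11-22 (11-day raw gap), tail 23-26 = 4 days < 5
        raw2 = _drop_days(raw, pd.date_range("2001-02-11", "2001-02-22"))
        segs = tp.segment(_regular_from_daily(raw), raw2)
        assert len(segs) == 1 and len(segs[0]) == 10

    def test_oracle_brute_force_gap_scan(self):
        """Segmentation equals an independent per-day scan on 200 random
        tracks with random missing-fix patterns."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(8, 45))
            raw = make_daily_track(n_days=n, dlon=0.1, seed=int(rng.integers(1e6)))
            drop = rng.random(n) < 0.35
            drop[0] = drop[-1] = False
            fixes = raw.fixes[~drop].reset_index(drop=True)
            raw2 = tp.RawTrack(raw.track_id, fixes)
            reg = _regular_from_daily(raw)
            segs = tp.segment(reg, raw2, gap_days=3, min_len=4)
            # oracle: mark each regular day as inside/outside a raw gap > 3 d
            t = fixes["time"].values
            keep = np.ones(n, bool)
            for i in range(len(t) - 1):
                if (t[i + 1] - t[i]) / np.timedelta64(1, "D") > 3:
                    keep &= ~((reg.dates.values > t[i]) & (reg.dates.values < t[i + 1]))
            runs = []
            cur = []
            for i in range(n):
                if keep[i]:
                    cur.append(i)
                elif cur:
                    runs.append(cur)
                    cur = []
            if cur:
                runs.append(cur)
            runs = [r for r in runs if len(r) >= 4]
            assert [len(s) for s in segs] == [len(r) for r in runs]
            for s, r in zip(segs, runs):
                np.testing.assert_array_equal(s.dates, reg.dates[r])

    def test_idempotent_on_own_output(self):
        raw = make_daily_track(n_days=30, dlon=0.1)
        raw2 = _drop_days(raw, pd.date_range("2001-02-11", "2001-02-21"))
        segs = tp.segment(_regular_from_daily(raw), raw2)
        for s in segs:
            reg = tp.RegularTrack(s.track_id, pd.DataFrame(
                {"date": s.dates, "lon": s.lons, "lat": s.lats, "lon_se": 0.0, "lat_se": 0.0}))
            raw_like = tp.RawTrack(s.track_id, pd.DataFrame(
                {"time": s.dates, "lon": s.lons, "lat": s.lats, "loc_class": "3"}))
            again = tp.segment(reg, raw_like)
            assert len(again) == 1 and len(again[0]) == len(s)


class TestTrimRelease:
    def test_open_water_release_identity(self):
        seg = make_segment(np.linspace(-25, -23, 20), np.full(20, 35.0))
        assert tp.trim_release([seg], release_from_shore=False) == [seg]

    def test_shore_release_drops_first_week(self):
        seg = make_segment(np.linspace(-25, -23, 20), np.full(20, 35.0))
        out = tp.trim_release([seg], release_from_shore=True)
        assert len(out) == 1 and len(out[0]) == 13
        assert out[0].start == seg.start + pd.Timedelta(days=7)

    def test_short_remnant_dropped(self):
        seg = make_segment(np.linspace(-25, -24, 10), np.full(10, 35.0))
        assert tp.trim_release([seg], release_from_shore=True) == []


class TestMovePersistence:
    def test_straight_track_gamma_one(self):
        raw = make_daily_track(n_days=15, dlon=0.2)
        ps = tp.move_persistence(_regular_from_daily(raw), window_days=7)
        interior = ps.gamma[3:-3]
        np.testing.assert_allclose(interior, 1.0, atol=1e-9)
        # net heading due east
        np.testing.assert_allclose(ps.heading_deg[3:-3], 90.0, atol=1.0)

    def test_stationary_gamma_zero(self):
        raw = make_daily_track(n_days=15, dlon=0.0)
        ps = tp.move_persistence(_regular_from_daily(raw), window_days=7)
        np.testing.assert_allclose(ps.gamma[3:-3], 0.0)

    def test_random_turning_low_gamma(self):
        """Uniform-random headings: window mean cosine -> 0, gamma small."""
        rng = np.random.default_rng(17)
        n = 400
        lon, lat = -25.0, 35.0
        lons, lats = [lon], [lat]
        for _ in range(n - 1):
            h = rng.uniform(0, 360)
            lon, lat = _geo.destination(lon, lat, h, rng.gamma(2.0, 10.0))
            lons.append(lon)
            lats.append(lat)
        reg = tp.RegularTrack("t", pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=n), "lon": lons,
            "lat": lats, "lon_se": 0.0, "lat_se": 0.0}))
        ps = tp.move_persistence(reg, window_days=21)
        # mean-cosine term ~ 0.5 and speed ratio < 1: clearly below the
        # straight-track value of 1
        assert np.nanmean(ps.gamma) < 0.5

    def test_window_too_small(self):
        raw = make_daily_track(n_days=15)
        with pytest.raises(ValueError):
            tp.move_persistence(_regular_from_daily(raw), window_days=2)

    def test_edges_undefined(self):
        raw = make_daily_track(n_days=15, dlon=0.2)
        ps = tp.move_persistence(_regular_from_daily(raw), window_days=7)
        assert np.isnan(ps.gamma[0]) and np.isnan(ps.gamma[-1])


def _convoluted_then_westward(n_local=30, n_west=30, seed=3):
    rng = np.random.default_rng(seed)
    lon, lat = -20.0, 35.0
    lons, lats = [lon], [lat]
    for _ in range(n_local - 1):
        h = rng.uniform(0, 360)
        lon, lat = _geo.destination(lon, lat, h, 12.0)
        lons.append(lon)
        lats.append(lat)
    for _ in range(n_west):
        lon, lat = _geo.destination(lon, lat, 270.0, 45.0)
        lons.append(lon)
        lats.append(lat)
    n = len(lons)
    return tp.RegularTrack("t", pd.DataFrame({
        "date": pd.date_range("2001-01-01", periods=n), "lon": lons,
        "lat": lats, "lon_se": 0.0, "lat_se": 0.0}))


class TestExcludeMigration:
    def test_no_westward_run_identity(self):
        raw = make_daily_track(n_days=30, dlon=0.2)  # eastward
        reg = _regular_from_daily(raw)
        ps = tp.move_persistence(reg)
        segs = [make_segment(raw.fixes["lon"].values, raw.fixes["lat"].values)]
        assert tp.exclude_migration(segs, ps) == segs

    def test_migration_onset_detected(self):
        reg = _convoluted_then_westward()
        ps = tp.move_persistence(reg, window_days=7)
        seg = make_segment(reg.data["lon"].values, reg.data["lat"].values,
                           start="2001-01-01")
        out = tp.exclude_migration([seg], ps, min_run_days=10)
        assert len(out) == 1
        cut = len(out[0])
        # onset at day 31 +/- the window width
        assert abs(cut - 30) <= 7

    def test_fully_migratory_track_removed_with_warning(self):
        lons = -20.0 - 0.5 * np.arange(40)
        seg = make_segment(lons, np.full(40, 35.0))
        reg = tp.RegularTrack("t", pd.DataFrame(
            {"date": seg.dates, "lon": seg.lons, "lat": seg.lats,
             "lon_se": 0.0, "lat_se": 0.0}))
        ps = tp.move_persistence(reg, window_days=7)
        with pytest.warns(UserWarning, match="every segment"):
            out = tp.exclude_migration([seg], ps, min_run_days=10)
        assert out == []

    def test_idempotent(self):
        reg = _convoluted_then_westward()
        ps = tp.move_persistence(reg, window_days=7)
        seg = make_segment(reg.data["lon"].values, reg.data["lat"].values)
        out = tp.exclude_migration([seg], ps, min_run_days=10)
        again = tp.exclude_migration(out, ps, min_run_days=10)
        assert [len(s) for s in again] == [len(s) for s in out]


class TestPipelineInvariants:
    def test_segments_on_sea_and_valid(self, small_segments, small_stack):
        for s in small_segments:
            assert len(s) >= 5
            assert np.all(np.diff(s.dates.values) == np.timedelta64(1, "D"))
            assert np.all(small_stack.is_sea(s.lons, s.lats))

    def test_regularized_speed_bound_on_synthetic(self, small_tracks):
        for t in small_tracks[:3]:
            reg = tp.regularize(tp.prefilter_speed(t))
            sp = _geo.implied_speeds_mps(reg.data["lon"], reg.data["lat"], reg.data["date"])
            assert np.all(sp <= 2.5)
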