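"""Shared fixtures: a small synthetic ocean and processed tracks.

Everything is generated at test time with fixed seeds; the heavier fixtures
are session-scoped so the pipeline stages are exercised once and reused.
"""

import numpy as np
import pandas as pd
import pytest

from lostyears import covariates as cov
from lostyears import pseudo_absence as pa
from lostyears import synthetic_data as sd
from lostyears import track_processing as tp


@pytest.fixture(scope="session")
def small_domain():
    return sd.SyntheticDomain(lon_min=-32.0, lon_max=-18.0, lat_min=28.0,
                              lat_max=42.0, grid_step=0.25, start="2001-01-01",
                              n_days=120)


@pytest.fixture(scope="session")
def small_stack(small_domain):
    stack = sd.gen_environment(small_domain, n_eddies=6, seed=11)
    cov.add_derived_fields(stack)
    return stack


@pytest.fixture(scope="session")
def truth():
    return sd.default_truth()


@pytest.fixture(scope="session")
def small_tracks(small_stack, truth):
    return sd.gen_tracks(small_stack, truth, n_tracks=6, seed=12)


@pytest.fixture(scope="session")
def small_segments(small_stack, small_tracks):
    segs = []
    for t in small_tracks:
        f = tp.prefilter_speed(t)
        r = tp.reroute_on_land(tp.regularize(f), small_stack)
        s = tp.segment(r, f)
        segs.extend(tp.trim_release(s, t.release_from_shore))
    assert segs
    return segs


@pytest.fixture(scope="session")
def small_pseudo(small_segments, small_stack):
    out = []
    for s in small_segments:
        d = pa.empirical_steps(s)
        reps = pa.simulate_crw(s, d, n_rep=20, stack=small_stack, seed=13)
        kept, _ = pa.filter_crw(reps, small_stack)
        out.extend(kept)
    assert out
    return out


@pytest.fixture(scope="session")
def observation_table(small_segments, small_pseudo, small_stack):
    return cov.build_observation_table(small_segments, small_pseudo, small_stack)


def make_daily_track(track_id="t0", n_days=30, lon0=-25.0, lat0=35.0,
                     dlon=0.2, dlat=0.0, start="2001-02-01", loc_class="3",
                     noise_sd=0.0, seed=0):
    """A simple raw track with one exactly-daily fix at 00:00 UTC."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    lons = lon0 + dlon * np.arange(n_days) + rng.normal(0, noise_sd, n_days)
    lats = lat0 + dlat * np.arange(n_days) + rng.normal(0, noise_sd, n_days)
    fixes = pd.DataFrame({"time": dates, "lon": lons, "lat": lats,
                          "loc_class": loc_class})
    return tp.RawTrack(track_id=track_id, fixes=fixes)


def make_segment(lons, lats, start="2001-02-01", segment_id="s0", track_id="t0"):
    lons = np.asarray(lons, dtype=float)
    dates = pd.date_range(start, periods=len(lons), freq="D")
    return tp.TrackSegment(segment_id, track_id, dates, lons, np.asarray(lats, float))


@pytest.fixture(scope="session")
def all_sea_stack():
    """A tiny all-sea stack with constant currents for rule fixtures."""
    import xarray as xr
    lons = -30.0 + 0.25 * np.arange(41)
    lats = 30.0 + 0.25 * np.arange(41)
    dates = pd.date_range("2001-01-01", periods=120, freq="D")
    shape = (len(dates), len(lats), len(lons))
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), np.full(shape, 0.1, dtype=np.float32)),
            "v": (("time", "lat", "lon"), np.zeros(shape, dtype=np.float32)),
        },
        coords={"time": dates, "lat": lats, "lon": lons},
    )
    return cov.CovariateStack(ds=ds, sea_mask=np.ones((len(lats), len(lons)), bool))
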