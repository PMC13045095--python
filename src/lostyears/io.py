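"""File dialects: track/segment/pseudo/eddy CSVs and NetCDF covariate stacks.

All CSV timestamps are ISO-8601 UTC. Malformed rows are rejected with their
line numbers. NetCDF files use CF-style lon/lat/time coordinates (written
through xarray's NetCDF-3 backend; the land mask travels as an int8
variable). Writing then reading any of these files is the identity on all
fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from lostyears.covariates import CovariateStack
from lostyears.pseudo_absence import PseudoTrack
from lostyears.track_processing import RawTrack, TrackSegment

TRACK_COLUMNS = ["track_id", "timestamp", "lon", "lat", "loc_class",
                 "tag_type", "release_from_shore"]


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_tracks(tracks: list[RawTrack], path) -> None:
    rows = []
    for t in tracks:
        for _, r in t.fixes.iterrows():
            rows.append((t.track_id, r["time"].strftime("%Y-%m-%dT%H:%M:%SZ"),
                         r["lon"], r["lat"], r["loc_class"], t.tag_type,
                         t.release_from_shore))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False, float_format="%.8f")


def read_tracks(path) -> list[RawTrack]:
    """Parse a track CSV; malformed rows raise with their line numbers."""
    df = pd.read_csv(path, dtype={"track_id": str, "loc_class": str})
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    errors = []
    times = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
    for i, raw_ts in enumerate(df["timestamp"]):
        line = i + 2  # 1-based + header
        try:
            ts = pd.to_datetime(raw_ts, format="%Y-%m-%dT%H:%M:%SZ")
        except (ValueError, TypeError):
            errors.append(f"line {line}: timestamp {raw_ts!r} is not ISO-8601 UTC")
            continue
        times.iloc[i] = ts
    for i, (lon, lat) in enumerate(zip(df["lon"], df["lat"])):
        line = i + 2
        if not (np.isfinite(lon) and -180 <= lon <= 180):
            errors.append(f"line {line}: lon {lon!r} out of [-180, 180]")
        if not (np.isfinite(lat) and -90 <= lat <= 90):
            errors.append(f"line {line}: lat {lat!r} out of [-90, 90]")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors[:20]))
    df = df.assign(time=times)
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        tag_type = str(g["tag_type"].iloc[0])
        shore = bool(np.asarray(g["release_from_shore"].iloc[0]))
        fixes = g[["time", "lon", "lat", "loc_class"]].sort_values("time").reset_index(drop=True)
        tracks.append(RawTrack(track_id=str(tid), fixes=fixes, tag_type=tag_type,
                               release_from_shore=shore))
    return tracks


# ---------------------------------------------------------------------------
# segments / pseudo-absences / eddies
# ---------------------------------------------------------------------------

def write_segments(segments: list[TrackSegment], path) -> None:
    rows = []
    for s in segments:
        for d, lon, lat in zip(s.dates, s.lons, s.lats):
            rows.append((s.segment_id, s.track_id, d.strftime("%Y-%m-%d"), lon, lat))
    pd.DataFrame(rows, columns=["segment_id", "track_id", "date", "lon", "lat"]
                 ).to_csv(path, index=False, float_format="%.8f")


def read_segments(path) -> list[TrackSegment]:
    df = pd.read_csv(path, dtype={"segment_id": str, "track_id": str}, parse_dates=["date"])
    out = []
    for sid, g in df.groupby("segment_id", sort=False):
        g = g.sort_values("date")
        out.append(TrackSegment(sid, str(g["track_id"].iloc[0]),
                                pd.DatetimeIndex(g["date"]), g["lon"].values, g["lat"].values))
    return out


def write_pseudo(pseudo: list[PseudoTrack], path, retained: set | None = None) -> None:
    rows = []
    for p in pseudo:
        flag = retained is None or (p.segment_id, p.replicate) in retained
        for d, lon, lat in zip(p.dates, p.lons, p.lats):
            rows.append((p.segment_id, p.replicate, d.strftime("%Y-%m-%d"), lon, lat, flag))
    pd.DataFrame(rows, columns=["segment_id", "replicate", "date", "lon", "lat",
                                "retained_flag"]).to_csv(path, index=False, float_format="%.8f")


def read_pseudo(path, retained_only: bool = True) -> list[PseudoTrack]:
    df = pd.read_csv(path, dtype={"segment_id": str}, parse_dates=["date"])
    if retained_only:
        df = df[df["retained_flag"]]
    out = []
    for (sid, rep), g in df.groupby(["segment_id", "replicate"], sort=False):
        g = g.sort_values("date")
        out.append(PseudoTrack(sid, int(rep), pd.DatetimeIndex(g["date"]),
                               g["lon"].values, g["lat"].values))
    return out


def write_eddies(eddies: pd.DataFrame, path) -> None:
    df = eddies.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6f")


def read_eddies(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"],
                       dtype={"id": int, "polarity": str})


# ---------------------------------------------------------------------------
# NetCDF stacks and map grids
# ---------------------------------------------------------------------------

def write_stack(stack: CovariateStack, path) -> None:
    ds = stack.ds.copy()
    ds["sea_mask"] = (("lat", "lon"), stack.sea_mask.astype(np.int8))
    for v, unit in stack.units.items():
        if v in ds:
            ds[v].attrs["units"] = unit
    ds.to_netcdf(path, engine="scipy")


def read_stack(path, eddies: pd.DataFrame | None = None) -> CovariateStack:
    ds = xr.load_dataset(path, engine="scipy", decode_timedelta=False)
    if "sea_mask" not in ds:
        raise ValueError(f"{path}: no sea_mask variable")
    allowed = {("lat", "lon"), ("time", "lat", "lon")}
    for v in ds.data_vars:
        if tuple(ds[v].dims) not in allowed:
            raise ValueError(f"{path}: variable {v!r} has dims {ds[v].dims}; "
                             "all variables must share the lon/lat (and time) grid")
    mask = ds["sea_mask"].values.astype(bool)
    units = {v: ds[v].attrs.get("units", "") for v in ds.data_vars if v != "sea_mask"}
    ds = ds.drop_vars("sea_mask")
    if eddies is None:
        eddies = pd.DataFrame(columns=["id", "date", "polarity", "lon", "lat",
                                       "radius_km", "lifetime_days"])
    return CovariateStack(ds=ds, sea_mask=mask, eddies=eddies, units=units)


def write_maps(maps: dict[str, xr.DataArray], path) -> None:
    """Write named 2-D (or 3-D) suitability/persistence grids to one NetCDF."""
    ds = xr.Dataset({k: v for k, v in maps.items()})
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def write_provenance(path, config, stage: str, seeds: dict, counts: dict) -> None:
    from lostyears import __version__
    rec = {
        "stage": stage,
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "seeds": seeds,
        "row_counts": counts,
    }
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True, default=str))
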