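"""Gridded environmental covariates: container, derivation and extraction.

The habitat model uses 17 covariates on a shared daily 0.25 deg lon/lat
lattice: bathymetry and its rugosity; absolute dynamic topography (ADT), sea
level anomaly (SLA) and their temporal standard deviations; mixed layer depth;
sea surface temperature (SST) and its temporal SD; chlorophyll-a; epipelagic
micronekton; net primary productivity; zooplankton; a finite-size Lyapunov
exponent (FSLE) stirring proxy; eddy kinetic energy (EKE) from current
anomalies; and the normalized distances to the closest long-lived cyclonic and
anticyclonic mesoscale eddies (distance to the nearest eddy center of that
polarity divided by that eddy's radius).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from lostyears import _geo

log = logging.getLogger(__name__)

#: base (provided) gridded variables expected in a stack, with units
BASE_UNITS = {
    "bathymetry": "m",
    "adt": "m",
    "sla": "m",
    "mld": "m",
    "sst": "degC",
    "chl": "mg m-3",
    "micronekton": "g m-2",
    "npp": "mg m-2 day-1",
    "zooplankton": "g m-2",
    "fsle": "day-1",
    "u": "m s-1",
    "v": "m s-1",
}

#: derived gridded variables, with units
DERIVED_UNITS = {
    "rugosity": "m",
    "adt_sd": "m",
    "sla_sd": "m",
    "sst_sd": "degC",
    "eke": "m2 s-2",
}

#: eddy-catalog covariates (dimensionless)
EDDY_VARS = ("dist_cyclonic", "dist_anticyclonic")

#: the 17 model covariates, in canonical order
MODEL_VARIABLES = (
    "bathymetry",
    "rugosity",
    "adt",
    "adt_sd",
    "sla",
    "sla_sd",
    "mld",
    "sst",
    "sst_sd",
    "chl",
    "micronekton",
    "npp",
    "zooplankton",
    "fsle",
    "eke",
    "dist_cyclonic",
    "dist_anticyclonic",
)

#: variables with no time axis
STATIC_VARIABLES = ("bathymetry", "rugosity")

#: eddies must have been detected for strictly more than this many days
EDDY_MIN_LIFETIME_DAYS = 10


@dataclass
class CovariateStack:
    """Daily gridded fields + land mask + mesoscale eddy catalog.

    Parameters
    ----------
    ds : xarray.Dataset
        Variables on dims ``(time, lat, lon)`` (static variables on
        ``(lat, lon)``); coordinates are cell centers in degrees.
    sea_mask : numpy.ndarray of bool, shape (nlat, nlon)
        True over sea cells.
    eddies : pandas.DataFrame
        Daily eddy records with columns ``id, date, polarity, lon, lat,
        radius_km, lifetime_days``. May be empty.
    units : dict
        Variable name -> unit string.
    """

    ds: xr.Dataset
    sea_mask: np.ndarray
    eddies: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "date", "polarity", "lon", "lat", "radius_km", "lifetime_days"]))
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        ny, nx = self.sea_mask.shape
        if self.ds.sizes["lat"] != ny or self.ds.sizes["lon"] != nx:
            raise ValueError("sea mask shape does not match grid")
        if not self.units:
            self.units = {v: BASE_UNITS.get(v, DERIVED_UNITS.get(v, "")) for v in self.ds.data_vars}
        if len(self.eddies) and not isinstance(self.eddies["date"].iloc[0], pd.Timestamp):
            self.eddies = self.eddies.assign(date=pd.to_datetime(self.eddies["date"]))

    # -- axis helpers -------------------------------------------------------
    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    @property
    def grid_step(self) -> float:
        return float(self.lons[1] - self.lons[0])

    def has_var(self, name: str) -> bool:
        return name in self.ds.data_vars

    def values(self, name: str) -> np.ndarray:
        """Raw ndarray for a variable: (time, lat, lon) or (lat, lon)."""
        return self.ds[name].values

    def nearest_cell(self, lon, lat):
        """Row/col indices of the nearest grid cell (clipped to the grid)."""
        ix = np.clip(np.rint((np.asarray(lon, float) - self.lons[0]) / self.grid_step).astype(int),
                     0, len(self.lons) - 1)
        iy = np.clip(np.rint((np.asarray(lat, float) - self.lats[0]) / self.grid_step).astype(int),
                     0, len(self.lats) - 1)
        return iy, ix

    def is_sea(self, lon, lat):
        """Whether the nearest grid cell to each point is sea."""
        iy, ix = self.nearest_cell(lon, lat)
        return self.sea_mask[iy, ix]

    def time_index(self, dates):
        """Positions of calendar days on the time axis (-1 when absent)."""
        axis = self.dates
        idx = axis.get_indexer(pd.DatetimeIndex(pd.to_datetime(dates)).normalize())
        return idx


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def sample_field(stack: CovariateStack, var: str, lon, lat, date=None) -> np.ndarray:
    """Bilinear, land-aware sampling of a gridded variable at points.

    The four surrounding cell centers form the stencil; land cells are
    excluded and the remaining bilinear weights renormalized. Returns NaN when
    the whole stencil is land, when the point falls outside the cell-center
    hull, or when the date is off-axis. Fields are daily, so dates match
    exactly (same-day).

    Parameters are scalars or equal-length arrays; a scalar query returns a
    float.
    """
    if not stack.has_var(var):
        raise KeyError(f"variable {var!r} not in stack")
    scalar = np.isscalar(lon) and np.isscalar(lat)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = len(lon)

    lons, lats = stack.lons, stack.lats
    step = stack.grid_step
    fx = (lon - lons[0]) / step
    fy = (lat - lats[0]) / step
    inside = (fx >= 0) & (fx <= len(lons) - 1) & (fy >= 0) & (fy <= len(lats) - 1)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} query point(s) outside grid; returning NaN")
    ix0 = np.clip(np.floor(fx).astype(int), 0, len(lons) - 2)
    iy0 = np.clip(np.floor(fy).astype(int), 0, len(lats) - 2)
    tx = np.clip(fx - ix0, 0.0, 1.0)
    ty = np.clip(fy - iy0, 0.0, 1.0)

    static = var in STATIC_VARIABLES or "time" not in stack.ds[var].dims
    grid = stack.values(var)
    if static:
        it = np.zeros(n, dtype=int)
        data = grid[np.newaxis]
    else:
        if date is None:
            raise ValueError(f"variable {var!r} is time-varying; date required")
        dates = np.atleast_1d(pd.to_datetime(date))
        if len(dates) == 1 and n > 1:
            dates = dates.repeat(n)
        it = stack.time_index(dates)
        if np.any(it < 0):
            warnings.warn("query date(s) outside stack time axis; returning NaN")
        data = grid

    out = np.zeros(n, dtype=float)
    wsum = np.zeros(n, dtype=float)
    it_safe = np.clip(it, 0, data.shape[0] - 1)
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        iy, ix = iy0 + dy, ix0 + dx
        w = (ty if dy else 1.0 - ty) * (tx if dx else 1.0 - tx)
        w = w * stack.sea_mask[iy, ix]
        vals = data[it_safe, iy, ix].astype(float)
        w = np.where(np.isfinite(vals), w, 0.0)
        out += w * np.where(np.isfinite(vals), vals, 0.0)
        wsum += w
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, out / np.where(wsum > 0, wsum, 1.0), np.nan)
    out = np.where(inside & (it >= 0), out, np.nan)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Derived grids
# ---------------------------------------------------------------------------

def derive_rugosity(bathymetry: np.ndarray, window: int = 3) -> np.ndarray:
    """Seafloor rugosity: neighborhood SD (ddof=0) of bathymetry, in meters.

    Edge cells use the neighbors that exist. ``window`` is the side of the
    square neighborhood in cells; a 1x1 window gives 0 everywhere.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    b = np.asarray(bathymetry, dtype=float)
    if window == 1:
        return np.zeros_like(b)
    half = window // 2
    # summed-area approach with edge-aware counts
    padded = np.pad(b, half, mode="constant", constant_values=np.nan)
    ny, nx = b.shape
    s = np.zeros_like(b)
    s2 = np.zeros_like(b)
    cnt = np.zeros_like(b)
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            block = padded[half + dy: half + dy + ny, half + dx: half + dx + nx]
            valid = np.isfinite(block)
            vals = np.where(valid, block, 0.0)
            s += vals
            s2 += vals ** 2
            cnt += valid
    mean = s / cnt
    var = s2 / cnt - mean ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def derive_eke(u: np.ndarray, v: np.ndarray, climatology_window: int | None = None) -> np.ndarray:
    """Eddy kinetic energy 0.5*(u'^2 + v'^2) in m2/s2.

    Anomalies are relative to the per-cell temporal mean over
    ``climatology_window`` trailing days (default: the full series).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 3:
        raise ValueError("u and v must be (time, lat, lon) grids of equal shape")
    if climatology_window is None or climatology_window >= u.shape[0]:
        ubar = np.nanmean(u, axis=0, keepdims=True)
        vbar = np.nanmean(v, axis=0, keepdims=True)
    else:
        ubar = _trailing_mean(u, climatology_window)
        vbar = _trailing_mean(v, climatology_window)
    return 0.5 * ((u - ubar) ** 2 + (v - vbar) ** 2)


def _trailing_sums(x: np.ndarray, window: int):
    """Trailing-window sum, sum of squares and count (window includes today,
    shorter at the head of the series)."""
    nt = x.shape[0]
    flat = x.reshape(nt, -1).astype(np.float64)
    c1 = np.cumsum(np.nan_to_num(flat), axis=0)
    c2 = np.cumsum(np.nan_to_num(flat) ** 2, axis=0)
    cn = np.cumsum(np.isfinite(flat).astype(np.float64), axis=0)
    s1 = c1.copy()
    s2 = c2.copy()
    n = cn.copy()
    if nt > window:
        s1[window:] = c1[window:] - c1[:-window]
        s2[window:] = c2[window:] - c2[:-window]
        n[window:] = cn[window:] - cn[:-window]
    return s1, s2, n, x.shape


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    s1, _, n, shape = _trailing_sums(x, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = s1 / n
    return m.reshape(shape)


def derive_temporal_sd(var: np.ndarray, window_days: int) -> np.ndarray:
    """Per cell-day trailing-window temporal SD (ddof=0) of a daily grid.

    The window includes the current day; the first ``window_days - 1`` days
    use whatever history exists (a single day gives SD 0).
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    x = np.asarray(var, dtype=float)
    s1, s2, n, shape = _trailing_sums(x, window_days)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        v = s2 / n - mean ** 2
    sd = np.sqrt(np.clip(v, 0.0, None)).reshape(shape)
    sd[~np.isfinite(x)] = np.nan
    return sd


def add_derived_fields(stack: CovariateStack, sd_window_days: int = 30,
                       rugosity_window: int = 3,
                       eke_climatology_window: int | None = None) -> CovariateStack:
    """Attach rugosity, EKE and the SST/ADT/SLA temporal-SD grids in place."""
    ds = stack.ds
    dims2 = ("lat", "lon")
    dims3 = ("time", "lat", "lon")
    if "rugosity" not in ds:
        ds["rugosity"] = (dims2, derive_rugosity(stack.values("bathymetry"), rugosity_window).astype(np.float32))
    if "eke" not in ds:
        ds["eke"] = (dims3, derive_eke(stack.values("u"), stack.values("v"),
                                       eke_climatology_window).astype(np.float32))
    for base in ("sst", "adt", "sla"):
        name = f"{base}_sd"
        if name not in ds:
            ds[name] = (dims3, derive_temporal_sd(stack.values(base), sd_window_days).astype(np.float32))
    for v, unit in DERIVED_UNITS.items():
        stack.units.setdefault(v, unit)
    return stack


# ---------------------------------------------------------------------------
# Eddy catalog covariates
# ---------------------------------------------------------------------------

def normalized_eddy_distance(lon, lat, date, catalog: pd.DataFrame, polarity: str,
                             min_lifetime_days: int = EDDY_MIN_LIFETIME_DAYS) -> float:
    """Distance to the closest long-lived eddy of a polarity, over its radius.

    Only eddies detected for strictly more than ``min_lifetime_days`` days
    qualify. Returns NaN when no qualifying eddy exists on that date.
    """
    if polarity not in ("cyclonic", "anticyclonic"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if catalog is None or len(catalog) == 0:
        return float("nan")
    day = pd.to_datetime(date).normalize()
    sub = catalog[(catalog["polarity"] == polarity)
                  & (catalog["lifetime_days"] > min_lifetime_days)
                  & (catalog["date"] == day)]
    if len(sub) == 0:
        return float("nan")
    d = _geo.haversine_km(lon, lat, sub["lon"].values, sub["lat"].values)
    i = int(np.argmin(d))
    return float(d[i] / sub["radius_km"].values[i])


def eddy_distances_bulk(lons, lats, dates, catalog: pd.DataFrame,
                        min_lifetime_days: int = EDDY_MIN_LIFETIME_DAYS) -> pd.DataFrame:
    """Vectorized (per-day) normalized eddy distances for many points.

    Returns a DataFrame with columns ``dist_cyclonic`` / ``dist_anticyclonic``
    aligned with the input order; NaN where no qualifying eddy is alive.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    days = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    out = {v: np.full(len(lons), np.nan) for v in EDDY_VARS}
    if catalog is None or len(catalog) == 0:
        return pd.DataFrame(out)
    cat = catalog[catalog["lifetime_days"] > min_lifetime_days]
    by_day = dict(tuple(cat.groupby("date")))
    for day in days.unique():
        sel = np.flatnonzero(days == day)
        sub = by_day.get(day)
        if sub is None or len(sub) == 0:
            continue
        for pol, col in (("cyclonic", "dist_cyclonic"), ("anticyclonic", "dist_anticyclonic")):
            ps = sub[sub["polarity"] == pol]
            if len(ps) == 0:
                continue
            d = _geo.haversine_km(lons[sel, None], lats[sel, None],
                                  ps["lon"].values[None, :], ps["lat"].values[None, :])
            j = np.argmin(d, axis=1)
            out[col][sel] = d[np.arange(len(sel)), j] / ps["radius_km"].values[j]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Observation table
# ---------------------------------------------------------------------------

def extract_covariates(stack: CovariateStack, lons, lats, dates) -> pd.DataFrame:
    """All 17 model covariates at arbitrary points/dates (one row per point)."""
    cols = {}
    for var in MODEL_VARIABLES:
        if var in EDDY_VARS:
            continue
        cols[var] = sample_field(stack, var, lons, lats, dates)
    eddy = eddy_distances_bulk(lons, lats, dates, stack.eddies)
    for var in EDDY_VARS:
        cols[var] = eddy[var].values
    return pd.DataFrame(cols)


def build_observation_table(segments, pseudo, stack: CovariateStack,
                            max_drop_fraction: float = 0.5) -> pd.DataFrame:
    """Assemble the presence / pseudo-absence table with all 17 covariates.

    One row per presence day (label 1) and per retained pseudo-absence day
    (label 0). Rows with any missing covariate are dropped (listwise); per-
    variable missing counts are logged, and losing more than
    ``max_drop_fraction`` of the rows raises (a sign the stack does not cover
    the data domain).
    """
    frames = []
    for seg in segments:
        frames.append(pd.DataFrame({
            "source_id": seg.segment_id, "date": seg.dates,
            "lon": seg.lons, "lat": seg.lats, "label": 1,
        }))
    for pt in pseudo:
        frames.append(pd.DataFrame({
            "source_id": f"{pt.segment_id}/r{pt.replicate}", "date": pt.dates,
            "lon": pt.lons, "lat": pt.lats, "label": 0,
        }))
    if not frames:
        raise ValueError("no segments or pseudo-tracks supplied")
    table = pd.concat(frames, ignore_index=True)
    cov = extract_covariates(stack, table["lon"].values, table["lat"].values, table["date"].values)
    table = pd.concat([table.reset_index(drop=True), cov], axis=1)

    missing_by_var = {v: int(cov[v].isna().sum()) for v in MODEL_VARIABLES if cov[v].isna().any()}
    if missing_by_var:
        log.info("missing covariate values by variable: %s", missing_by_var)
    keep = ~cov.isna().any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop > max_drop_fraction * len(table):
        raise ValueError(
            f"{n_drop}/{len(table)} rows dropped for missing covariates "
            f"(> {max_drop_fraction:.0%}); stack likely does not cover the data domain. "
            f"Missing by variable: {missing_by_var}")
    if n_drop:
        log.info("dropped %d/%d rows with missing covariates", n_drop, len(table))
    return table[keep].reset_index(drop=True)
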