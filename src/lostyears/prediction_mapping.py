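"""Daily suitability prediction, seasonal means and habitat persistence.

The fitted habitat model is applied to every sea cell of the covariate grid
for every day (contemporaneous covariates, never climatologies), giving a
suitability cube in [0, 1]. From the cube derive: per-season mean maps
(spring = Mar-May, summer = Jun-Aug, autumn = Sep-Nov, winter = Dec-Feb, with
December grouped with the following January-February); a data-driven
persistence threshold (the 0.75 quantile of the pooled suitability values
after discarding values below 0.1); and persistence maps — the per-cell
fraction of days with suitability strictly above the threshold, overall, per
season and per year. A generic season/region event tally supports comparing
predictions with e.g. stranding records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from lostyears.covariates import (EDDY_VARS, MODEL_VARIABLES, STATIC_VARIABLES,
                                  CovariateStack, eddy_distances_bulk)
from lostyears.habitat_model import FittedModel

log = logging.getLogger(__name__)

SEASONS = ("spring", "summer", "autumn", "winter")
_MONTH_SEASON = {3: "spring", 4: "spring", 5: "spring",
                 6: "summer", 7: "summer", 8: "summer",
                 9: "autumn", 10: "autumn", 11: "autumn",
                 12: "winter", 1: "winter", 2: "winter"}

PERSISTENCE_FLOOR = 0.1
PERSISTENCE_QUANTILE = 0.75


@dataclass
class PersistenceMaps:
    """Overall, per-season and optionally per-year persistence grids."""

    overall: xr.DataArray
    seasonal: dict[str, xr.DataArray]
    threshold: float
    yearly: dict[int, xr.DataArray] | None = None


def season_of(date) -> str:
    """Meteorological season of a date; December belongs to the winter that
    runs into the following January-February."""
    return _MONTH_SEASON[pd.to_datetime(date).month]


def predict_daily(model: FittedModel, stack: CovariateStack,
                  dates=None) -> xr.DataArray:
    """Predict habitat suitability for every sea cell-day.

    Covariates are taken at cell centers (the same derivations as training);
    a cell-day with any missing covariate is left missing. ``dates`` limits
    prediction to a subset of the stack's days (default: all).
    """
    for var in MODEL_VARIABLES:
        if var not in EDDY_VARS and not stack.has_var(var):
            raise KeyError(f"stack is missing model variable {var!r}")
    lons, lats = stack.lons, stack.lats
    if dates is None:
        dates = stack.dates
    else:
        dates = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    tidx = stack.time_index(dates)
    if np.any(tidx < 0):
        raise ValueError("requested prediction dates outside the stack time axis")
    sea_iy, sea_ix = np.nonzero(stack.sea_mask)
    LONc = lons[sea_ix]
    LATc = lats[sea_iy]
    ncell = len(sea_iy)

    cube = np.full((len(dates), len(lats), len(lons)), np.nan, dtype=np.float32)
    static_cols = {v: stack.values(v)[sea_iy, sea_ix].astype(float)
                   for v in MODEL_VARIABLES if v in STATIC_VARIABLES}
    Xbuf = np.empty((ncell, len(MODEL_VARIABLES)), dtype=float)
    for k, (date, ti) in enumerate(zip(dates, tidx)):
        eddy = eddy_distances_bulk(LONc, LATc, np.repeat(date, ncell), stack.eddies)
        for j, var in enumerate(MODEL_VARIABLES):
            if var in static_cols:
                Xbuf[:, j] = static_cols[var]
            elif var in EDDY_VARS:
                Xbuf[:, j] = eddy[var].values
            else:
                Xbuf[:, j] = stack.values(var)[ti, sea_iy, sea_ix]
        ok = np.isfinite(Xbuf).all(axis=1)
        if ok.any():
            p = model.predict(Xbuf[ok])
            layer = np.full(ncell, np.nan, dtype=np.float32)
            layer[ok] = p
            cube[k, sea_iy, sea_ix] = layer
    return xr.DataArray(cube, coords={"time": dates, "lat": lats, "lon": lons},
                        dims=("time", "lat", "lon"), name="suitability")


def extract_model_vector(stack: CovariateStack, lon: float, lat: float, date) -> np.ndarray:
    """The 17-covariate vector at one cell center/date, in model order."""
    from lostyears.covariates import extract_covariates
    df = extract_covariates(stack, np.array([lon]), np.array([lat]), [date])
    return df[list(MODEL_VARIABLES)].to_numpy(dtype=float)[0]


def seasonal_mean(cube: xr.DataArray) -> dict[str, xr.DataArray]:
    """Per-cell mean suitability for each season across all years, ignoring
    missing days; a cell with no data in a season stays missing."""
    if cube.sizes["time"] == 0:
        raise ValueError("empty cube")
    seasons = np.array([season_of(d) for d in pd.DatetimeIndex(cube["time"].values)])
    out = {}
    for s in SEASONS:
        sel = cube.isel(time=np.flatnonzero(seasons == s))
        out[s] = (sel.mean("time", skipna=True) if sel.sizes["time"]
                  else xr.full_like(cube.isel(time=0, drop=True), np.nan))
    return out


def persistence_threshold(cube: xr.DataArray, floor: float = PERSISTENCE_FLOOR,
                          q: float = PERSISTENCE_QUANTILE) -> float:
    """Data-driven suitability threshold.

    Pools every non-missing cell-day value, discards values below ``floor``,
    and returns the ``q`` quantile (linear interpolation between order
    statistics).
    """
    vals = cube.values
    vals = vals[np.isfinite(vals)]
    vals = vals[vals >= floor]
    if len(vals) == 0:
        raise ValueError(f"no suitability values >= {floor}; threshold undefined")
    return float(np.quantile(vals, q, method="linear"))


def _fraction_above(values: np.ndarray, threshold: float) -> np.ndarray:
    """Per-cell fraction of non-missing days strictly above threshold."""
    finite = np.isfinite(values)
    n = finite.sum(axis=0)
    hits = (np.where(finite, values, -np.inf) > threshold).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return out


def persistence(cube: xr.DataArray, threshold: float, by_season: bool = True,
                by_year: bool = False) -> PersistenceMaps:
    """Persistence maps: fraction of days with suitability strictly greater
    than ``threshold`` (a day exactly at the threshold does not count).

    Seasonal maps restrict the day set per season; yearly maps use calendar
    years, with winter days assigned to the year containing their January
    (so December 2001 counts toward 2002).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    times = pd.DatetimeIndex(cube["time"].values)
    vals = cube.values
    coords = {"lat": cube["lat"], "lon": cube["lon"]}

    def _wrap(arr):
        return xr.DataArray(arr, coords=coords, dims=("lat", "lon"))

    overall = _wrap(_fraction_above(vals, threshold))
    seasonal = {}
    if by_season:
        seasons = np.array([season_of(d) for d in times])
        for s in SEASONS:
            sel = seasons == s
            seasonal[s] = _wrap(_fraction_above(vals[sel], threshold) if sel.any()
                                else np.full(vals.shape[1:], np.nan))
    yearly = None
    if by_year:
        persist_year = np.where(times.month == 12, times.year + 1, times.year)
        yearly = {}
        for yr in np.unique(persist_year):
            sel = persist_year == yr
            yearly[int(yr)] = _wrap(_fraction_above(vals[sel], threshold))
    return PersistenceMaps(overall=overall, seasonal=seasonal,
                           threshold=threshold, yearly=yearly)


def tally_events_by_season(events: pd.DataFrame, regions: list[str]) -> pd.DataFrame:
    """Season x region cross-tab of event counts with percentages.

    ``events`` needs columns ``region`` and ``date``. Returns one row per
    region plus a ``total`` row; columns are per-season counts, per-season
    percentages of the grand total, and the row total.
    """
    out = pd.DataFrame(0, index=list(regions) + ["total"],
                       columns=list(SEASONS), dtype=int)
    if len(events):
        unknown = set(events["region"]) - set(regions)
        if unknown:
            raise ValueError(f"unknown region label(s): {sorted(unknown)}")
        seasons = [season_of(d) for d in pd.to_datetime(events["date"])]
        for region, s in zip(events["region"], seasons):
            out.loc[region, s] += 1
            out.loc["total", s] += 1
    result = out.copy().astype(float)
    grand = out.loc["total"].sum()
    result["n"] = out.sum(axis=1)
    for s in SEASONS:
        result[f"{s}_pct"] = 100.0 * out[s] / grand if grand else 0.0
    result["pct"] = 100.0 * result["n"] / grand if grand else 0.0
    return result
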