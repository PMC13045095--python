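"""Synthetic ocean and telemetry generator with a planted habitat preference.

Every downstream stage of the pipeline is exercised against this module's
output, for which the truth is known exactly:

* ``gen_environment`` builds a daily 0.25 deg covariate stack — SST with a
  meridional and seasonal structure, bathymetry with a mid-basin ridge, an
  eastern shelf/coastal land strip and islands, a meandering geostrophic jet
  plus eddy-induced rotation (divergence-free, streamfunction-derived
  currents), biogeochemical fields, an FSLE stirring proxy, and a mesoscale
  eddy catalog.
* ``true_suitability`` evaluates the planted logistic preference
  ``logistic(intercept + sum_i w_i * covariate_i)``.
* ``gen_tracks`` simulates animals as biased correlated random walks whose
  turn bias points up the suitability gradient, optionally advected by the
  current, observed at irregular times with class-dependent Gaussian noise
  and occasional multi-day gaps.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from lostyears import _geo
from lostyears.covariates import BASE_UNITS, CovariateStack, sample_field
from lostyears.track_processing import RawTrack

KM_PER_DEG = 111.32


@dataclass
class SyntheticDomain:
    """Spatial/temporal extent of the artificial ocean."""

    lon_min: float = -40.0
    lon_max: float = -10.0
    lat_min: float = 20.0
    lat_max: float = 50.0
    grid_step: float = 0.25
    start: str = "2000-01-01"
    n_days: int = 731  # two years

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("degenerate domain: min must be < max on both axes")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.n_lon <= 1 or self.n_lat <= 1:
            raise ValueError("degenerate domain: need more than one cell per axis")

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.grid_step)) + 1
        return self.lon_min + self.grid_step * np.arange(n)

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.grid_step)) + 1
        return self.lat_min + self.grid_step * np.arange(n)

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.grid_step)) + 1

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.grid_step)) + 1

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")


@dataclass
class TruthParams:
    """Planted logistic habitat preference: ground truth for recovery tests."""

    intercept: float
    weights: dict[str, float]

    def __post_init__(self):
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be nonzero")


def default_truth() -> TruthParams:
    """Preference for warm, deep water: SST and bathymetry are the drivers.

    The two drivers carry comparable weight — one dynamic (SST, ~0.3 per
    degC over a ~13 degC meridional range) and one static (bathymetry,
    ~ -8e-4 per m over the plain/ridge/shelf relief) — and are sized so the
    linear predictor spans roughly -3 .. +3 over the default domain with no
    broad saturated plateau: suitability 0.5 sits near 21 degC over -3500 m,
    rising toward warm abyssal water and falling on the cold side and over
    ridges/shelves.
    """
    return TruthParams(intercept=-8.75, weights={"sst": 0.35, "bathymetry": -4e-4})


def _smooth_noise(rng, shape, sigma_cells):
    """Spatially smooth unit-variance random field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_cells, mode="nearest")
    sd = sm.std()
    return sm / (sd if sd > 0 else 1.0)


def _temporal_modes(rng, n_days, n_modes, corr_days=20.0):
    """Smooth AR(1) temporal coefficients, unit variance, (n_modes, n_days)."""
    phi = np.exp(-1.0 / corr_days)
    eps = rng.standard_normal((n_modes, n_days)) * np.sqrt(1 - phi ** 2)
    a = np.zeros((n_modes, n_days))
    a[:, 0] = rng.standard_normal(n_modes)
    for t in range(1, n_days):
        a[:, t] = phi * a[:, t - 1] + eps[:, t]
    return a


def _spacetime_field(rng, nt, ny, nx, n_modes=4, sigma_cells=6.0, corr_days=20.0):
    """Low-rank smooth space-time noise field with ~unit variance."""
    pats = np.stack([_smooth_noise(rng, (ny, nx), sigma_cells) for _ in range(n_modes)])
    amps = _temporal_modes(rng, nt, n_modes, corr_days)
    f = np.tensordot(amps.T, pats, axes=1) / np.sqrt(n_modes)
    return f.astype(np.float32)


def _gen_eddies(rng, domain: SyntheticDomain, n_eddies: int, sea_mask, lons, lats,
                n_concurrent: int = 4) -> pd.DataFrame:
    """Eddy catalog with exactly ``n_eddies`` eddies, all long-lived (> 10 d).

    Eddies are split between the two polarities and arranged in up to
    ``n_concurrent`` parallel chains per polarity, so that (for enough
    eddies) several eddies of each polarity are alive on every day — as in
    real basin-scale eddy atlases, where the distance to the closest eddy is
    a few hundred km, not a basin-width coordinate. With n_eddies >= 2 at
    least one eddy of each polarity is alive on every day, keeping the
    eddy-distance covariates defined everywhere.
    """
    rows = []
    dates = domain.dates
    nt = len(dates)
    sea_iy, sea_ix = np.nonzero(sea_mask)

    def _spawn(eid, polarity, birth, lifetime):
        k = rng.integers(0, len(sea_iy))
        lon, lat = float(lons[sea_ix[k]]), float(lats[sea_iy[k]])
        radius = float(rng.uniform(60.0, 150.0))
        for d in range(lifetime):
            if birth + d >= nt:
                break
            rows.append((eid, dates[birth + d], polarity, lon, lat, radius, lifetime))
            # slow westward drift with jitter, well under 100 km/day
            lon += (-rng.uniform(2.0, 5.0) + rng.normal(0, 1.0)) / (KM_PER_DEG * np.cos(np.radians(lat)))
            lat += rng.normal(0, 1.0) / KM_PER_DEG

    eid = 0
    pol_counts = {"cyclonic": (n_eddies + 1) // 2, "anticyclonic": n_eddies // 2}
    for polarity, n_pol in pol_counts.items():
        if n_pol == 0:
            continue
        n_chains = min(n_concurrent, n_pol)
        chain_sizes = [n_pol // n_chains + (1 if j < n_pol % n_chains else 0)
                       for j in range(n_chains)]
        for m in chain_sizes:
            span = int(np.ceil(nt / m))
            for j in range(m):
                birth = j * span
                lifetime = max(15, min(nt - birth, span + int(rng.integers(2, 10))))
                _spawn(eid, polarity, birth, lifetime)
                eid += 1
    return pd.DataFrame(rows, columns=["id", "date", "polarity", "lon", "lat",
                                       "radius_km", "lifetime_days"])


def gen_environment(domain: SyntheticDomain, n_eddies: int = 48, seed: int = 0) -> CovariateStack:
    """Generate the full synthetic covariate stack (base variables only;
    derived grids are attached by :func:`lostyears.covariates.add_derived_fields`).

    Deterministic: the same (domain, n_eddies, seed) is bit-identical.
    """
    if n_eddies < 0:
        raise ValueError("n_eddies must be >= 0")
    rng = np.random.default_rng(seed)
    lons, lats = domain.lons, domain.lats
    nx, ny, nt = len(lons), len(lats), domain.n_days
    LON, LAT = np.meshgrid(lons, lats)
    dates = domain.dates
    doy = dates.dayofyear.values
    lat_frac = (LAT - domain.lat_min) / (domain.lat_max - domain.lat_min)

    # --- bathymetry: abyssal plain + meridional ridge + eastern shelf/coast + islands
    ridge_lon = domain.lon_min + 0.35 * (domain.lon_max - domain.lon_min)
    bathy = -4800.0 + 2600.0 * np.exp(-((LON - ridge_lon) / 2.5) ** 2)
    coast_lon = domain.lon_max - 1.5
    bathy += 5400.0 / (1.0 + np.exp(-(LON - (coast_lon - 2.0)) / 0.8))
    w_lon = domain.lon_max - domain.lon_min
    w_lat = domain.lat_max - domain.lat_min
    for _ in range(3):  # islands that break the surface
        clon = rng.uniform(domain.lon_min + 0.15 * w_lon, domain.lon_max - 0.25 * w_lon)
        clat = rng.uniform(domain.lat_min + 0.15 * w_lat, domain.lat_max - 0.15 * w_lat)
        bathy += 5600.0 * np.exp(-(((LON - clon) / 0.5) ** 2 + ((LAT - clat) / 0.5) ** 2))
    bathy += 250.0 * _smooth_noise(rng, (ny, nx), 3.0)
    sea_mask = bathy < 0.0
    bathy = bathy.astype(np.float32)

    # --- SST: meridional gradient + seasonal cycle (stronger poleward) + smooth noise
    seasonal = np.cos(2 * np.pi * (doy - 221) / 365.25)  # warmest ~ early August
    sst = (27.5 - 13.0 * lat_frac[None, :, :]
           + (1.0 + 2.5 * lat_frac)[None, :, :] * seasonal[:, None, None]
           + 0.8 * _spacetime_field(rng, nt, ny, nx, sigma_cells=8.0)).astype(np.float32)

    # --- currents from a streamfunction: meandering zonal jet + eddy vortices
    eddies = _gen_eddies(rng, domain, n_eddies, sea_mask, lons, lats)
    # a mid-basin zonal jet in the thermal transition zone, with a large,
    # propagating meander (as Gulf-Stream-class jets have), so the
    # time-mean flow is a broad smeared band rather than a sharp line
    jet_lat0 = domain.lat_min + 0.55 * (domain.lat_max - domain.lat_min)
    jet_u0 = 0.3          # m/s peak
    jet_w = 1.8           # deg half-width
    meander_amp = 3.5     # deg
    meander_wavelength = 15.0
    phase_speed = 2 * np.pi / 60.0  # rad/day
    L = jet_w * KM_PER_DEG * 1000.0
    dy = domain.grid_step * KM_PER_DEG * 1000.0
    dx = dy * np.cos(np.radians(LAT))
    u = np.empty((nt, ny, nx), dtype=np.float32)
    v = np.empty((nt, ny, nx), dtype=np.float32)
    eddies_by_day = dict(tuple(eddies.groupby("date"))) if len(eddies) else {}
    for t in range(nt):
        lat0 = jet_lat0 + meander_amp * np.sin(2 * np.pi * (LON - domain.lon_min) / meander_wavelength
                                               + phase_speed * t)
        psi = -jet_u0 * L * np.tanh((LAT - lat0) / jet_w)
        sub = eddies_by_day.get(dates[t])
        if sub is not None:
            for _, e in sub.iterrows():
                r_m = e.radius_km * 1000.0
                d2 = (((LON - e.lon) * KM_PER_DEG * np.cos(np.radians(e.lat))) ** 2
                      + ((LAT - e.lat) * KM_PER_DEG) ** 2) * 1e6
                sign = 1.0 if e.polarity == "anticyclonic" else -1.0
                psi = psi + sign * 0.25 * r_m * np.exp(-d2 / (2 * r_m ** 2))
        gy, gx = np.gradient(psi, axis=(0, 1))
        u[t] = -(gy / dy)
        v[t] = gx / dx
    # --- sea level from the streamfunction (geostrophic balance, f/g scaling)
    f_over_g = 8.0e-5 / 9.81
    adt_all = np.empty((nt, ny, nx), dtype=np.float32)
    for t in range(nt):
        lat0 = jet_lat0 + meander_amp * np.sin(2 * np.pi * (LON - domain.lon_min) / meander_wavelength
                                               + phase_speed * t)
        adt_all[t] = (-jet_u0 * L * np.tanh((LAT - lat0) / jet_w) * f_over_g)
    adt_all += 0.05 * _spacetime_field(rng, nt, ny, nx, sigma_cells=6.0)
    sla = adt_all - adt_all.mean(axis=0, keepdims=True)

    # --- mixed layer depth: a winter-deepening seasonal cycle that is
    #     stronger poleward, on top of dynamic noise (little static offset)
    mld = (45.0 - 28.0 * lat_frac[None, :, :] * seasonal[:, None, None]
           + 12.0 * _spacetime_field(rng, nt, ny, nx, sigma_cells=5.0))
    mld = np.clip(mld, 8.0, None).astype(np.float32)

    # --- biogeochemistry: mild coastal enhancement plus dominant dynamic
    #     patchiness, with npp / zooplankton / micronekton tied to chl
    dist_coast = np.clip((coast_lon - LON) / 6.0, 0.0, 1.0)
    chl_base = 0.15 + 0.10 * (1.0 - dist_coast)
    chl = (chl_base[None, :, :] * np.exp(0.7 * _spacetime_field(rng, nt, ny, nx, sigma_cells=4.0))
           ).astype(np.float32)
    npp = (250.0 + 900.0 * (chl / (chl + 0.3))
           + 60.0 * _spacetime_field(rng, nt, ny, nx, sigma_cells=5.0)).astype(np.float32)
    zoo = (1.5 + 4.0 * (chl / (chl + 0.4))
           + 0.4 * _spacetime_field(rng, nt, ny, nx, sigma_cells=5.0)).astype(np.float32)
    mnk = (0.8 + 1.8 * (zoo / (zoo + 3.0))
           + 0.2 * _spacetime_field(rng, nt, ny, nx, sigma_cells=5.0)).astype(np.float32)

    # --- FSLE proxy: stretched function of the current shear
    du = np.abs(np.gradient(u, axis=1)) + np.abs(np.gradient(u, axis=2))
    dv = np.abs(np.gradient(v, axis=1)) + np.abs(np.gradient(v, axis=2))
    shear = du + dv
    ref = np.quantile(shear, 0.9) or 1.0
    fsle = (0.02 + 0.25 * (shear / ref) ** 0.7).astype(np.float32)

    coords = {"time": dates, "lat": lats, "lon": lons}
    d3 = ("time", "lat", "lon")
    ds = xr.Dataset(
        {
            "bathymetry": (("lat", "lon"), bathy),
            "sst": (d3, sst),
            "adt": (d3, adt_all),
            "sla": (d3, sla.astype(np.float32)),
            "mld": (d3, mld),
            "chl": (d3, chl),
            "micronekton": (d3, mnk),
            "npp": (d3, npp),
            "zooplankton": (d3, zoo),
            "fsle": (d3, fsle),
            "u": (d3, u),
            "v": (d3, v),
        },
        coords=coords,
    )
    for name in ds.data_vars:
        ds[name].attrs["units"] = BASE_UNITS[name]
    return CovariateStack(ds=ds, sea_mask=sea_mask, eddies=eddies)


# ---------------------------------------------------------------------------
# planted suitability
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _suitability_nocheck(stack: CovariateStack, truth: TruthParams, lon, lat, date):
    """Suitability at points; NaN where a weighted covariate is unavailable."""
    eta = np.full(np.broadcast(np.atleast_1d(lon), np.atleast_1d(lat)).shape,
                  truth.intercept, dtype=float)
    for var, w in truth.weights.items():
        if w == 0:
            continue
        eta = eta + w * np.atleast_1d(sample_field(stack, var, lon, lat, date))
    return _logistic(eta)


def true_suitability(stack: CovariateStack, truth: TruthParams, lon, lat, date) -> float | np.ndarray:
    """Planted habitat suitability in [0, 1] at sea locations.

    Raises for locations whose nearest grid cell is land.
    """
    sea = stack.is_sea(lon, lat)
    if not np.all(sea):
        raise ValueError("true_suitability queried on land")
    out = _suitability_nocheck(stack, truth, lon, lat, date)
    return float(out[0]) if np.isscalar(lon) else out


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

@dataclass
class TrackGenConfig:
    """Knobs for the synthetic telemetry generator.

    Defaults emulate a mixed Argos/geolocator deployment: ~2 fixes/day, a 1%
    daily chance of entering a multi-day transmission gap, moderate
    habitat-gradient bias, and advection by the local current.
    """

    mean_fixes_per_day: float = 2.0
    error_sd_by_class: dict = field(default_factory=lambda: {
        "3": (0.003, 0.003), "2": (0.006, 0.006), "1": (0.014, 0.014),
        "0": (0.05, 0.05), "A": (0.10, 0.10), "B": (0.20, 0.20),
        "GL": (1.0, 1.8),
    })
    class_probs: dict = field(default_factory=lambda: {
        "3": 0.10, "2": 0.15, "1": 0.25, "0": 0.20, "A": 0.15, "B": 0.15})
    p_gap: float = 0.01
    gap_days_range: tuple[int, int] = (3, 14)
    advection: bool = True
    duration_days_range: tuple[int, int] = (100, 200)
    swim_mean_km_day: float = 45.0
    swim_shape: float = 3.0
    swim_max_km_day: float = 120.0   # ~1.4 m/s sustained; well under the 2.5 m/s cap
    bias_strength: float = 0.9       # weight of the uphill-suitability direction
    heading_noise_deg: float = 20.0
    ars_strength: float = 0.0        # area-restricted search: daily travel scales
                                     # by (1 - ars_strength * suitability), so
                                     # residence time rises with habitat quality
    frac_geolocator: float = 0.25
    frac_shore_release: float = 0.2
    boundary_margin_deg: float = 1.5
    start_bias_power: float = 2.0    # release sites sample the population:
                                     # start-cell weight = suitability^power


def _current_at(stack, lon, lat, date):
    u = sample_field(stack, "u", lon, lat, date)
    v = sample_field(stack, "v", lon, lat, date)
    return (0.0 if not np.isfinite(u) else u), (0.0 if not np.isfinite(v) else v)


def _gradient_bearing(stack, truth, lon, lat, date, delta=0.5):
    """Compass bearing of the local suitability gradient (NaN if undefined)."""
    pts_lon = np.array([lon - delta, lon + delta, lon, lon])
    pts_lat = np.array([lat, lat, lat - delta, lat + delta])
    s = _suitability_nocheck(stack, truth, pts_lon, pts_lat, [date] * 4)
    if not np.all(np.isfinite(s)):
        return np.nan
    coslat = np.cos(np.radians(lat))
    ds_de = (s[1] - s[0]) / (2 * delta * coslat)
    ds_dn = (s[3] - s[2]) / (2 * delta)
    if ds_de == 0 and ds_dn == 0:
        return np.nan
    return np.degrees(np.arctan2(ds_de, ds_dn)) % 360.0


def _simulate_true_path(stack, truth, cfg: TrackGenConfig, rng, start_lon, start_lat,
                        start_t: int, n_days: int):
    dom_lons, dom_lats = stack.lons, stack.lats
    lon_lo = dom_lons[0] + cfg.boundary_margin_deg
    lon_hi = dom_lons[-1] - cfg.boundary_margin_deg
    lat_lo = dom_lats[0] + cfg.boundary_margin_deg
    lat_hi = dom_lats[-1] - cfg.boundary_margin_deg
    dates = stack.dates
    lons = [start_lon]
    lats = [start_lat]
    heading = rng.uniform(0, 360)
    for d in range(n_days - 1):
        date = dates[start_t + d]
        lon, lat = lons[-1], lats[-1]
        g = _gradient_bearing(stack, truth, lon, lat, date)
        if np.isfinite(g) and cfg.bias_strength > 0:
            b = cfg.bias_strength
            hx = (1 - b) * np.sin(np.radians(heading)) + b * np.sin(np.radians(g))
            hy = (1 - b) * np.cos(np.radians(heading)) + b * np.cos(np.radians(g))
            heading = np.degrees(np.arctan2(hx, hy)) % 360.0
        # area-restricted search: slow down in good habitat, transit fast
        # through poor habitat
        s_here = _suitability_nocheck(stack, truth, np.array([lon]), np.array([lat]),
                                      [date])[0]
        ars = 1.0 - cfg.ars_strength * (s_here if np.isfinite(s_here) else 0.5)
        step = min(rng.gamma(cfg.swim_shape, cfg.swim_mean_km_day / cfg.swim_shape) * ars,
                   cfg.swim_max_km_day)
        placed = False
        for attempt in range(24):
            h = (heading + rng.normal(0, cfg.heading_noise_deg)
                 + (attempt * 30.0 if attempt else 0.0)) % 360.0
            nlon, nlat = _geo.destination(lon, lat, h, step)
            if cfg.advection:
                cu, cv = _current_at(stack, lon, lat, date)
                nlon = nlon + cu * _geo.KM_PER_DAY_PER_MPS / (KM_PER_DEG * np.cos(np.radians(nlat)))
                nlat = nlat + cv * _geo.KM_PER_DAY_PER_MPS / KM_PER_DEG
            inside = lon_lo <= nlon <= lon_hi and lat_lo <= nlat <= lat_hi
            if inside and stack.is_sea(nlon, nlat):
                heading = h
                placed = True
                break
        if not placed:
            nlon, nlat = lon, lat  # trapped: stay put for a day
        lons.append(float(nlon))
        lats.append(float(nlat))
    return np.array(lons), np.array(lats)


def gen_tracks(stack: CovariateStack, truth: TruthParams, n_tracks: int,
               cfg: TrackGenConfig | None = None, seed: int = 0) -> list[RawTrack]:
    """Simulate ``n_tracks`` synthetic telemetry tracks.

    Each track's true daily path is a habitat-biased, current-advected CRW;
    the observed fixes are irregularly timed, class-noised versions of it
    (kept alongside the truth for recovery tests). Swimming is capped at
    ``swim_max_km_day`` so the true ground speed never exceeds 2.5 m/s plus
    the local current magnitude.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    cfg = cfg or TrackGenConfig()
    if any(np.min(v) < 0 for v in cfg.error_sd_by_class.values()):
        raise ValueError("error SDs must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(n_tracks)
    dates = stack.dates
    sea_iy, sea_ix = np.nonzero(stack.sea_mask)
    # candidate starts away from the boundary
    margin = cfg.boundary_margin_deg + 1.0
    ok = ((stack.lons[sea_ix] > stack.lons[0] + margin)
          & (stack.lons[sea_ix] < stack.lons[-1] - margin)
          & (stack.lats[sea_iy] > stack.lats[0] + margin)
          & (stack.lats[sea_iy] < stack.lats[-1] - margin))
    cand_lon, cand_lat = stack.lons[sea_ix[ok]], stack.lats[sea_iy[ok]]
    if len(cand_lon) == 0:
        raise ValueError("no interior sea cells to start tracks from")

    tracks = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tag_type = "geolocator" if rng.random() < cfg.frac_geolocator else "argos"
        shore = bool(rng.random() < cfg.frac_shore_release)
        n_days = min(int(rng.integers(*cfg.duration_days_range)), len(dates))
        start_t = int(rng.integers(0, len(dates) - n_days + 1))
        # animals are tagged where animals are: release sites sample the
        # population, so start cells are drawn with weight proportional to
        # the true suitability at deployment time
        s0 = _suitability_nocheck(stack, truth, cand_lon, cand_lat,
                                  np.repeat(dates[start_t], len(cand_lon)))
        w = np.where(np.isfinite(s0), s0, 0.0)
        if cfg.start_bias_power > 0 and w.sum() > 0:
            w = w ** cfg.start_bias_power
            p = w / w.sum()
        else:
            p = np.full(len(cand_lon), 1.0 / len(cand_lon))
        for _ in range(50):
            k = rng.choice(len(cand_lon), p=p)
            s_lon, s_lat = float(cand_lon[k]), float(cand_lat[k])
            if stack.is_sea(s_lon, s_lat):
                break
        else:
            raise RuntimeError("could not place a sea start position")
        t_lons, t_lats = _simulate_true_path(stack, truth, cfg, rng, s_lon, s_lat,
                                             start_t, n_days)
        truth_df = pd.DataFrame({"date": dates[start_t:start_t + n_days],
                                 "lon": t_lons, "lat": t_lats})
        # ---- observation process
        classes = list(cfg.class_probs)
        probs = np.array([cfg.class_probs[c] for c in classes])
        probs = probs / probs.sum()
        rows = []
        gap_until = -1
        for d in range(n_days):
            if d <= gap_until:
                continue
            if cfg.p_gap > 0 and rng.random() < cfg.p_gap and 0 < d < n_days - 2:
                gap_until = d + int(rng.integers(*cfg.gap_days_range))
                continue
            n_fix = rng.poisson(cfg.mean_fixes_per_day)
            if d in (0, n_days - 1):
                n_fix = max(n_fix, 1)
            if n_fix == 0:
                continue
            fracs = np.sort(rng.uniform(0, 1, n_fix))
            for fr in fracs:
                if d < n_days - 1:
                    lon = t_lons[d] + fr * (t_lons[d + 1] - t_lons[d])
                    lat = t_lats[d] + fr * (t_lats[d + 1] - t_lats[d])
                else:
                    lon, lat = t_lons[d], t_lats[d]
                c = "GL" if tag_type == "geolocator" else classes[rng.choice(len(classes), p=probs)]
                sl, st = cfg.error_sd_by_class[c]
                rows.append((dates[start_t + d] + pd.Timedelta(seconds=float(fr) * 86400.0),
                             lon + rng.normal(0, sl), lat + rng.normal(0, st), c))
        fixes = pd.DataFrame(rows, columns=["time", "lon", "lat", "loc_class"])
        fixes = fixes.drop_duplicates(subset="time").sort_values("time").reset_index(drop=True)
        fixes["lon"] = _geo.normalize_lon(fixes["lon"])
        fixes["lat"] = fixes["lat"].clip(-90, 90)
        tracks.append(RawTrack(track_id=f"sim{i:03d}", fixes=fixes, tag_type=tag_type,
                               release_from_shore=shore, truth=truth_df))
    return tracks
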