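"""Spherical-earth geometry used throughout the pipeline.

All public interfaces take and return degrees; internal trigonometry is in
radians. Distances are haversine great-circle distances on a sphere of radius
6371.0088 km (IUGG mean earth radius). Bearings are compass bearings
(0 deg = north, 90 deg = east).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DAY_PER_MPS = 86.4  # 1 m/s sustained for one day
SECONDS_PER_DAY = 86400.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial compass bearing (degrees in [0, 360)) from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination(lon, lat, bearing_deg, distance_km):
    """Destination point after travelling ``distance_km`` along ``bearing_deg``.

    Returns (lon, lat) in degrees with longitude normalized to [-180, 180].
    """
    lon_r = np.radians(np.asarray(lon, dtype=float))
    lat_r = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat_r) * np.cos(delta) + np.cos(lat_r) * np.sin(delta) * np.cos(brg))
    lon2 = lon_r + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat_r),
        np.cos(delta) - np.sin(lat_r) * np.sin(lat2),
    )
    return normalize_lon(np.degrees(lon2)), np.degrees(lat2)


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180]."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_angle_pi(angle_rad):
    """Wrap angles into (-pi, pi]."""
    a = np.asarray(angle_rad, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out


def ground_velocity_mps(lon1, lat1, lon2, lat2, dt_seconds):
    """East/north velocity components (m/s) implied by a displacement.

    The great-circle distance is decomposed along the initial bearing of the
    displacement, giving a locally-flat east/north velocity vector.
    """
    d_km = haversine_km(lon1, lat1, lon2, lat2)
    brg = np.radians(initial_bearing_deg(lon1, lat1, lon2, lat2))
    speed = d_km * 1000.0 / np.asarray(dt_seconds, dtype=float)
    ve = speed * np.sin(brg)
    vn = speed * np.cos(brg)
    # zero displacement has an undefined bearing; the velocity is zero anyway
    zero = d_km == 0
    ve = np.where(zero, 0.0, ve)
    vn = np.where(zero, 0.0, vn)
    return ve, vn


def implied_speeds_mps(lons, lats, times):
    """Adjacent-fix great-circle speeds (m/s) along an ordered track.

    ``times`` is anything convertible to numpy datetime64[ns].
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    t = np.asarray(times, dtype="datetime64[ns]").astype("int64") / 1e9
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    d_km = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    return d_km * 1000.0 / dt
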