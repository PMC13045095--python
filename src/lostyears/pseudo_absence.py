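"""Correlated-random-walk pseudo-absence tracks and the active-speed filter.

Background (availability) data for the presence-only habitat model are built
by simulating, for each presence segment, ``n_rep`` correlated random walks
that start at the segment's first position, resample the segment's own
empirical step-length and turning-angle distributions, share its dates (so
covariates are contemporaneous), and avoid land. A replicate is discarded
when any of its daily steps would have required an active swimming speed
(ground velocity minus the local current vector) above 2 m/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lostyears import _geo
from lostyears.covariates import CovariateStack, sample_field
from lostyears.track_processing import TrackSegment

log = logging.getLogger(__name__)

V_ACTIVE_MAX_MPS = 2.0
N_REP_DEFAULT = 100


@dataclass
class StepDistribution:
    """Empirical daily step lengths (km) and turning angles (radians)."""

    segment_id: str
    steps_km: np.ndarray
    angles_rad: np.ndarray

    @property
    def degenerate(self) -> bool:
        """True when the source segment never moved (no defined angles)."""
        return len(self.angles_rad) == 0 or np.all(self.steps_km == 0)


@dataclass
class PseudoTrack:
    """One CRW replicate, date-matched 1:1 to its source segment."""

    segment_id: str
    replicate: int
    dates: pd.DatetimeIndex
    lons: np.ndarray
    lats: np.ndarray

    def __len__(self):
        return len(self.dates)


def empirical_steps(segment: TrackSegment) -> StepDistribution:
    """Step lengths (successive great-circle distances) and signed turning
    angles (change in bearing between successive steps) of a segment.

    Zero-length steps are kept in the step sample; turning angles that would
    involve an undefined bearing are skipped.
    """
    if len(segment) < 5:
        raise ValueError("segment must have >= 5 positions")
    lons, lats = segment.lons, segment.lats
    steps = _geo.haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    bear = _geo.initial_bearing_deg(lons[:-1], lats[:-1], lons[1:], lats[1:])
    nonzero = steps > 0
    angles = []
    for i in range(len(steps) - 1):
        if nonzero[i] and nonzero[i + 1]:
            angles.append(_geo.wrap_angle_pi(np.radians(bear[i + 1] - bear[i])))
    dist = StepDistribution(segment.segment_id, steps, np.asarray(angles, dtype=float))
    if dist.degenerate:
        log.warning("segment %s: degenerate step distribution (stationary)", segment.segment_id)
    return dist


def simulate_crw(segment: TrackSegment, dist: StepDistribution, n_rep: int = N_REP_DEFAULT,
                 stack: CovariateStack | None = None, seed: int = 0,
                 max_step_redraws: int = 100, max_resim: int = 50) -> list[PseudoTrack]:
    """Simulate ``n_rep`` land-avoiding CRW replicates of a segment.

    Each replicate starts at the segment's first position with a uniform
    random initial bearing and draws step lengths and turning angles
    independently, with replacement, from the empirical distributions. A step
    proposing a land position is redrawn up to ``max_step_redraws`` times;
    a stuck replicate is restarted (up to ``max_resim`` times per replicate)
    before the whole simulation fails naming the segment.
    """
    if dist.degenerate:
        raise ValueError(f"segment {segment.segment_id}: degenerate step distribution")
    n_steps = len(segment) - 1
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, _stable_id(segment.segment_id)]))

    # lockstep simulation of all replicates; failed ones are resimulated
    pending = n_rep
    tracks_lon = []
    tracks_lat = []
    for _ in range(max_resim):
        if pending == 0:
            break
        lons = np.empty((pending, len(segment)))
        lats = np.empty((pending, len(segment)))
        lons[:, 0] = segment.lons[0]
        lats[:, 0] = segment.lats[0]
        heading = rng.uniform(0.0, 360.0, size=pending)
        alive = np.ones(pending, dtype=bool)
        for i in range(n_steps):
            need = alive.copy()
            for _ in range(max_step_redraws):
                idx = np.flatnonzero(need)
                if len(idx) == 0:
                    break
                step = dist.steps_km[rng.integers(len(dist.steps_km), size=len(idx))]
                ang = dist.angles_rad[rng.integers(len(dist.angles_rad), size=len(idx))]
                h = (heading[idx] + np.degrees(ang)) % 360.0
                nlon, nlat = _geo.destination(lons[idx, i], lats[idx, i], h, step)
                if stack is None:
                    ok = np.ones(len(idx), dtype=bool)
                else:
                    ok = (stack.is_sea(nlon, nlat)
                          & (nlon >= stack.lons[0]) & (nlon <= stack.lons[-1])
                          & (nlat >= stack.lats[0]) & (nlat <= stack.lats[-1]))
                good = idx[ok]
                heading[good] = h[ok]
                lons[good, i + 1] = nlon[ok]
                lats[good, i + 1] = nlat[ok]
                need[good] = False
            alive &= ~need  # replicates stuck on this step die and restart
        for k in np.flatnonzero(alive):
            tracks_lon.append(lons[k])
            tracks_lat.append(lats[k])
        survivors = int(alive.sum())
        pending -= survivors
    else:
        if pending > 0:
            raise RuntimeError(
                f"segment {segment.segment_id}: could not simulate {pending} sea-valid "
                f"CRW replicate(s) within the attempt budget")
    return [PseudoTrack(segment.segment_id, rep + 1, segment.dates,
                        tracks_lon[rep], tracks_lat[rep]) for rep in range(n_rep)]


def _stable_id(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


def active_speed(p1: tuple[float, float], p2: tuple[float, float], dt_seconds: float,
                 current_u: float, current_v: float) -> float:
    """Active swimming speed (m/s): |ground velocity - current vector|.

    ``p1``/``p2`` are (lon, lat) in degrees; the ground velocity is the local
    east/north vector implied by the great-circle displacement over
    ``dt_seconds``; the current is its (U east, V north) m/s components.
    """
    if dt_seconds <= 0:
        raise ValueError("dt_seconds must be > 0")
    ve, vn = _geo.ground_velocity_mps(p1[0], p1[1], p2[0], p2[1], dt_seconds)
    return float(np.hypot(ve - current_u, vn - current_v))


def _step_active_speeds(lons, lats, dates, stack: CovariateStack):
    """Active speed of each daily step; current sampled at the step start.

    Returns (speeds, missing_current_flag per step).
    """
    if len(lons) < 2:
        return np.array([]), np.array([], bool)
    u = sample_field(stack, "u", lons[:-1], lats[:-1], dates[:-1])
    v = sample_field(stack, "v", lons[:-1], lats[:-1], dates[:-1])
    dt = np.diff(pd.DatetimeIndex(dates).asi8) / 1e9
    ve, vn = _geo.ground_velocity_mps(lons[:-1], lats[:-1], lons[1:], lats[1:], dt)
    missing = ~(np.isfinite(u) & np.isfinite(v))
    with np.errstate(invalid="ignore"):
        speeds = np.hypot(ve - u, vn - v)
    return speeds, missing


def filter_crw(pseudo: list[PseudoTrack], stack: CovariateStack,
               v_active_max: float = V_ACTIVE_MAX_MPS) -> tuple[list[PseudoTrack], dict]:
    """Remove whole replicates requiring unrealistic active swimming.

    A replicate is excluded if any of its daily steps has an active speed
    strictly greater than ``v_active_max`` (the boundary value is retained),
    or if the current is missing at any of its step-start positions.
    Returns (surviving replicates unchanged, removal-count log).
    """
    if not (stack.has_var("u") and stack.has_var("v")):
        raise ValueError("stack is missing the current components u/v needed by the CRW filter")
    kept = []
    n_speed = 0
    n_missing = 0
    for pt in pseudo:
        speeds, missing = _step_active_speeds(pt.lons, pt.lats, pt.dates, stack)
        if missing.any():
            n_missing += 1
            log.warning("replicate %s/r%d: missing current value; removed",
                        pt.segment_id, pt.replicate)
            continue
        if np.any(speeds > v_active_max):
            n_speed += 1
            continue
        kept.append(pt)
    counts = {"kept": len(kept), "removed_speed": n_speed, "removed_missing_current": n_missing}
    log.info("CRW active-speed filter: %s", counts)
    return kept, counts


def observed_max_active_speed(segments: list[TrackSegment], stack: CovariateStack) -> float:
    """Maximum current-corrected active speed over all presence steps (m/s)."""
    if not segments:
        raise ValueError("empty segment set")
    best = 0.0
    for seg in segments:
        speeds, missing = _step_active_speeds(seg.lons, seg.lats, seg.dates, stack)
        valid = speeds[~missing]
        if len(valid):
            best = max(best, float(np.nanmax(valid)))
    return best
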