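"""Movement simulation: biased correlated random walks with known habitat
preference, colony attendance during breeding, and behaviour states.

The walk is discrete-time (hourly) on the lon/lat plane; at each step the
bird picks a heading with probability proportional to
``exp(kappa * cos(turn) + S(destination))`` where ``S`` is the linear
habitat-preference score (sum of configured weights times per-month
z-standardized predictor fields).  Breeding birds are central-place
foragers: after ``trip_duration`` days at sea they home to the colony,
spend the night in the burrow, and depart again.  Behaviour states
(WATER / FLIGHT / BURROW) are drawn per 10-min block from phase- and
day/night-specific water-occupancy budgets; BURROW occurs only at the
colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .. import solar
from .config import SimConfig

__all__ = ["TrueTrack", "simulate_tracks", "simulate_drift_track", "phase_of_month"]

STATES = ("WATER", "FLIGHT", "BURROW")
COLONY_RADIUS_DEG = 0.35  # within this of the colony counts as "at colony"
NIGHT_HOURS_AT_COLONY = 8


def phase_of_month(month) -> np.ndarray:
    """BREEDING for Dec-May, NONBREEDING for Jun-Nov (array-aware)."""
    m = np.asarray(month)
    return np.where((m >= 12) | (m <= 5), "BREEDING", "NONBREEDING")


@dataclass
class TrueTrack:
    """Ground-truth trajectory with per-10-min behaviour states."""

    bird_id: str
    colony: str
    times: np.ndarray       # hourly, datetime64[s]
    lon: np.ndarray
    lat: np.ndarray
    state_times: np.ndarray  # 10-min block starts, datetime64[s]
    states: np.ndarray       # "WATER" | "FLIGHT" | "BURROW"

    def position_at(self, when) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (lon, lat) at arbitrary UTC times."""
        t0 = self.times.astype("datetime64[s]").astype("int64")
        tq = np.asarray(when, dtype="datetime64[s]").astype("int64")
        return (
            np.interp(tq, t0, self.lon),
            np.interp(tq, t0, self.lat),
        )

    @property
    def phases(self) -> np.ndarray:
        """Phase label per hourly sample."""
        months = self.times.astype("datetime64[M]").astype(int) % 12 + 1
        return phase_of_month(months)


class _ScoreLookup:
    """Nearest-cell lookup of the per-month preference score rasters."""

    def __init__(self, env: xr.Dataset, colony: str, weights_by_phase: dict):
        self.lon = np.asarray(env["lon"], dtype=float)
        self.lat = np.asarray(env["lat"], dtype=float)
        self.cell = float(self.lon[1] - self.lon[0])
        self.months = [int(m) for m in np.asarray(env["month"])]
        self.grids = {}
        for m in self.months:
            phase = str(phase_of_month(m))
            weights = weights_by_phase.get((colony, phase), {})
            score = np.zeros((self.lat.size, self.lon.size))
            for var, w in weights.items():
                layer = env[var]
                if "colony" in layer.dims:
                    layer = layer.sel(colony=colony)
                if "month" in layer.dims:
                    layer = layer.sel(month=m)
                vals = np.asarray(layer, dtype=float)
                z = (vals - np.nanmean(vals)) / (np.nanstd(vals) + 1e-12)
                score += w * np.nan_to_num(z)
            self.grids[m] = score

    def __call__(self, month: int, lon, lat):
        i = np.clip(((lat - self.lat[0]) / self.cell).round().astype(int), 0, self.lat.size - 1)
        j = np.clip(((lon - self.lon[0]) / self.cell).round().astype(int), 0, self.lon.size - 1)
        return self.grids[month][i, j]


def _draw_states(rng, track_times, lon, lat, at_colony, colony, cfg: SimConfig):
    """Per-10-min behaviour states given hourly positions."""
    t0, t1 = track_times[0], track_times[-1]
    block_starts = np.arange(t0, t1, np.timedelta64(600, "s"))
    mid = block_starts + np.timedelta64(300, "s")
    ti = track_times.astype("int64")
    qi = mid.astype("datetime64[s]").astype("int64")
    blon = np.interp(qi, ti, lon)
    blat = np.interp(qi, ti, lat)
    # a block is BURROW only when both bracketing hourly samples are at the
    # colony, so interpolated positions of burrow blocks sit exactly there
    burrow = np.interp(qi, ti, at_colony.astype(float)) > 0.999
    elev = solar.solar_elevation(mid, blon, blat)
    is_day = elev > -12.0  # nautical dawn/dusk boundary
    months = mid.astype("datetime64[M]").astype(int) % 12 + 1
    phases = phase_of_month(months)
    p_water = np.empty(mid.size)
    for phase in ("BREEDING", "NONBREEDING"):
        occ = cfg.water_occupancy[(colony, phase)]
        sel = phases == phase
        p_water[sel] = np.where(is_day[sel], occ["day"], occ["night"])
    states = np.where(rng.random(mid.size) < p_water, "WATER", "FLIGHT").astype("U6")
    states[burrow] = "BURROW"
    return block_starts.astype("datetime64[s]"), states


def _walk_one(rng, score, colony_lonlat, cfg, colony, times, extent):
    """Hourly biased CRW for a single bird; returns lon, lat, at_colony."""
    n = times.size
    lon = np.empty(n)
    lat = np.empty(n)
    at_col = np.zeros(n, dtype=bool)
    clon, clat = colony_lonlat
    lon[0], lat[0] = clon, clat
    at_col[0] = True
    heading = rng.uniform(0, 2 * np.pi)
    months = times.astype("datetime64[M]").astype(int) % 12 + 1
    hours = (times.astype("datetime64[s]").astype("int64") // 3600) % 24
    cand = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    trip_limit_h = cfg.trip_duration_days.get(colony, 6.0) * 24.0
    hours_out = 0.0
    homing = False
    resting = True  # starts in the burrow, leaves at dawn
    lon0, lon1, lat0, lat1 = extent
    for t in range(1, n):
        breeding = str(phase_of_month(months[t])) == "BREEDING"
        px, py = lon[t - 1], lat[t - 1]
        dist_col = np.hypot(px - clon, py - clat)
        if breeding and resting:
            # overnight in the burrow; depart around 06:00 UTC
            if hours[t] == 6:
                resting = False
                hours_out = 0.0
            else:
                lon[t], lat[t], at_col[t] = clon, clat, True
                continue
        if breeding and not homing and hours_out >= trip_limit_h:
            homing = True
        if homing:
            step = min(3.0 * cfg.step_sd_deg, dist_col)
            ang = np.arctan2(clat - py, clon - px)
            lon[t] = px + step * np.cos(ang)
            lat[t] = py + step * np.sin(ang)
            if np.hypot(lon[t] - clon, lat[t] - clat) < COLONY_RADIUS_DEG:
                lon[t], lat[t] = clon, clat
                at_col[t] = True
                homing = False
                resting = True
            heading = ang
            continue
        step = cfg.step_sd_deg * rng.rayleigh(1.0) / np.sqrt(np.pi / 2)
        dx = step * np.cos(cand)
        dy = step * np.sin(cand)
        sc = score(months[t], px + dx, py + dy)
        logw = cfg.turn_concentration * np.cos(cand - heading) + sc
        logw -= logw.max()
        w = np.exp(logw)
        k = rng.choice(cand.size, p=w / w.sum())
        heading = cand[k]
        lon[t] = np.clip(px + dx[k], lon0 + 0.3, lon1 - 0.3)
        lat[t] = np.clip(py + dy[k], lat0 + 0.3, lat1 - 0.3)
        if not breeding:
            continue
        hours_out += 1.0
    return lon, lat, at_col


def simulate_tracks(env: xr.Dataset, config: SimConfig, start="2012-06-01", n_days=60):
    """Simulate all birds of both colonies over ``n_days`` from ``start``.

    Raises ``KeyError`` if a preference variable is missing from ``env``.
    """
    for key, weights in config.preference_weights.items():
        for var in weights:
            if var not in env:
                raise KeyError(f"preference variable {var!r} (for {key}) missing from env")
    t0 = np.datetime64(start, "s")
    times = t0 + np.arange(n_days * 24 + 1) * np.timedelta64(3600, "s")
    extent = tuple(env.attrs.get("extent", SimConfig().extent))
    tracks = []
    for ci, colony in enumerate(sorted(config.n_birds)):
        score = _ScoreLookup(env, colony, config.preference_weights)
        for b in range(config.n_birds[colony]):
            rng = np.random.default_rng([config.seed, 7919, ci, b])
            lon, lat, at_col = _walk_one(
                rng, score, config.colonies[colony], config, colony, times, extent
            )
            st, states = _draw_states(rng, times, lon, lat, at_col, colony, config)
            tracks.append(
                TrueTrack(
                    bird_id=f"{colony}{b:02d}",
                    colony=colony,
                    times=times.copy(),
                    lon=lon,
                    lat=lat,
                    state_times=st,
                    states=states,
                )
            )
    return tracks


def simulate_drift_track(
    lonlat=(-30.0, 40.0),
    start="2012-05-01",
    n_days=60,
    step_sd_deg=0.02,
    reversion=0.01,
    seed=0,
    bird_id="drift00",
):
    """Slow mean-reverting random walk (all-WATER states).

    The reference trajectory for geolocation round-trip experiments: slow
    enough that within-day movement is small against the method's
    resolution, mean-reverting so the bird stays at mid-latitudes.
    """
    rng = np.random.default_rng(seed)
    t0 = np.datetime64(start, "s")
    times = t0 + np.arange(n_days * 24 + 1) * np.timedelta64(3600, "s")
    n = times.size
    lon = np.empty(n)
    lat = np.empty(n)
    lon[0], lat[0] = lonlat
    steps = rng.normal(0.0, step_sd_deg, size=(n - 1, 2))
    for t in range(1, n):
        lon[t] = lon[t - 1] + reversion * (lonlat[0] - lon[t - 1]) + steps[t - 1, 0]
        lat[t] = lat[t - 1] + reversion * (lonlat[1] - lat[t - 1]) + steps[t - 1, 1]
    st = np.arange(times[0], times[-1], np.timedelta64(600, "s")).astype("datetime64[s]")
    states = np.full(st.size, "WATER", dtype="U6")
    return TrueTrack(bird_id, "CI", times, lon, lat, st, states)
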