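"""Threshold light-level geolocation.

From a per-minute light series (0-64, BAS-logger scale) the pipeline
detects twilight threshold crossings, forms sunrise/sunset pairs, and
converts each pair into one position fix: longitude from the time of local
noon (midnight) relative to Greenwich — the pair midpoint corrected by the
equation of time — and latitude from day (night) length through the sunrise
equation

    cos(H) = (sin(alpha) - sin(phi) sin(delta)) / (cos(phi) cos(delta)),

with ``H`` the half-day hour angle, ``alpha`` the calibrated sun elevation
angle for the light threshold, and ``delta`` the solar declination at the
fix time.  Fixes from interrupted light curves and fixes within a week of
the equinoxes (when day length carries no latitude information) are
discarded, and the retained track is smoothed with two passes of a 3-point
moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import solar
from .envfields import great_circle_km

__all__ = [
    "LightSeries",
    "TwilightPair",
    "GeoFix",
    "Calibration",
    "Track",
    "detect_twilights",
    "fix_from_pair",
    "fixes_from_twilights",
    "filter_fixes",
    "smooth_track",
    "geolocate",
    "equinox_window_mask",
    "calibrate_elevation_angle",
]

INTERRUPTION_WINDOW_MIN = 45.0  # extra crossings this close to a pair flag it
MAX_CROSSING_SLOPE = 8.0  # units/min; steeper transitions = shaded twilight


@dataclass
class LightSeries:
    """Per-minute light channel of one logger (integer 0-64)."""

    bird_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    light: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.light = np.asarray(self.light, dtype=float)
        if self.times.size != self.light.size:
            raise ValueError("times and light lengths differ")
        if self.times.size > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.light.size and (self.light.min() < 0 or self.light.max() > 64):
            raise ValueError("light values outside [0, 64]")

    def to_csv(self, path):
        pd.DataFrame(
            {"timestamp_utc": self.times.astype("datetime64[s]"), "light": self.light.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bird_id=None) -> "LightSeries":
        df = pd.read_csv(path, parse_dates=["timestamp_utc"])
        return cls(
            bird_id or str(path),
            df["timestamp_utc"].values.astype("datetime64[s]"),
            df["light"].values,
        )


@dataclass
class TwilightPair:
    """One sunrise/sunset (day pair) or sunset/sunrise (night pair)."""

    first: np.datetime64   # earlier event
    second: np.datetime64  # later event
    kind: str              # "DAY" (sunrise->sunset) or "NIGHT" (sunset->sunrise)
    quality: str           # "CLEAN" | "INTERRUPTED"
    date: np.datetime64    # civil date the pair anchors

    @property
    def sunrise_utc(self):
        return self.first if self.kind == "DAY" else self.second

    @property
    def sunset_utc(self):
        return self.second if self.kind == "DAY" else self.first

    @property
    def midpoint(self) -> np.datetime64:
        return self.first + (self.second - self.first) / 2


@dataclass
class GeoFix:
    """A twice-daily position estimate."""

    time_utc: np.datetime64
    lon: float
    lat: float
    valid: bool = True
    reason: str = "NONE"  # NONE | EQUINOX | BAD_CURVE | UNDEFINED_LAT


@dataclass
class Calibration:
    """Threshold-method calibration constants.

    ``sun_elevation_deg`` defaults are the values fitted at the two study
    colonies (CI: -4.0, SG: -4.5); ``light_threshold`` is on the 0-64
    logger scale.
    """

    light_threshold: float = 10.0
    sun_elevation_deg: dict = field(default_factory=lambda: {"CI": -4.0, "SG": -4.5})

    def __post_init__(self):
        if not 0.0 < self.light_threshold < 64.0:
            raise ValueError("light threshold must lie inside (0, 64)")
        for angle in self.sun_elevation_deg.values():
            if not -12.0 < angle < 0.0:
                raise ValueError("elevation angle must lie in (-12, 0) degrees")

    def angle_for(self, colony: str) -> float:
        return self.sun_elevation_deg[colony]


@dataclass
class Track:
    """Ordered, validated, smoothed fixes of one bird."""

    bird_id: str
    colony: str
    fixes: list
    retention: float = 1.0

    @property
    def lon(self):
        return np.array([f.lon for f in self.fixes])

    @property
    def lat(self):
        return np.array([f.lat for f in self.fixes])

    @property
    def times(self):
        return np.array([f.time_utc for f in self.fixes], dtype="datetime64[s]")

    @property
    def phases(self):
        months = self.times.astype("datetime64[M]").astype(int) % 12 + 1
        return np.where((months >= 12) | (months <= 5), "BREEDING", "NONBREEDING")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bird": self.bird_id,
                "time_utc": self.times,
                "lon": self.lon,
                "lat": self.lat,
                "phase": self.phases,
            }
        )


# ---------------------------------------------------------------------------
# twilight detection


def _crossings(series: LightSeries, threshold: float, presmooth: int = 5):
    """All threshold crossings: (time, direction) with +1 = rising.

    A short rolling-median prefilter (default 5 min) suppresses
    single-minute sensor noise chatter at the threshold while leaving
    >=10-min shading interruptions (which must be detected) intact.
    """
    light = series.light
    if presmooth and presmooth > 1 and light.size >= presmooth:
        light = ndimage.median_filter(light, size=presmooth, mode="nearest")
    t = series.times.astype("int64").astype(float)  # seconds
    above = light > threshold
    idx = np.flatnonzero(above[1:] != above[:-1])
    times, direction, slopes = [], [], []
    for i in idx:
        frac = (threshold - light[i]) / (light[i + 1] - light[i])
        times.append(t[i] + frac * (t[i + 1] - t[i]))
        direction.append(1 if light[i + 1] > light[i] else -1)
        minutes = (t[i + 1] - t[i]) / 60.0
        slopes.append(abs(light[i + 1] - light[i]) / max(minutes, 1e-9))
    return np.array(times), np.array(direction, dtype=int), np.array(slopes)


def _merged_day_runs(times, direction, gap_max_s=3600.0):
    """Sunrise/sunset of each day span, merging brief dark interruptions.

    Runs above threshold separated by short below-threshold gaps (shading
    dips) are merged; each merged run is one candidate day span.
    """
    runs = []
    i = 0
    n = times.size
    while i < n:
        if direction[i] == 1:
            j = i + 1
            while j < n and direction[j] == -1 and j + 1 < n and direction[j + 1] == 1 and (
                times[j + 1] - times[j] <= gap_max_s
            ):
                j += 2  # swallow the dip
            if j < n and direction[j] == -1:
                runs.append((times[i], times[j]))
                i = j + 1
            else:  # run is open at the record end
                i = j + 1
        else:
            i += 1
    return runs


def detect_twilights(
    series: LightSeries, cal: Calibration | None = None, presmooth: int = 5
) -> list:
    """Locate sunrise/sunset pairs from threshold crossings.

    Crossings are interpolated linearly between flanking minutes.  Day
    pairs bracket daylight spans, night pairs bracket the night between
    consecutive day spans.  A pair is flagged INTERRUPTED when extra
    crossings fall inside its span or within 45 min outside its endpoints
    (light-curve interruptions around sunset and sunrise).  A series with
    no crossings (polar day/night) yields an empty list.
    """
    cal = cal or Calibration()
    span_days = (series.times[-1] - series.times[0]) / np.timedelta64(1, "D")
    if span_days < 1.0:
        raise ValueError("light series must span at least one full day")
    times, direction, slopes = _crossings(series, cal.light_threshold, presmooth)
    if times.size == 0:
        return []
    runs = _merged_day_runs(times, direction)
    pairs = []

    def _quality(lo, hi):
        near = (times >= lo - INTERRUPTION_WINDOW_MIN * 60.0) & (
            times <= hi + INTERRUPTION_WINDOW_MIN * 60.0
        )
        if near.sum() > 2:
            return "INTERRUPTED"
        # a twilight swallowed by shading shows as an abnormally abrupt
        # transition through the threshold — another curve interruption
        endpoints = np.isin(times, (lo, hi))
        if (slopes[endpoints] > MAX_CROSSING_SLOPE).any():
            return "INTERRUPTED"
        return "CLEAN"

    def _dt(sec):
        return np.datetime64(int(round(sec)), "s")

    for k, (sr, ss) in enumerate(runs):
        date = np.datetime64(int(sr + (ss - sr) / 2), "s").astype("datetime64[D]")
        pairs.append(TwilightPair(_dt(sr), _dt(ss), "DAY", _quality(sr, ss), date))
        if k + 1 < len(runs):
            nr = runs[k + 1][0]  # next sunrise
            date_n = np.datetime64(int(ss + (nr - ss) / 2), "s").astype("datetime64[D]")
            pairs.append(TwilightPair(_dt(ss), _dt(nr), "NIGHT", _quality(ss, nr), date_n))
    return pairs


# ---------------------------------------------------------------------------
# pair -> fix


def _solve_latitude(half_hour_angle_deg, declination_deg, alpha_deg):
    """Latitude satisfying the sunrise equation, or NaN when undefined.

    Writes ``sin(alpha) = a sin(phi) + b cos(phi)`` with ``a = sin(delta)``
    and ``b = cos(delta) cos(H)``; the root of smallest absolute latitude
    is returned when two exist (the second sits near the pole).
    """
    H = np.deg2rad(half_hour_angle_deg)
    d = np.deg2rad(declination_deg)
    a = np.sin(d)
    b = np.cos(d) * np.cos(H)
    r = np.hypot(a, b)
    s = np.sin(np.deg2rad(alpha_deg)) / r
    if np.abs(s) > 1.0:
        return np.nan
    theta = np.arctan2(b, a)
    cands = [np.arcsin(s) - theta, np.pi - np.arcsin(s) - theta]
    cands = [np.rad2deg(c) for c in cands]
    cands = [c for c in cands if -90.0 <= c <= 90.0]
    if not cands:
        return np.nan
    return min(cands, key=abs)


def fix_from_pair(pair: TwilightPair, cal: Calibration, colony: str = "CI") -> GeoFix:
    """Convert one twilight pair into a position fix.

    Longitude comes from the offset of the pair midpoint (local noon or
    midnight) from Greenwich solar noon/midnight; latitude from the day or
    night length via the sunrise equation at the calibrated sun elevation
    angle.  Degenerate day lengths give an UNDEFINED_LAT fix.
    """
    mid = pair.midpoint
    span_h = (pair.second - pair.first) / np.timedelta64(1, "h")
    if span_h <= 0 or span_h >= 24.0:
        return GeoFix(mid, np.nan, np.nan, False, "UNDEFINED_LAT")
    day_h = span_h if pair.kind == "DAY" else 24.0 - span_h
    # Greenwich apparent noon: 12:00 UTC minus the equation of time
    eot_min = float(solar.equation_of_time(mid))
    day_start = mid.astype("datetime64[D]").astype("datetime64[s]")
    ref = day_start + np.timedelta64(int(round((720 - eot_min) * 60)), "s")
    if pair.kind == "NIGHT":
        ref = ref + np.timedelta64(12 * 3600, "s") * (1 if mid > ref else -1)
    lon = -((mid - ref) / np.timedelta64(1, "h")) * 15.0
    lon = (lon + 180.0) % 360.0 - 180.0
    decl = float(solar.solar_declination(mid))
    lat = _solve_latitude(day_h * 15.0 / 2.0, decl, cal.angle_for(colony))
    if np.isnan(lat):
        return GeoFix(mid, lon, np.nan, False, "UNDEFINED_LAT")
    return GeoFix(mid, float(lon), float(lat), True, "NONE")


def fixes_from_twilights(pairs, cal: Calibration, colony: str = "CI") -> list:
    """All pairs -> fixes, chronological; INTERRUPTED pairs flagged BAD_CURVE."""
    fixes = []
    for pair in pairs:
        fix = fix_from_pair(pair, cal, colony)
        if pair.quality == "INTERRUPTED":
            fix = replace(fix, valid=False, reason="BAD_CURVE")
        fixes.append(fix)
    fixes.sort(key=lambda f: f.time_utc)
    return fixes


# ---------------------------------------------------------------------------
# filtering and smoothing


def equinox_window_mask(times, window_days: int = 7) -> np.ndarray:
    """True where a time falls within +/-window_days of either equinox."""
    t = np.asarray(times, dtype="datetime64[s]")
    years = np.unique(t.astype("datetime64[Y]"))
    mask = np.zeros(t.shape, dtype=bool)
    win = np.timedelta64(window_days * 86400, "s")
    for y in years:
        for eq in (np.timedelta64(78, "D"), np.timedelta64(264, "D")):  # Mar 20, Sep 22
            centre = (y.astype("datetime64[D]") + eq).astype("datetime64[s]") + np.timedelta64(
                12 * 3600, "s"
            )
            mask |= np.abs(t - centre) <= win
    return mask


def filter_fixes(fixes, window_days: int = 7):
    """Flag equinox-window fixes; compute retention = valid / total.

    Returns ``(filtered fixes, retention)``.  Already-invalid fixes
    (BAD_CURVE, UNDEFINED_LAT) keep their reason.  Idempotent.
    """
    out = []
    for f in fixes:
        if f.valid and equinox_window_mask(f.time_utc, window_days):
            f = replace(f, valid=False, reason="EQUINOX")
        out.append(f)
    n = len(out)
    retention = (sum(f.valid for f in out) / n) if n else 0.0
    return out, retention


def _circular_mean_deg(angles):
    a = np.deg2rad(np.asarray(angles, dtype=float))
    m = np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return (m + 180.0) % 360.0 - 180.0


def smooth_track(track: Track, passes: int = 2) -> Track:
    """3-point moving-average smoothing, applied ``passes`` times.

    Endpoints average their two available neighbours; longitudes are
    averaged on the circle so antimeridian-straddling tracks stay put.
    Fewer than 3 valid fixes: returned unchanged with a warning.
    """
    valid_idx = [i for i, f in enumerate(track.fixes) if f.valid]
    if len(valid_idx) < 3:
        warnings.warn("fewer than 3 valid fixes; track returned unsmoothed")
        return track
    lon = np.array([track.fixes[i].lon for i in valid_idx])
    lat = np.array([track.fixes[i].lat for i in valid_idx])
    for _ in range(passes):
        new_lon = lon.copy()
        new_lat = lat.copy()
        for i in range(lon.size):
            lo = max(0, i - 1)
            hi = min(lon.size, i + 2)
            new_lon[i] = _circular_mean_deg(lon[lo:hi])
            new_lat[i] = lat[lo:hi].mean()
        lon, lat = new_lon, new_lat
    fixes = list(track.fixes)
    for k, i in enumerate(valid_idx):
        fixes[i] = replace(fixes[i], lon=float(lon[k]), lat=float(lat[k]))
    return replace(track, fixes=fixes)


def geolocate(
    series: LightSeries,
    colony: str = "CI",
    cal: Calibration | None = None,
    window_days: int = 7,
    smooth_passes: int = 2,
) -> Track:
    """Full chain: twilights -> fixes -> equinox/curve filter -> smoothing."""
    cal = cal or Calibration()
    pairs = detect_twilights(series, cal)
    fixes = fixes_from_twilights(pairs, cal, colony)
    fixes, retention = filter_fixes(fixes, window_days)
    track = Track(series.bird_id, colony, fixes, retention)
    if smooth_passes:
        track = smooth_track(track, smooth_passes)
    return track


def calibrate_elevation_angle(
    series: LightSeries,
    known_lonlat,
    cal: Calibration | None = None,
    angles=np.arange(-9.0, -0.9, 0.1),
) -> float:
    """Fit the sun elevation angle from a known-position deployment.

    Emulates on-colony calibration devices: the angle minimizing the
    median great-circle error of raw fixes against the known position.
    """
    cal = cal or Calibration()
    pairs = [p for p in detect_twilights(series, cal) if p.quality == "CLEAN"]
    if not pairs:
        raise ValueError("no clean twilight pairs in the calibration series")
    best, best_err = None, np.inf
    for angle in angles:
        trial = Calibration(cal.light_threshold, {"X": float(angle)})
        fixes = [fix_from_pair(p, trial, "X") for p in pairs]
        good = [f for f in fixes if f.valid]
        if not good:
            continue
        err = np.median(
            great_circle_km(
                [f.lon for f in good], [f.lat for f in good], known_lonlat[0], known_lonlat[1]
            )
        )
        if err < best_err:
            best, best_err = float(angle), err
    return best
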