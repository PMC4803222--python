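"""Solar geometry for light-level geolocation.

Vectorized NOAA-style solar position (Meeus truncations): declination,
equation of time and apparent solar elevation as functions of UTC time and
position.  One shared implementation is used both by the logger simulator
and by the geolocation estimator, so that round-trip tests exercise the
same astronomy; :func:`solar_declination_crude` is a deliberately degraded
variant for robustness checks (it lets tests break the simulator/estimator
symmetry on purpose).

Angles are degrees throughout; times are UTC ``numpy.datetime64``.
No atmospheric-refraction correction is applied: with threshold
geolocation the calibrated sun-elevation angle absorbs refraction (and
sensor response) wholesale.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "julian_century",
    "solar_declination",
    "solar_declination_crude",
    "equation_of_time",
    "solar_elevation",
    "solar_noon_utc",
    "twilight_times",
]

_UNIX_JD = 2440587.5  # Julian date of 1970-01-01T00:00Z


def _to_seconds(times) -> np.ndarray:
    """UTC datetime64 (any unit) -> float seconds since the Unix epoch."""
    t = np.asarray(times, dtype="datetime64[s]")
    return t.astype("int64").astype(float)


def julian_century(times) -> np.ndarray:
    """Julian centuries since J2000.0 for UTC times."""
    jd = _to_seconds(times) / 86400.0 + _UNIX_JD
    return (jd - 2451545.0) / 36525.0


def _sun_angles(times):
    """Return (declination deg, equation of time minutes)."""
    T = julian_century(times)
    # geometric mean longitude / anomaly of the sun, degrees
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.deg2rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    # obliquity of the ecliptic, corrected
    mean_obl = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    obl = mean_obl + 0.00256 * np.cos(omega)
    oblr = np.deg2rad(obl)
    decl = np.rad2deg(np.arcsin(np.sin(oblr) * np.sin(np.deg2rad(app_long))))
    # equation of time, minutes
    y = np.tan(oblr / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )
    return decl, eot


def solar_declination(times) -> np.ndarray:
    """Solar declination (degrees) at UTC times; accuracy ~0.01 deg."""
    return _sun_angles(times)[0]


def solar_declination_crude(times) -> np.ndarray:
    """Cosine-of-day-of-year declination, no equation of time (~1 deg off).

    Degraded variant used to probe sensitivity of the estimator to the
    astronomy model; never used by the default pipeline.
    """
    doy = (
        np.asarray(times, dtype="datetime64[D]")
        - np.asarray(times, dtype="datetime64[Y]").astype("datetime64[D]")
    ).astype(float)
    return -23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.24)


def equation_of_time(times) -> np.ndarray:
    """Equation of time (minutes): apparent minus mean solar time."""
    return _sun_angles(times)[1]


def solar_elevation(times, lon, lat) -> np.ndarray:
    """True solar elevation (degrees) at UTC times and position(s).

    ``times``, ``lon`` and ``lat`` broadcast against each other.
    """
    decl, eot = _sun_angles(times)
    secs = _to_seconds(times)
    minutes_of_day = (secs / 60.0) % 1440.0
    tst = minutes_of_day + eot + 4.0 * np.asarray(lon, dtype=float)
    hour_angle = tst / 4.0 - 180.0
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    declr = np.deg2rad(decl)
    har = np.deg2rad(hour_angle)
    sin_el = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(har)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def solar_noon_utc(date, lon=0.0) -> np.ndarray:
    """UTC time of local solar noon on ``date`` at longitude ``lon``."""
    day = np.asarray(date, dtype="datetime64[D]")
    approx = day.astype("datetime64[s]") + np.timedelta64(12 * 3600, "s")
    lon = np.asarray(lon, dtype=float)
    # one fixed-point refinement of the equation of time is ample (< 1 s)
    for _ in range(2):
        eot = equation_of_time(approx)
        offset = ((720.0 - 4.0 * lon - eot) * 60.0).astype("timedelta64[s]")
        approx = day.astype("datetime64[s]") + offset
    return approx


def twilight_times(date, lon, lat, elevation_angle):
    """UTC times the sun crosses ``elevation_angle`` on ``date`` (deg).

    Returns ``(dawn, dusk)`` as datetime64[s]; NaT where the sun never
    reaches the angle (polar day/night for that angle).
    """
    noon = solar_noon_utc(date, lon)
    decl = solar_declination(noon)
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    declr = np.deg2rad(decl)
    alphar = np.deg2rad(float(elevation_angle))
    cos_h0 = (np.sin(alphar) - np.sin(latr) * np.sin(declr)) / (np.cos(latr) * np.cos(declr))
    with np.errstate(invalid="ignore"):
        h0 = np.rad2deg(np.arccos(cos_h0))  # NaN when |cos_h0| > 1
    half = h0 * 4.0 * 60.0  # degrees -> seconds of time
    bad = ~np.isfinite(half)
    half = np.where(bad, 0.0, half)
    dawn = noon - half.astype("timedelta64[s]")
    dusk = noon + half.astype("timedelta64[s]")
    if np.ndim(bad) == 0:
        if bad:
            return np.datetime64("NaT"), np.datetime64("NaT")
        return dawn, dusk
    dawn[bad] = np.datetime64("NaT")
    dusk[bad] = np.datetime64("NaT")
    return dawn, dusk
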