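"""Threshold geolocation: twilight detection, the sunrise equation,
filtering rules and track smoothing."""

import numpy as np
import pytest

from glspipe import geoloc
from glspipe.envfields import great_circle_km
from glspipe.geoloc import Calibration, GeoFix, LightSeries, Track, TwilightPair
from glspipe.synth import SimConfig, simulate_drift_track, simulate_light


def _series(light, start="2012-07-01", bird="b0"):
    light = np.asarray(light, dtype=float)
    t = np.datetime64(start, "s") + np.arange(light.size) * np.timedelta64(60, "s")
    return LightSeries(bird, t, light)


def _square_day(rise_min, set_min, n_min=2880):
    """Square-wave light: 64 between the given minutes-of-day, else 0."""
    light = np.zeros(n_min)
    for d in range(n_min // 1440 + 1):
        lo, hi = d * 1440 + rise_min, d * 1440 + set_min
        light[max(0, lo) : min(n_min, hi)] = 64.0
    return _series(light)


def _trapezoid_day(rise_min, set_min, ramp=40, n_min=2880):
    """Realistic light curve: linear twilight ramps over ``ramp`` minutes."""
    m = np.arange(n_min) % 1440
    up = np.clip((m - rise_min) / ramp, 0, 1)
    down = np.clip((set_min + ramp - m) / ramp, 0, 1)
    return _series(64.0 * np.minimum(up, down))


# --- detection -------------------------------------------------------------


def test_square_wave_crossings_at_events():
    pairs = geoloc.detect_twilights(_square_day(360, 1080))
    day = [p for p in pairs if p.kind == "DAY"]
    assert len(day) == 2
    for p in day:
        rise_min = (p.sunrise_utc - p.sunrise_utc.astype("datetime64[D]")) / np.timedelta64(1, "m")
        set_min = (p.sunset_utc - p.sunset_utc.astype("datetime64[D]")) / np.timedelta64(1, "m")
        assert rise_min == pytest.approx(360, abs=3)
        assert set_min == pytest.approx(1080, abs=3)


def test_gradual_twilight_pairs_are_clean():
    pairs = geoloc.detect_twilights(_trapezoid_day(360, 1080))
    assert pairs and all(p.quality == "CLEAN" for p in pairs)


def test_ramp_crossing_interpolated_subminute():
    # light climbs 1 unit/min from 0: crosses 10 exactly at minute 10.0;
    # shift the ramp by half a unit so the crossing falls mid-minute
    light = np.clip(np.arange(2880) % 1440 / 2.0 - 100.0, 0, 64)
    series = _series(light)
    # crossing when (m/2 - 100) = 10 -> minute 220 of each day
    times, direction, _ = geoloc._crossings(series, 10.0, presmooth=0)
    rising = times[direction == 1]
    minute_of_day = (rising / 60.0) % 1440.0
    assert np.allclose(minute_of_day, 220.0, atol=0.01)


def test_shading_spike_flags_interrupted():
    series = _trapezoid_day(360, 1080)
    light = series.light.copy()
    light[540:550] = 0.0  # 10-min mid-morning shading on day 1
    pairs = geoloc.detect_twilights(_series(light))
    day = [p for p in pairs if p.kind == "DAY"]
    assert day[0].quality == "INTERRUPTED"
    assert day[1].quality == "CLEAN"


def test_no_crossings_returns_empty():
    assert geoloc.detect_twilights(_series(np.zeros(2880))) == []
    with pytest.raises(ValueError):
        geoloc.detect_twilights(_series(np.zeros(100)))


# --- pair -> fix -----------------------------------------------------------


def test_greenwich_midpoint_gives_zero_longitude():
    # symmetric 12-h day centred on Greenwich apparent noon -> lon ~ 0
    from glspipe import solar

    noon = solar.solar_noon_utc(np.datetime64("2012-08-01"), 0.0)
    pair = TwilightPair(
        noon - np.timedelta64(6 * 3600, "s"),
        noon + np.timedelta64(6 * 3600, "s"),
        "DAY",
        "CLEAN",
        np.datetime64("2012-08-01"),
    )
    fix = geoloc.fix_from_pair(pair, Calibration(), "CI")
    assert fix.lon == pytest.approx(0.0, abs=0.05)


def test_24h_day_undefined_latitude():
    pair = TwilightPair(
        np.datetime64("2012-07-01T00:00", "s"),
        np.datetime64("2012-07-02T00:00", "s"),
        "DAY",
        "CLEAN",
        np.datetime64("2012-07-01"),
    )
    fix = geoloc.fix_from_pair(pair, Calibration(), "CI")
    assert not fix.valid and fix.reason == "UNDEFINED_LAT"


def test_roundtrip_noise_free_within_half_degree():
    cfg = SimConfig(light_noise_sd=0.0, shading_prob=0.0)
    track = simulate_drift_track((-30.0, 40.0), "2012-07-01", 6, step_sd_deg=0.0, seed=3)
    fixes = geoloc.geolocate(simulate_light(track, cfg), "CI", smooth_passes=0)
    good = [f for f in fixes.fixes if f.valid]
    assert good
    for f in good:
        assert abs(f.lon - (-30.0)) < 0.5
        assert abs(f.lat - 40.0) < 0.5


def test_two_fixes_per_interior_day():
    cfg = SimConfig(light_noise_sd=0.0, shading_prob=0.0)
    track = simulate_drift_track((-30.0, 40.0), "2012-07-01", 10, step_sd_deg=0.0, seed=3)
    fixes = geoloc.geolocate(simulate_light(track, cfg), "CI").fixes
    days, counts = np.unique(
        np.array([f.time_utc for f in fixes if f.valid]).astype("datetime64[D]"),
        return_counts=True,
    )
    assert np.all(counts[1:-1] == 2)


# --- filtering -------------------------------------------------------------


def test_equinox_window_and_retention():
    fixes = [
        GeoFix(np.datetime64("2012-03-20T12:00", "s"), 0.0, 40.0),
        GeoFix(np.datetime64("2012-06-21T12:00", "s"), 0.0, 40.0),
        GeoFix(np.datetime64("2012-09-25T00:00", "s"), 0.0, 40.0),
    ]
    out, retention = geoloc.filter_fixes(fixes)
    assert not out[0].valid and out[0].reason == "EQUINOX"
    assert out[1].valid
    assert not out[2].valid  # Sep 25 is within +/-7 d of Sep 22
    assert retention == pytest.approx(1 / 3)


def test_retention_ratio_arithmetic():
    fixes = [GeoFix(np.datetime64("2012-06-01T12:00", "s") + np.timedelta64(i, "h"), 0.0, 40.0)
             for i in range(100)]
    for i in range(13):
        fixes[i] = GeoFix(fixes[i].time_utc, 0.0, 40.0, False, "BAD_CURVE")
    _, retention = geoloc.filter_fixes(fixes)
    assert retention == pytest.approx(0.87)


def test_filtering_idempotent():
    fixes = [GeoFix(np.datetime64("2012-03-20T12:00", "s"), 0.0, 40.0),
             GeoFix(np.datetime64("2012-06-21T12:00", "s"), 0.0, 40.0)]
    once, r1 = geoloc.filter_fixes(fixes)
    twice, r2 = geoloc.filter_fixes(once)
    assert [(f.valid, f.reason) for f in once] == [(f.valid, f.reason) for f in twice]
    assert r1 == r2


# --- smoothing -------------------------------------------------------------


def _track_from(lons, lats):
    t0 = np.datetime64("2012-06-01T12:00", "s")
    fixes = [
        GeoFix(t0 + np.timedelta64(12 * i, "h"), lon, lat)
        for i, (lon, lat) in enumerate(zip(lons, lats))
    ]
    return Track("b0", "CI", fixes)


def test_smoothing_preserves_collinear_interior():
    tr = _track_from(np.linspace(0, 9, 10), np.linspace(40, 49, 10))
    sm = geoloc.smooth_track(tr, passes=2)
    np.testing.assert_allclose(sm.lon[2:-2], tr.lon[2:-2], atol=1e-9)
    np.testing.assert_allclose(sm.lat[2:-2], tr.lat[2:-2], atol=1e-9)


def test_single_outlier_pulled_by_hand_computed_factor():
    lats = np.full(11, 40.0)
    lats[5] = 43.0  # 3-degree outlier among constants
    tr = _track_from(np.zeros(11), lats)
    one = geoloc.smooth_track(tr, passes=1)
    # one pass: centre value = mean(40, 43, 40) = 41 -> deviation / 3
    assert one.lat[5] == pytest.approx(41.0)
    two = geoloc.smooth_track(tr, passes=2)
    # second pass: neighbours moved to 41 too -> centre stays at 41,
    # flanks at 40 + 2/9 * 3 (hand-evaluated 3-point mean twice)
    assert two.lat[5] == pytest.approx(41.0)
    assert two.lat[4] == pytest.approx(40.0 + 2.0 / 3.0)


def test_smoothing_contractive_path_length():
    rng = np.random.default_rng(2)
    tr = _track_from(rng.uniform(-5, 5, 30), 40 + rng.uniform(-5, 5, 30))
    sm = geoloc.smooth_track(tr, passes=2)

    def path(track):
        return np.sum(great_circle_km(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:]))

    assert path(sm) <= path(tr)


def test_antimeridian_longitudes_average_on_circle():
    tr = _track_from([179.5, -179.5, 179.5], [0.0, 0.0, 0.0])
    sm = geoloc.smooth_track(tr, passes=1)
    assert np.all(np.abs(np.abs(sm.lon) - 180.0) < 1.0)


def test_short_track_returned_unchanged_with_warning():
    tr = _track_from([0.0, 1.0], [40.0, 41.0])
    with pytest.warns(UserWarning):
        sm = geoloc.smooth_track(tr)
    np.testing.assert_array_equal(sm.lon, tr.lon)


# --- calibration -----------------------------------------------------------


def test_calibration_validation():
    with pytest.raises(ValueError):
        Calibration(light_threshold=0.0)
    with pytest.raises(ValueError):
        Calibration(sun_elevation_deg={"CI": -13.0})


def test_elevation_angle_recovered_from_known_position():
    cfg = SimConfig(light_noise_sd=0.0, shading_prob=0.0)
    track = simulate_drift_track((-16.33, 33.06), "2012-07-01", 8, step_sd_deg=0.0, seed=1)
    series = simulate_light(track, cfg)
    angle = geoloc.calibrate_elevation_angle(series, (-16.33, 33.06))
    # the generator's light curve crosses threshold 10 at -4 deg
    assert angle == pytest.approx(-4.0, abs=0.5)


def test_latitude_error_grows_toward_equinox():
    cfg = SimConfig(light_noise_sd=0.0, shading_prob=0.0)
    track = simulate_drift_track((-30.0, 40.0), "2012-08-10", 40, step_sd_deg=0.0, seed=0)
    fixes = geoloc.geolocate(simulate_light(track, cfg), "CI", smooth_passes=0).fixes
    good = [f for f in fixes if f.valid]
    err = np.array([abs(f.lat - 40.0) for f in good])
    days_to_eq = np.array(
        [(np.datetime64("2012-09-22") - f.time_utc.astype("datetime64[D]")) / np.timedelta64(1, "D")
         for f in good]
    )
    far = err[days_to_eq > 30].mean()
    near = err[(days_to_eq <= 20) & (days_to_eq > 7)].mean()
    assert near > far
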