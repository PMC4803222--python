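"""Logger-channel simulation: per-minute light and per-10-min immersion.

The light channel mimics a BAS-type logger: ambient light is a logistic
function of the true solar elevation at the bird's true position, scaled to
the 0-64 integer range, with Gaussian sensor noise, episodic shading
(feathers/burrow entrance shadowing the sensor, geometric duration), and a
hard zero whenever the bird is in its burrow.  The immersion channel
counts wet 3-second conductivity tests per 10-min block, Binomial(200, p)
with p set by the behaviour state.
"""

from __future__ import annotations

import zlib

import numpy as np

from .. import solar
from ..activity import ImmersionSeries
from ..geoloc import LightSeries
from .config import SimConfig
from .tracks import TrueTrack

__all__ = ["simulate_light", "simulate_immersion", "light_response"]


def light_response(elevation_deg, elev0: float = -1.47, scale: float = 1.5):
    """Noise-free logger light level (0-64) for a solar elevation.

    Logistic in elevation; the default midpoint/width are chosen so the
    level crosses the standard threshold of 10 at a sun elevation of
    -4.0 deg, matching the default calibration.
    """
    return 64.0 / (1.0 + np.exp(-(np.asarray(elevation_deg, dtype=float) - elev0) / scale))


def _shading_mask(rng, n: int, occupancy: float, mean_minutes: float) -> np.ndarray:
    """Two-state Markov shading process with given stationary occupancy.

    Events last Geometric(1/mean_minutes) minutes; starts occur at rate
    ``occupancy / ((1 - occupancy) * mean_minutes)`` per unshaded minute so
    the long-run shaded fraction equals ``occupancy``.
    """
    if occupancy <= 0 or n == 0:
        return np.zeros(n, dtype=bool)
    start_rate = min(1.0, occupancy / max(1e-12, (1.0 - occupancy) * mean_minutes))
    starts = rng.random(n) < start_rate
    durations = rng.geometric(1.0 / mean_minutes, size=n)
    mask = np.zeros(n + 1, dtype=np.int64)
    idx = np.flatnonzero(starts)
    ends = np.minimum(idx + durations[idx], n)
    np.add.at(mask, idx, 1)
    np.add.at(mask, ends, -1)
    return np.cumsum(mask[:-1]) > 0


def simulate_light(track: TrueTrack, config: SimConfig | None = None) -> LightSeries:
    """Per-minute light series along a track (integers 0-64)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng([cfg.seed, 211, _bird_stream(track.bird_id)])
    t0 = track.times[0].astype("datetime64[s]")
    t1 = track.times[-1].astype("datetime64[s]")
    minutes = np.arange(t0, t1, np.timedelta64(60, "s")).astype("datetime64[s]")
    lon, lat = track.position_at(minutes)
    elev = solar.solar_elevation(minutes, lon, lat)
    light = light_response(elev, cfg.light_elev0, cfg.light_elev_scale)
    if cfg.light_noise_sd > 0:
        light = light + rng.normal(0.0, cfg.light_noise_sd, size=light.size)
    shaded = _shading_mask(rng, light.size, cfg.shading_prob, cfg.shading_mean_minutes)
    light[shaded] = 0.0
    # burrow: sensor underground, light identically zero
    blocks = ((minutes - track.state_times[0]) / np.timedelta64(600, "s")).astype(int)
    blocks = np.clip(blocks, 0, track.states.size - 1)
    light[track.states[blocks] == "BURROW"] = 0.0
    light = np.clip(np.rint(light), 0, 64)
    return LightSeries(track.bird_id, minutes, light)


def simulate_immersion(track: TrueTrack, config: SimConfig | None = None) -> ImmersionSeries:
    """Per-10-min wet counts along a track (integers 0-200)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng([cfg.seed, 409, _bird_stream(track.bird_id)])
    p_by_state = {
        "WATER": cfg.p_wet_water,
        "FLIGHT": cfg.p_wet_flight,
        "BURROW": cfg.p_wet_burrow,
    }
    p = np.array([p_by_state[s] for s in track.states])
    counts = rng.binomial(200, p)
    return ImmersionSeries(track.bird_id, track.state_times.copy(), counts)


def _bird_stream(bird_id: str) -> int:
    """Stable small integer sub-stream id for a bird (process-independent)."""
    return zlib.crc32(bird_id.encode()) % (2**31)
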