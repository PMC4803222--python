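# glspipe

An end-to-end biologging pipeline for archival **GLS (global location
sensing) loggers** on seabirds: threshold light-level geolocation,
immersion-based at-sea activity budgets, kernel utilization-distribution
space use, environmental predictor rasters, presence–background
habitat-suitability models, and clustered permutation statistics — plus a
synthetic-data generator that gives every stage known ground truth.

It is aimed at movement ecologists working with BAS-style loggers that
record per-minute light (integer 0–64) and per-10-min salt-water immersion
counts (0–200), and at anyone who wants a fully testable, reproducible
version of the classic two-colony segregation analysis: do neighbouring
colonies separate in space, behaviour and habitat during the non-breeding
season?

## The methods in brief

**Threshold geolocation.** Twilights are threshold crossings (default 10)
of the light curve; each sunrise/sunset pair yields one fix. Longitude
comes from the time of local noon (midnight) relative to Greenwich
apparent noon, latitude from day (night) length via the sunrise equation

    cos H = (sin α − sin φ sin δ) / (cos φ cos δ),

with calibrated sun elevation α (CI −4.0°, SG −4.5°) and declination δ at
the fix time. Interrupted light curves are removed, fixes within a week of
the equinoxes discarded, and the track smoothed twice with a 3-point
moving average.

**Activity.** 10-min immersion blocks are split into daylight/darkness at
nautical twilight, burrow attendance is masked (prolonged dry-and-dark
runs; darkness during the day), water/flight bouts and foraging trips are
segmented, and day/night time-on-water budgets computed per phase
(breeding Dec–May, non-breeding Jun–Nov).

**Space use.** Kernel UDs with h = 1° on a 0.25° grid; 50% (core region)
and 95% (home range) isopleths; directional isopleth overlap within and
among colonies.

**Habitat models.** MaxEnt-style presence–background suitability via its
penalized-logistic equivalence (linear + quadratic features, L2 penalty):
bird-balanced bootstrap presences, collinearity screening (|r| > 0.7),
50 replicates with a 30% test split, logistic output in [0, 1], test AUC,
percent/permutation contributions and jackknife gains —
`MaxentModel(...).fit()` returns a `MaxentResults` with a `summary()`.

**Statistics.** Group differences are tested by permuting whole birds
(clusters) across groups, preserving repeated-measures structure.

## Worked example

Simulate 60 days of per-minute light along a known slow random walk at
40°N (sensor noise sd 2, 5% shading) and recover the track:

```python
import numpy as np
from glspipe.synth import SimConfig, simulate_drift_track, simulate_light
from glspipe import geoloc
from glspipe.envfields import great_circle_km

cfg = SimConfig(seed=1, light_noise_sd=2.0, shading_prob=0.05)
track = simulate_drift_track((-30.0, 40.0), "2012-05-01", 60, step_sd_deg=0.02, seed=1)
series = simulate_light(track, cfg)

est = geoloc.geolocate(series, colony="CI")
good = [f for f in est.fixes if f.valid]
tlon, tlat = track.position_at([f.time_utc for f in good])
err = great_circle_km([f.lon for f in good], [f.lat for f in good], tlon, tlat)
print(f"fixes: {len(est.fixes)}  valid: {len(good)}  retention: {est.retention:.2f}")
print(f"mean great-circle error: {err.mean():.1f} km (median {np.median(err):.1f} km)")
```

prints

```
fixes: 119  valid: 38  retention: 0.32
mean great-circle error: 16.6 km (median 15.0 km)
```

119 twilight pairs give twice-daily fixes; two-thirds are rejected by the
interrupted-curve screen under this deliberately harsh shading regime, and
the surviving smoothed fixes land ~17 km from the true positions — far
inside the ~180 km nominal accuracy of the method on real loggers.

A habitat model on simulated tracks works the same way:

```python
from glspipe.synth import make_environment, simulate_tracks
from glspipe.habitat import MaxentModel, balance_presences

env = make_environment(seed=5)
tracks = simulate_tracks(env, SimConfig(seed=2), start="2012-06-01", n_days=90)
pset = balance_presences(tracks, env, "CI", "NONBREEDING", n_per_bird=100, seed=2)
print(MaxentModel(pset).fit(n_replicates=50, seed=2).summary())
```

There is also a thin CLI (`glspipe simulate`, `glspipe geolocate`,
`glspipe activity`, `glspipe kernel`, `glspipe envfields`,
`glspipe compare`) over the same functions.

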