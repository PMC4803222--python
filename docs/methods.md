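# Methods

`glspipe` implements an end-to-end analysis pipeline for archival GLS
(global location sensing) loggers on small procellariiform seabirds, built
around two colonies in the Madeiran archipelago (Cima Islet, "CI", and
Selvagem Grande, "SG"). The pipeline has no access to real tracking data;
every stage is validated against a synthetic-data generator whose outputs
carry known ground truth. This note documents the models, the defaults and
why, the numerical choices, and what the synthetic validation does and does
not establish.

## Annual cycle

All analyses split the year into a breeding phase (1 December – 31 May) and
a non-breeding phase (1 June – 30 November). Feather isotope samples map
onto the phases through moult timing: the innermost primary (P1) grows at
the end of breeding, the eighth secondary (S8) at the end of non-breeding.

## Solar geometry

A shared NOAA/Meeus-style solar model (declination accurate to ~0.01°,
equation of time to a few seconds) underlies both the light simulator and
the geolocation estimator. Using one implementation on both sides makes
round-trip tests exact up to the method's own information loss; to keep
that symmetry from hiding model error, a deliberately degraded declination
variant (`solar_declination_crude`, cosine-of-day-of-year, no equation of
time, ~1° error) is provided and exercised in tests. No atmospheric
refraction term is included: with the threshold method, the calibrated sun
elevation angle absorbs refraction and sensor response wholesale.

## Light-level geolocation (threshold method)

The logger records per-minute light truncated to an integer 0–64. Twilights
are detected as crossings of a fixed threshold (default 10), located by
linear interpolation between flanking minutes after a 5-minute rolling
median prefilter. The prefilter suppresses single-minute sensor noise
chatter at the threshold while leaving ≥10-minute shading interruptions
(which must be detected and flagged) intact.

Each sunrise→sunset pair yields a noon fix and each sunset→sunrise pair a
midnight fix; both streams are merged chronologically:

* **Longitude** from the pair midpoint relative to Greenwich apparent
  noon/midnight (12:00 UTC corrected by the equation of time), at
  15° h⁻¹. Omitting the equation-of-time correction would bias longitude
  by up to ±4°.
* **Latitude** from day (night) length through the sunrise equation
  cos H = (sin α − sin φ sin δ)/(cos φ cos δ), with δ evaluated at the fix
  midpoint and α the calibrated sun elevation angle (CI −4.0°, SG −4.5°;
  a helper refits α from a known-position deployment by minimizing median
  position error). Writing sin α = a sin φ + b cos φ, the equation can
  admit two latitude roots; the root of smaller |φ| is taken (the second
  sits near a pole and never arises at the mid-latitudes simulated).
  Day lengths of 0 or ≥24 h, or |sin α| exceeding the envelope, give an
  `UNDEFINED_LAT` fix.

**Quality screening.** A pair is flagged `INTERRUPTED` (and its fix
`BAD_CURVE`) when (a) extra threshold crossings fall inside its span or
within 45 min outside its endpoints, or (b) an accepted crossing passes
through the threshold faster than 8 units min⁻¹. Rule (b) catches shading
events that swallow a twilight entirely: these shift the apparent crossing
without creating extra crossings, but the recovery from full shade to
above-threshold light is far steeper than any real twilight ramp
(~1.5 units min⁻¹ near the threshold under the default light response).
Without rule (b), rare swallowed twilights produce position errors of
thousands of km that dominate the mean. Both the ±45-min window and the
slope bound are our operationalization of removing "curves with apparent
interruptions around sunset and sunrise"; the reference desktop tools do
not document their exact heuristic.

Fixes within ±7 days of 20 March / 22 September are flagged `EQUINOX`
(day length carries no latitude information there; the window is
configurable). Retention is the valid/total fix ratio. Valid fixes are
then smoothed with two passes of a 3-point moving average (endpoints
average their two available fixes; longitudes averaged on the circle so
antimeridian tracks are safe) — the standard compensation for the
twilight-interval position lag.

Measured on the generator at the default study conditions (60 days,
May–August, slow mean-reverting walk at ~40°N, light noise sd 2, shading
occupancy 5% with mean 10-min events), the full chain delivers a mean
great-circle error of ~15–20 km over valid fixes, and ~5 km noise-free;
the nominal accuracy of the method on real loggers is c. 180 km, which is
the bound the acceptance script checks. Synthetic retention (~30%) is
well below what good field deployments achieve because the simulated
shading regime is deliberately harsh; the retention statistic itself is
just ratio arithmetic and is tested as such.

## At-sea activity

The immersion channel stores, per 10-min block, the number of wet 3-s
conductivity tests (0–200). Blocks are labelled DAYLIGHT/DARKNESS by
whether the sun at the block midpoint is above −12° (nautical dawn/dusk).
Burrow attendance is masked by two rules: runs of **more than** 4
consecutive blocks (>40 min) simultaneously dry (count 0) and dark
(light 0), and runs of ≥2 dark blocks during daylight (the 2-block minimum
avoids flagging single shading events). Water bouts are maximal runs with
any immersion (count ≥ 1, i.e. at least one 3-s wet test); flight bouts
are maximal all-dry runs; together with the burrow mask they partition the
record exactly. Foraging trips are maximal at-sea intervals between burrow
stints; open intervals at the record edges are excluded from means and
gaps shorter than 0.5 d count as colony attendance rather than trips.

Time-on-water proportions are computed from wet-count fractions
(Σcount / (200 × blocks), the logger's sub-block resolution) by default;
a block-counting variant is available (`weight="block"`). Per-phase
day/night budgets recover the generating occupancy × wetness product
within ±2 percentage points on 60-day simulations. Known limitation
(shared with the rule it implements): long nocturnal flight bouts are
occasionally mis-masked as burrow time, which slightly biases night
budgets and can fragment trip intervals.

## Environmental predictors

Eight layers on a 0.25° analysis grid (cells half-open, longitudes in
[−180, 180)): bathymetry as positive depth (BAT, m), SST (°C),
chlorophyll-a (CHL, mg m⁻³), wind speed (WSPD, m s⁻¹), great-circle
distance to each colony (DCOL, m; the colony is snapped to its cell centre
so the colony cell is exactly 0), and the gradients BATG, SSTG, CHLG.
The gradient is the relative range over a 3×3 window,
g = (max − min) × 100 / max — a front-detection statistic in [0, 100] for
non-negative fields, which is why depth is made positive before BATG.
Edge cells use the truncated neighbourhood (implemented via nearest-padded
min/max filters, which is provably identical); all-zero windows give 0;
all-missing windows stay missing. Finer sources are aggregated to the
analysis grid by missing-aware area-weighted block means; dynamic
variables are averaged into monthly composites. Gradients are computed
after regridding.

## Space use

The utilization distribution is a fixed-bandwidth bivariate Gaussian
kernel density (h = 1°, matching the mean accuracy of light-level
geolocation) evaluated on the 0.25° grid and normalized to integrate
to 1. The KDE is computed on the lon/lat plane in degrees with no
latitude correction — a documented limitation, acceptable at ~30–45°N
over ~10° extents, and consistent with expressing h in degrees. Isopleths
take cells in decreasing density order until the cumulative probability
reaches the level (ties broken by cell index for determinism): 50% = core
foraging region (FR), 95% = home range (HR); isopleths are nested in the
level. Overlap between two isopleths is the directional area proportion
area(A∩B)/area(A) × 100; group summaries average over ordered bird pairs
(mean ± SD) within and among colonies. A volume-intersection index
(∫min(UDa, UDb)) is available as an alternative. With the default
preference structure, among-colony 50% overlap in the non-breeding phase
falls an order of magnitude below within-colony overlap — the
segregation signature — and the dispersing colony (CI) shows the looser
within-colony overlap, as expected for birds spreading over a larger
pelagic region.

## Habitat suitability (presence–background)

The habitat model follows the maximum-entropy/penalized-logistic
equivalence: linear + quadratic features of predictors standardized
against the background sample, L2-penalized logistic regression of
presence cells against background cells, logistic output in [0, 1].
Protocol per colony × phase:

1. **Bird-balanced bootstrap**: an equal number of fixes per bird
   (default 100) drawn with replacement and snapped to grid cells;
   background is a uniform random sample of study-area cells (default
   10,000; reduced in desk-scale runs). Duplicate cells within the
   presence set are removed before fitting.
2. **Screening**: of any predictor pair with |Pearson r| > 0.7 on
   background cells, the one with lower single-variable training gain is
   dropped; optional candidate sets are then ranked by AIC of a single
   fit. If everything is collinear the single best variable is kept.
3. **Replicates**: 50 random 70/30 presence splits; each replicate is fit
   on the training presences vs background and scored by test AUC (test
   presences ranked against background). The inverse penalty C is chosen
   once by inner validation on a held-out quarter of the presences
   (grid 0.01–10). Replicates raising convergence failures are dropped;
   the model is invalid if >20% drop. Mean and coefficient-of-variation
   suitability surfaces aggregate the replicate predictions.
4. **Variable importance**: *percent contribution* decomposes training
   gain (mean log-likelihood improvement over the intercept-only model)
   along a greedy forward fit path, attributing each increment to the
   variable added, normalized to 100% and averaged over replicates (exact
   reference-implementation accounting is not reproducible from its
   published description; a path decomposition is the transparent
   surrogate). For runtime, the path is computed on a configurable subset
   of replicates (default 10) — AUC, surfaces and permutation
   contributions always use all replicates. *Permutation contribution* is
   the test-AUC drop when one variable's values are shuffled across
   evaluation cells, clipped at 0 and normalized to 100%. *Jackknife
   gains* report each variable's training gain alone and the gain of the
   model omitting it, on the full presence set.

AUC bands follow the usual convention (>0.9 excellent, 0.8–0.9 good,
0.7–0.8 acceptable, 0.6–0.7 bad, ≤0.6 invalid); degenerate all-equal
scores score 0.5. On tracks generated with preference weight only on SST,
SST attains the largest percent contribution and the largest isolated
jackknife gain with mean test AUC ≈ 0.9–0.97; uniform-presence null
controls give mean AUC within 0.5 ± 0.05. Habitat recovery runs discard
the first 15 days of simulated tracks as burn-in: the transient dispersal
from the colony otherwise injects a distance-to-colony signal that the
generating preference does not contain. No hinge/threshold/product
features and no extrapolation diagnostics are implemented.

## Group statistics

Colony and phase comparisons use clustered permutation tests: the
statistic is the difference of group means of bird-level means; the null
permutes whole birds across groups, never splitting a bird's repeated
measures — preserving exactly the dependence a mixed model's random
bird-identity term addresses, without distributional assumptions.
p = (1 + #{|T*| ≥ |T|})/(1 + n_perm), two-sided, default 9999
permutations, no multiplicity correction. Type-I error at α = 0.05 is
within [0.035, 0.065] over 1000 exchangeable-null replicates. Summary
tables report mean ± 1 SD per cell.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, chosen once:

* **Environment** (seeded, bit-reproducible): smooth Gaussian random
  fields on the study extent (40°W–8°W, 22°N–46°N by default) with a
  cool, productive coastal-upwelling band along the eastern boundary, a
  shallow seamount ridge near (31°W, 38.5°N), a latitudinal SST gradient
  with a seasonal cycle (warmest ~September), log-normal CHL (strictly
  positive), and wind increasing north- and westwards. CHL keeps enough
  independent structure that |r(SST, CHL)| stays well inside the 0.7
  collinearity screen.
* **Movement**: discrete-time correlated random walk on the lon/lat plane
  (hourly; great-circle stepping is unnecessary at ~10° extents). Headings
  are sampled from 24 candidates with log-weights
  κ·cos(turn) + S(destination), where S sums configured weights times
  per-month z-standardized predictor fields. Default weights encode the
  habitat associations the two populations are known for: both colonies
  cool/productive/shallow and
  near-colony while breeding; non-breeding SG stays on the upwelling near
  the colony while CI disperses to cold, low-CHL, windy, distant water
  with frontal-gradient and seamount affinity. Breeding birds home to the
  colony after the configured trip duration (CI 9.4 d, SG 4.8 d by
  default), overnight in the burrow, and depart at dawn, so every
  breeding bird attends the colony at least once per trip_duration + 1
  days.
* **Behaviour states** per 10-min block: BURROW only when both bracketing
  hourly positions are at the colony; otherwise WATER with a day/night,
  phase- and colony-specific occupancy (defaults back-calculated from
  field-typical time-on-water budgets divided by the wet probability), else
  FLIGHT.
* **Light**: 64/(1 + exp(−(elevation − e₀)/s)) with e₀ = −1.47°,
  s = 1.5°, chosen so the level crosses the threshold of 10 exactly at
  −4.0° sun elevation — consistent with the default calibration; plus
  Gaussian noise (sd 2), shading events (two-state Markov process with
  stationary shaded fraction 0.05 and geometric durations of mean 10 min
  — the noise/shading parameters are free simulator knobs, not estimates
  of a particular logger model), a hard zero in the burrow, and integer
  truncation to [0, 64].
* **Immersion**: Binomial(200, p) per block with p = 0.95 on water, 0 in
  flight and in the burrow.
* **Isotopes**: Gaussian draws per (colony, feather) cell; defaults encode
  CI nitrogen-enrichment in both feathers and CI carbon depletion in S8
  only, at sd 0.4–0.5‰ — the qualitative group pattern, with the same
  bird ids across feathers so repeated-measures structure is real.

One master seed fixes all randomness end-to-end (per-bird substreams are
derived with CRC-based keys, process-independent).

**What passing tests show — and don't.** The generator emulates solar
twilight structure, logger truncation and noise, shading, behaviour-driven
wet/dry sequences, colony attendance and habitat preference. It does not
emulate weather-driven light anomalies, sensor drift, biofouling of the
immersion electrodes, tag effects on behaviour, or real mesoscale
oceanography; recovery results bound what the pipeline can do when its
assumptions hold, not field accuracy.

## Problem sizes

Default experiment sizes (60–90 day simulations, 5–6 birds per colony,
50 model replicates, 1000 calibration replicates, 10⁴-cell grids) were
chosen as the smallest runs at which the measured quantities are stable
across seeds; all headline checks complete in well under a minute each.
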