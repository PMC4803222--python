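"""At-sea activity from salt-water immersion loggers.

The logger tests for immersion every 3 s and stores the number of wet
tests per 10-min block (0 = continuously dry ... 200 = continuously wet).
This module classifies blocks into daylight/darkness by nautical twilight,
masks burrow attendance (prolonged dry-and-dark runs, or darkness during
the day), segments water and flight bouts, splits the record into foraging
trips between burrow visits, and computes per-phase day/night time-on-water
budgets.

Proportion of time on water is computed from wet-count fractions
(count / 200) by default, which uses the logger's sub-block resolution; a
block-counting variant (share of blocks with any immersion) is available
via ``weight="block"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "ImmersionSeries",
    "Bout",
    "Budget",
    "assign_phase",
    "label_day_night",
    "detect_burrow",
    "segment_bouts",
    "segment_trips",
    "time_budget",
]

BLOCK_SECONDS = 600
TESTS_PER_BLOCK = 200
MIN_TRIP_DAYS = 0.5          # shorter gaps between burrow stints = attendance
BURROW_RUN_BLOCKS = 4        # "> 40 min" = strictly more than 4 blocks
DARK_DAY_RUN_BLOCKS = 2      # dark-during-day rule needs >= 2 blocks


@dataclass
class ImmersionSeries:
    """Per-10-min wet-count channel of one logger (integer 0-200)."""

    bird_id: str
    times: np.ndarray  # block start times, datetime64[s], contiguous
    counts: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.size != self.counts.size:
            raise ValueError("times and counts lengths differ")
        if self.counts.size and (self.counts.min() < 0 or self.counts.max() > TESTS_PER_BLOCK):
            raise ValueError("wet counts outside [0, 200]")

    def to_csv(self, path):
        pd.DataFrame({"block_start_utc": self.times, "wet_count": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, bird_id=None) -> "ImmersionSeries":
        df = pd.read_csv(path, parse_dates=["block_start_utc"])
        return cls(bird_id or str(path), df["block_start_utc"].values, df["wet_count"].values)


@dataclass
class Bout:
    start: np.datetime64
    end: np.datetime64
    kind: str  # WATER | FLIGHT

    @property
    def minutes(self) -> float:
        return (self.end - self.start) / np.timedelta64(60, "s")


@dataclass
class Budget:
    """Per-phase day/night time-on-water budget of one bird."""

    bird_id: str
    prop_day_on_water: dict = field(default_factory=dict)    # phase -> %
    prop_night_on_water: dict = field(default_factory=dict)  # phase -> %
    monthly: pd.DataFrame | None = None
    trip_days: list = field(default_factory=list)
    bouts: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phase, v in self.prop_day_on_water.items():
            rows.append((self.bird_id, phase, "prop_day_on_water", v))
        for phase, v in self.prop_night_on_water.items():
            rows.append((self.bird_id, phase, "prop_night_on_water", v))
        for d in self.trip_days:
            # trips are bounded by burrow visits, hence breeding-phase only
            rows.append((self.bird_id, "BREEDING", "trip_days", d))
        return pd.DataFrame(rows, columns=["bird", "phase", "metric", "value"])


def assign_phase(date) -> np.ndarray | str:
    """BREEDING for Dec 1 - May 31, NONBREEDING for Jun 1 - Nov 30."""
    d = np.asarray(date, dtype="datetime64[s]")
    months = d.astype("datetime64[M]").astype(int) % 12 + 1
    out = np.where((months >= 12) | (months <= 5), "BREEDING", "NONBREEDING")
    return out[()] if out.ndim == 0 else out


def label_day_night(series: ImmersionSeries, lon, lat) -> np.ndarray:
    """DAYLIGHT/DARKNESS label per block by nautical twilight.

    A block is DAYLIGHT iff the sun at the block midpoint (at the supplied
    position, which may be per-block arrays from estimated fixes) is above
    the nautical dawn/dusk boundary (-12 deg).
    """
    mid = series.times + np.timedelta64(BLOCK_SECONDS // 2, "s")
    elev = solar.solar_elevation(mid, lon, lat)
    return np.where(elev > -12.0, "DAYLIGHT", "DARKNESS")


def detect_burrow(series: ImmersionSeries, light_per_block, day_labels) -> np.ndarray:
    """Burrow mask: prolonged dry+dark runs, or darkness during daylight.

    ``light_per_block`` is the per-block maximum light level (0-64);
    a run of more than ``BURROW_RUN_BLOCKS`` consecutive blocks that are
    simultaneously dry (count 0) and dark (light 0) is burrow attendance,
    as is any run of >= ``DARK_DAY_RUN_BLOCKS`` dark blocks labelled
    DAYLIGHT (a bird underground at midday).
    """
    counts = series.counts
    light = np.asarray(light_per_block, dtype=float)
    day = np.asarray(day_labels) == "DAYLIGHT"
    mask = np.zeros(counts.size, dtype=bool)
    drydark = (counts == 0) & (light <= 0)
    for lo, hi in _runs(drydark):
        if hi - lo > BURROW_RUN_BLOCKS:
            mask[lo:hi] = True
    darkday = (light <= 0) & day
    for lo, hi in _runs(darkday):
        if hi - lo >= DARK_DAY_RUN_BLOCKS:
            mask[lo:hi] = True
    return mask


def _runs(flags: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def segment_bouts(series: ImmersionSeries, burrow_mask=None) -> list:
    """Partition the at-sea record into WATER and FLIGHT bouts.

    Maximal runs of blocks with any immersion (count >= 1, i.e. at least
    one 3-s wet test) are water bouts; maximal all-dry runs are flight
    bouts.  Burrow blocks break bouts and belong to neither.
    """
    if burrow_mask is None:
        burrow_mask = np.zeros(series.counts.size, dtype=bool)
    bouts = []
    at_sea = ~np.asarray(burrow_mask, dtype=bool)
    for lo, hi in _runs(at_sea):
        wet = series.counts[lo:hi] >= 1
        edges = np.flatnonzero(np.diff(wet.astype(int))) + 1
        bounds = np.concatenate([[0], edges, [hi - lo]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            kind = "WATER" if wet[a] else "FLIGHT"
            start = series.times[lo + a]
            end = series.times[lo + b - 1] + np.timedelta64(BLOCK_SECONDS, "s")
            bouts.append(Bout(start, end, kind))
    return bouts


def segment_trips(series: ImmersionSeries, burrow_mask) -> tuple[list, int]:
    """Foraging trips: maximal at-sea intervals between burrow stints.

    Returns ``(closed trip durations in days, n_open)``; intervals at the
    record edges (no bracketing burrow visit) are open and excluded, and
    gaps shorter than ``MIN_TRIP_DAYS`` count as colony attendance.
    """
    burrow = np.asarray(burrow_mask, dtype=bool)
    trips = []
    n_open = 0
    for lo, hi in _runs(~burrow):
        days = (hi - lo) * BLOCK_SECONDS / 86400.0
        closed = lo > 0 and hi < burrow.size
        if not closed:
            n_open += 1
            continue
        if days >= MIN_TRIP_DAYS:
            trips.append(days)
    return trips, n_open


def time_budget(
    series: ImmersionSeries,
    day_labels,
    burrow_mask=None,
    weight: str = "wet_fraction",
) -> pd.DataFrame:
    """Per-phase, per-month day/night proportion of time on water (%).

    ``weight="wet_fraction"`` (default) sums wet counts over non-burrow
    blocks and divides by 200 x the number of blocks; ``weight="block"``
    counts blocks with any immersion.  Cells with no non-burrow blocks are
    reported as missing (NaN).
    """
    if burrow_mask is None:
        burrow_mask = np.zeros(series.counts.size, dtype=bool)
    keep = ~np.asarray(burrow_mask, dtype=bool)
    phases = assign_phase(series.times)
    months = series.times.astype("datetime64[M]").astype(int) % 12 + 1
    df = pd.DataFrame(
        {
            "phase": phases[keep],
            "month": months[keep],
            "label": np.asarray(day_labels)[keep],
            "count": series.counts[keep],
        }
    )
    if weight == "wet_fraction":
        agg = df.groupby(["phase", "month", "label"])["count"].agg(["sum", "size"])
        agg["prop"] = agg["sum"] / (TESTS_PER_BLOCK * agg["size"]) * 100.0
    elif weight == "block":
        agg = df.assign(wet=df["count"] >= 1).groupby(["phase", "month", "label"])["wet"].agg(
            ["sum", "size"]
        )
        agg["prop"] = agg["sum"] / agg["size"] * 100.0
    else:
        raise ValueError("weight must be 'wet_fraction' or 'block'")
    out = agg["prop"].reset_index()
    out.insert(0, "bird", series.bird_id)
    return out


def phase_budget(budget_frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse a monthly budget table to per-phase day/night proportions.

    Block-weighted collapse is not possible from the percentages alone, so
    the per-month proportions are averaged (months carry near-equal block
    counts on contiguous records).
    """
    return (
        budget_frame.groupby(["bird", "phase", "label"])["prop"].mean().reset_index()
    )
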