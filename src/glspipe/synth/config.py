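"""Simulation configuration.

Defaults describe the study system the package targets: two small
shearwater colonies in the Madeiran archipelago (Cima Islet off Porto
Santo, and Selvagem Grande, ~340 km apart), birds tracked with BAS-type
loggers recording per-minute light (0-64) and per-10-min salt-water
immersion counts (0-200), over a north-east Atlantic study area spanning
the Canary Current upwelling and the open ocean towards the Mid-Atlantic
Ridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["SimConfig", "COLONIES"]

# colony positions (lon, lat), degrees
COLONIES = {
    "CI": (-16.33, 33.06),  # Cima Islet, Porto Santo
    "SG": (-15.87, 30.14),  # Selvagem Grande
}

# Day/night probabilities that a 10-min at-sea block is spent sitting on
# the water, per phase and colony.  Multiplied by p_wet_water these give
# field-typical proportions of day/night time on the water surface for
# small shearwaters (breeding ~20%/12-18%, non-breeding ~53-63%/59-80%).
_DEFAULT_WATER_OCCUPANCY = {
    ("CI", "BREEDING"): {"day": 0.205, "night": 0.123},
    ("SG", "BREEDING"): {"day": 0.225, "night": 0.188},
    ("CI", "NONBREEDING"): {"day": 0.558, "night": 0.623},
    ("SG", "NONBREEDING"): {"day": 0.661, "night": 0.841},
}

# Habitat-preference weights on standardized predictor scores.  Breeding
# birds of both colonies favour the cool productive upwelling near the
# colonies (negative SST, positive CHL, shallow water) close to the colony;
# non-breeding CI birds shift offshore to the seamount/frontal region while
# SG birds stay on the upwelling.
_DEFAULT_PREFERENCE = {
    ("CI", "BREEDING"): {"SST": -1.0, "CHL": 1.0, "BAT": -0.5, "DCOL": -2.5},
    ("SG", "BREEDING"): {"SST": -1.0, "CHL": 1.0, "BAT": -0.5, "DCOL": -2.5},
    ("CI", "NONBREEDING"): {
        "SST": -0.8, "CHL": -0.8, "WSPD": 1.2, "DCOL": 1.2,
        "SSTG": 0.5, "CHLG": 0.5, "BAT": -0.6,  # seamount-ridge affinity
    },
    ("SG", "NONBREEDING"): {"SST": -0.5, "CHL": 2.0, "DCOL": -1.5},
}

# Feather isotope group parameters (mean, sd in permil): P1 grows at the
# end of breeding, S8 at the end of non-breeding.  CI is nitrogen-enriched
# in both feathers; CI carbon is depleted (pelagic) in S8 only.
_DEFAULT_ISOTOPES = {
    ("CI", "P1"): {"d13C": (-17.5, 0.4), "d15N": (12.6, 0.5)},
    ("SG", "P1"): {"d13C": (-17.3, 0.4), "d15N": (11.6, 0.5)},
    ("CI", "S8"): {"d13C": (-18.6, 0.4), "d15N": (13.1, 0.5)},
    ("SG", "S8"): {"d13C": (-16.9, 0.4), "d15N": (11.9, 0.5)},
}


@dataclass
class SimConfig:
    """All simulator knobs; one seed fixes every random stream end-to-end."""

    seed: int = 0
    n_birds: dict = field(default_factory=lambda: {"CI": 10, "SG": 8})
    colonies: dict = field(default_factory=lambda: dict(COLONIES))
    extent: tuple = (-40.0, -8.0, 22.0, 46.0)  # lon0, lon1, lat0, lat1
    cell: float = 0.25

    # movement
    step_sd_deg: float = 0.35          # hourly step scale of the random walk
    turn_concentration: float = 1.0    # persistence of heading
    preference_weights: dict = field(default_factory=lambda: dict(_DEFAULT_PREFERENCE))
    trip_duration_days: dict = field(default_factory=lambda: {"CI": 9.4, "SG": 4.8})

    # light channel
    light_noise_sd: float = 2.0        # Gaussian noise on the 0-64 scale
    shading_prob: float = 0.05         # stationary P(any given minute is shaded)
    shading_mean_minutes: float = 10.0 # geometric event duration
    light_elev0: float = -1.47         # logistic midpoint elevation (deg)
    light_elev_scale: float = 1.5      # logistic width (deg)

    # immersion channel
    p_wet_water: float = 0.95          # P(3-s test wet | sitting on water)
    p_wet_flight: float = 0.0
    p_wet_burrow: float = 0.0
    water_occupancy: dict = field(default_factory=lambda: dict(_DEFAULT_WATER_OCCUPANCY))

    # isotopes
    isotope_params: dict = field(default_factory=lambda: dict(_DEFAULT_ISOTOPES))

    def __post_init__(self):
        for p in (self.shading_prob, self.p_wet_water, self.p_wet_flight, self.p_wet_burrow):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_stringify_keys(asdict(self)), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("preference_weights", "water_occupancy", "isotope_params"):
            if key in raw:
                raw[key] = {_split_key(k): v for k, v in raw[key].items()}
        if "extent" in raw:
            raw["extent"] = tuple(raw["extent"])
        if "colonies" in raw:
            raw["colonies"] = {k: tuple(v) for k, v in raw["colonies"].items()}
        if "isotope_params" in raw:
            raw["isotope_params"] = {
                k: {iso: tuple(ms) for iso, ms in v.items()} for k, v in raw["isotope_params"].items()
            }
        return cls(**raw)


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {
            ("|".join(k) if isinstance(k, tuple) else k): _stringify_keys(v)
            for k, v in obj.items()
        }
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, list):
        return [_stringify_keys(v) for v in obj]
    return obj


def _split_key(key):
    return tuple(key.split("|")) if "|" in key else key
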