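"""Feather stable-isotope simulation.

Feathers integrate diet over their growth window: the innermost primary
(P1) moults at the end of breeding (April-May) and the eighth secondary
(S8) at the end of the non-breeding period (October-November), so the two
feathers carry breeding- and non-breeding-season signatures respectively.
delta-13C tracks inshore (enriched) vs pelagic (depleted) foraging;
delta-15N tracks trophic level.  Samples are Gaussian draws around
per-(colony, feather) group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IsotopeSample", "simulate_isotopes", "isotopes_frame"]

FEATHERS = ("P1", "S8")


@dataclass
class IsotopeSample:
    bird_id: str
    colony: str
    feather: str  # P1 (breeding) | S8 (non-breeding)
    d13C: float   # permil
    d15N: float   # permil


def simulate_isotopes(group_params: dict, n_per_group: int, seed: int = 0) -> list:
    """Draw ``n_per_group`` birds per (colony, feather) cell.

    ``group_params`` maps ``(colony, feather)`` to
    ``{"d13C": (mean, sd), "d15N": (mean, sd)}``; negative sd is rejected.
    ``n_per_group = 0`` returns an empty list.
    """
    for key, isos in group_params.items():
        for iso, (mu, sd) in isos.items():
            if sd < 0:
                raise ValueError(f"negative sd for {key} {iso}")
    rng = np.random.default_rng(seed)
    samples = []
    for (colony, feather), isos in sorted(group_params.items()):
        c_mu, c_sd = isos["d13C"]
        n_mu, n_sd = isos["d15N"]
        for i in range(n_per_group):
            samples.append(
                IsotopeSample(
                    bird_id=f"{colony}{i:02d}",
                    colony=colony,
                    feather=feather,
                    d13C=float(rng.normal(c_mu, c_sd)),
                    d15N=float(rng.normal(n_mu, n_sd)),
                )
            )
    return samples


def isotopes_frame(samples) -> pd.DataFrame:
    """Tidy per-sample table (one row per bird x feather)."""
    return pd.DataFrame(
        {
            "bird": [s.bird_id for s in samples],
            "colony": [s.colony for s in samples],
            "feather": [s.feather for s in samples],
            "d13C": [s.d13C for s in samples],
            "d15N": [s.d15N for s in samples],
        }
    )
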