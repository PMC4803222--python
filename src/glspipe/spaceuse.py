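"""Kernel utilization distributions and spatial-segregation statistics.

The utilization distribution (UD) is a bivariate Gaussian kernel density of
a bird's position fixes evaluated on the 0.25-degree analysis grid with a
fixed smoothing parameter h = 1 degree — h matching the mean accuracy of
light-level geolocation.  The 50% isopleth (smallest cell set holding 50%
of the density) is the core foraging region (FR), the 95% isopleth the
home range (HR).  Segregation is quantified by directional isopleth-area
overlap percentages within and among groups.

The KDE is computed on the lon/lat plane in degrees with no latitude
correction (h is specified in degrees); a documented limitation acceptable
at the study's mid-latitude, ~10-degree extents.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .envfields import make_grid

__all__ = ["UDSurface", "Isopleth", "kernel_ud", "isopleth", "overlap_percent", "group_overlap"]


@dataclass
class UDSurface:
    """Normalized kernel density on the analysis grid."""

    density: xr.DataArray  # (lat, lon), integrates to 1 over the grid
    h: float               # bandwidth, degrees
    cell: float            # grid cell, degrees
    source: str = ""       # bird or group id
    phase: str = ""

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell  # degree^2, consistent with density units


@dataclass
class Isopleth:
    """Cell mask of the smallest set reaching a cumulative density level."""

    level: float
    mask: xr.DataArray  # bool (lat, lon)
    source: str = ""

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def kernel_ud(
    lon,
    lat,
    h: float = 1.0,
    cell: float = 0.25,
    extent=None,
    source: str = "",
    phase: str = "",
) -> UDSurface:
    """Gaussian kernel UD of fixes on a regular grid.

    Requires >= 5 fixes (pool birds or phases below that).  ``extent``
    defaults to the fix bounding box padded by 3h.  Density is normalized
    to integrate to 1 over the grid (cell area in square degrees).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 5:
        raise ValueError("kernel UD needs >= 5 fixes; pool individuals or phases")
    if extent is None:
        pad = 3.0 * h
        extent = (lon.min() - pad, lon.max() + pad, lat.min() - pad, lat.max() + pad)
    glon, glat = make_grid(extent, cell)
    dx = glon[None, :, None] - lon[None, None, :]
    dy = glat[:, None, None] - lat[None, None, :]
    dens = np.exp(-(dx * dx + dy * dy) / (2.0 * h * h)).sum(axis=2)
    dens /= dens.sum() * cell * cell
    da = xr.DataArray(dens, coords={"lat": glat, "lon": glon}, dims=("lat", "lon"))
    return UDSurface(da, h=h, cell=cell, source=source, phase=phase)


def isopleth(ud: UDSurface, level: float) -> Isopleth:
    """Smallest cell set whose cumulative probability reaches ``level``.

    Cells are accumulated in order of decreasing density; ties break by
    flat cell index for determinism.  Nested in ``level``.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("isopleth level must lie in (0, 1]")
    dens = np.asarray(ud.density).ravel()
    prob = dens * ud.cell_area
    order = np.lexsort((np.arange(dens.size), -dens))
    csum = np.cumsum(prob[order])
    # number of cells needed to reach the level (all nonzero cells at 1.0)
    k = int(np.searchsorted(csum, min(level, csum[-1]) - 1e-12) + 1)
    if level >= 1.0:
        k = int(np.sum(dens > 0))
    chosen = order[:k]
    mask = np.zeros(dens.size, dtype=bool)
    mask[chosen] = True
    mask = xr.DataArray(
        mask.reshape(ud.density.shape), coords=ud.density.coords, dims=ud.density.dims
    )
    return Isopleth(level, mask, ud.source)


def overlap_percent(a: Isopleth, b: Isopleth) -> float:
    """Directional overlap: area(a intersect b) / area(a) x 100.

    Both isopleths must live on the same grid.  Empty ``a`` is undefined
    (NaN).
    """
    if a.mask.shape != b.mask.shape:
        raise ValueError("isopleths are on different grids")
    na = int(a.mask.sum())
    if na == 0:
        return float("nan")
    inter = int((a.mask & b.mask).sum())
    return inter / na * 100.0


def volume_intersection(a: UDSurface, b: UDSurface) -> float:
    """VI index: integral of min(UD_a, UD_b), in [0, 1] (alternative index)."""
    if a.density.shape != b.density.shape:
        raise ValueError("UDs are on different grids")
    return float(np.minimum(a.density, b.density).sum() * a.cell_area)


def group_overlap(isopleths_by_bird: dict, groups: dict) -> pd.DataFrame:
    """Mean +/- SD directional overlap over ordered pairs, within/among groups.

    ``isopleths_by_bird`` maps bird id -> Isopleth (one level); ``groups``
    maps bird id -> group label.  Returns a tidy frame with rows per
    (group_a, group_b) combination; ``group_a == group_b`` rows are the
    within-group summaries.
    """
    rows = []
    labels = sorted(set(groups.values()))
    for ga, gb in itertools.product(labels, labels):
        vals = []
        for i, j in itertools.permutations(isopleths_by_bird, 2):
            if groups[i] == ga and groups[j] == gb and i != j:
                vals.append(overlap_percent(isopleths_by_bird[i], isopleths_by_bird[j]))
        if vals:
            rows.append((ga, gb, float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0, len(vals)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean", "sd", "n_pairs"])
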