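"""Synthetic north-east Atlantic environmental fields.

Generates the predictor stack a habitat analysis needs, with the broad
oceanographic structure of the study region built in: a cool, productive
coastal-upwelling band along the eastern (African shelf) boundary, a
shallow seamount ridge offshore to the north-west, a latitudinal SST
gradient with a seasonal cycle, and spatially smooth month-to-month noise.
Everything is deterministic under the seed.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

from .. import envfields
from .config import SimConfig

__all__ = ["make_environment"]

# offshore seamount ridge centre (lon, lat) and radius (deg)
SEAMOUNT = (-31.0, 38.5, 3.0)


def _smooth_noise(rng, shape, sigma_cells=6.0):
    """Unit-variance spatially smooth Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def make_environment(
    extent=None,
    cell: float = 0.25,
    months=range(1, 13),
    seed: int = 0,
    colonies=None,
) -> xr.Dataset:
    """Build the eight-variable raster stack on a regular lon/lat grid.

    Parameters
    ----------
    extent : (lon0, lon1, lat0, lat1), degrees; must cover the colonies.
    cell : grid cell size in degrees (<= 0.25).
    months : iterable of month numbers for the dynamic layers.
    seed : RNG seed; same seed and arguments give bit-identical grids.
    colonies : mapping name -> (lon, lat); defaults to the two study
        colonies (CI, SG).

    Returns an :class:`xarray.Dataset` with static ``BAT`` (positive depth,
    m), ``DCOL`` (m, per colony), dynamic ``SST`` (degC), ``CHL``
    (mg m-3, > 0), ``WSPD`` (m s-1) and the gradient layers ``BATG``,
    ``SSTG``, ``CHLG`` (relative range, 0-100).
    """
    cfg = SimConfig()
    if extent is None:
        extent = cfg.extent
    if colonies is None:
        colonies = cfg.colonies
    if cell > 0.25 + 1e-9:
        raise ValueError("cell size must be <= 0.25 degrees")
    months = list(months)
    lon, lat = envfields.make_grid(extent, cell)
    for name, (clon, clat) in colonies.items():
        if not (extent[0] <= clon <= extent[1] and extent[2] <= clat <= extent[3]):
            raise ValueError(f"extent does not cover colony {name} at ({clon}, {clat})")

    rng = np.random.default_rng(seed)
    LON, LAT = np.meshgrid(lon, lat)
    shape = LON.shape
    lon0, lon1, lat0, lat1 = map(float, extent)

    # eastern-boundary upwelling intensity: strongest within ~4 deg of the
    # eastern edge, tapering offshore
    upwell = np.exp(-((lon1 - LON) / 4.0) ** 2)
    # seamount ridge: shallow BAT patch offshore
    smx, smy, smr = SEAMOUNT
    seamount = np.exp(-((LON - smx) ** 2 + (LAT - smy) ** 2) / (2 * smr**2))

    # --- bathymetry: positive depth, m ------------------------------------
    shelf = np.exp(-((lon1 - LON) / 2.5) ** 2)  # shallow continental shelf
    bat = 4200.0 - 3900.0 * shelf - 3000.0 * seamount + 350.0 * _smooth_noise(rng, shape)
    bat = np.clip(bat, 30.0, None)

    # --- dynamic fields per month -----------------------------------------
    sst = np.empty((len(months),) + shape)
    chl = np.empty_like(sst)
    wspd = np.empty_like(sst)
    for k, m in enumerate(months):
        season = np.cos(2.0 * np.pi * (m - 9) / 12.0)  # warmest ~September
        sst_k = (
            24.0
            - 0.20 * (LAT - lat0)          # cooler northwards
            + 2.5 * season
            - 5.0 * upwell                 # upwelling cools the eastern band
            + 0.8 * _smooth_noise(rng, shape)
        )
        # CHL: log-normal around an upwelling-enhanced mean, independent
        # smooth structure keeps |r(SST, CHL)| away from the collinearity
        # screen's 0.7 cut
        log_chl = (
            np.log(0.15)
            + 2.2 * upwell
            + 0.012 * (LAT - lat0)
            + 0.55 * _smooth_noise(rng, shape)
            - 0.25 * season
        )
        chl_k = np.exp(log_chl)
        wspd_k = (
            7.5
            + 0.18 * (LAT - lat0)          # windier to the north
            + 2.5 * np.exp(-((LON - lon0) / 8.0) ** 2)  # and offshore to the west
            + 1.2 * _smooth_noise(rng, shape)
            - 1.0 * season
        )
        sst[k], chl[k], wspd[k] = sst_k, chl_k, np.clip(wspd_k, 0.5, None)

    coords = {"month": months, "lat": lat, "lon": lon}
    env = xr.Dataset(
        {
            "BAT": (("lat", "lon"), bat, {"units": "m", "long_name": "depth"}),
            "SST": (("month", "lat", "lon"), sst, {"units": "degC"}),
            "CHL": (("month", "lat", "lon"), chl, {"units": "mg m-3"}),
            "WSPD": (("month", "lat", "lon"), wspd, {"units": "m s-1"}),
        },
        coords=coords,
        attrs={"cell": cell, "extent": list(extent)},
    )
    env = envfields.add_gradients(env)
    dcol = xr.concat(
        [envfields.distance_to_colony(lon, lat, colonies[c]) for c in colonies],
        dim=xr.DataArray(list(colonies), dims="colony", name="colony"),
    )
    env["DCOL"] = dcol.assign_attrs(units="m")
    return env
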