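"""Environmental predictor rasters.

Builds the eight-layer predictor stack used for habitat modelling:
bathymetry (BAT, m, positive depth), sea-surface temperature (SST, degC),
chlorophyll-a (CHL, mg m-3), wind speed (WSPD, m s-1), distance to colony
(DCOL, m) and the moving-window gradients BATG, SSTG, CHLG.  Layers live in
:class:`xarray.Dataset` / :class:`xarray.DataArray` objects on a regular
lon/lat grid (cells half-open ``[lo, hi)``, 0-based indexing, longitudes in
``[-180, 180)``); dynamic layers carry a leading ``month`` dimension.

The gradient is a relative range over a 3x3 cell window,

    g = (max - min) * 100 / max,

a front-detection statistic: strong local variation in SST or CHL shows up
more clearly in SSTG/CHLG than in the raw field.  It is only meaningful for
non-negative fields (bathymetry is therefore expressed as positive depth
before taking BATG), and then lies in [0, 100].
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy import ndimage

__all__ = [
    "make_grid",
    "window_gradient",
    "regrid_to",
    "monthly_composite",
    "distance_to_colony",
    "great_circle_km",
    "add_gradients",
]

EARTH_RADIUS_M = 6_371_000.0

STATIC_VARS = ("BAT", "DCOL", "BATG")
DYNAMIC_VARS = ("SST", "CHL", "WSPD", "SSTG", "CHLG")


def make_grid(extent, cell):
    """Cell-centre coordinates for ``extent = (lon0, lon1, lat0, lat1)``.

    Cells are half-open ``[lo, lo + cell)`` so the grid tiles the extent
    without overlap; returns ``(lon, lat)`` 1-D centre arrays.
    """
    lon0, lon1, lat0, lat1 = map(float, extent)
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError(f"degenerate extent {extent!r}: zero or negative area")
    nlon = int(round((lon1 - lon0) / cell))
    nlat = int(round((lat1 - lat0) / cell))
    if nlon < 1 or nlat < 1:
        raise ValueError(f"extent {extent!r} smaller than one {cell} deg cell")
    lon = lon0 + cell * (np.arange(nlon) + 0.5)
    lat = lat0 + cell * (np.arange(nlat) + 0.5)
    return lon, lat


def window_gradient(layer: xr.DataArray) -> xr.DataArray:
    """Relative-range gradient over a 3x3 moving window.

    Per cell ``g = (max - min) * 100 / max`` over the 3x3 neighbourhood;
    edge cells use the truncated neighbourhood; windows whose max is 0
    give ``g = 0``; all-missing windows stay missing.  Negative values are
    rejected (convert depths to positive before calling).
    """
    data = np.asarray(layer, dtype=float)
    finite = np.isfinite(data)
    if finite.any() and data[finite].min() < 0:
        raise ValueError("window_gradient requires a non-negative field")

    def _grad2d(a):
        mask = np.isnan(a)
        # nearest padding maps every out-of-bounds window slot onto an
        # in-bounds neighbour, so min/max equal the truncated-window values
        hi = ndimage.maximum_filter(np.where(mask, -np.inf, a), size=3, mode="nearest")
        lo = ndimage.minimum_filter(np.where(mask, np.inf, a), size=3, mode="nearest")
        all_missing = ndimage.minimum_filter(mask.astype(np.uint8), size=3, mode="nearest") == 1
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(hi > 0, (hi - lo) * 100.0 / hi, 0.0)
        g[all_missing] = np.nan
        return g

    if data.ndim == 2:
        out = _grad2d(data)
    else:  # leading month dimension: window is spatial only
        out = np.stack([_grad2d(data[k]) for k in range(data.shape[0])])
    return xr.DataArray(out, coords=layer.coords, dims=layer.dims)


def _axis_weights(src: np.ndarray, dst: np.ndarray):
    """Overlap-length matrix between two 1-D cell-centre axes."""
    def edges(c):
        e = np.empty(c.size + 1)
        e[1:-1] = 0.5 * (c[1:] + c[:-1])
        e[0] = c[0] - (e[1] - c[0])
        e[-1] = c[-1] + (c[-1] - e[-2])
        return e

    se, de = edges(src), edges(dst)
    lo = np.maximum(se[:-1][:, None], de[:-1][None, :])
    hi = np.minimum(se[1:][:, None], de[1:][None, :])
    return np.clip(hi - lo, 0.0, None)  # (n_src, n_dst)


def regrid_to(layer: xr.DataArray, cell: float = 0.25, extent=None) -> xr.DataArray:
    """Aggregate a finer layer onto a ``cell``-degree grid by block mean.

    Missing-aware area-weighted averaging; exact block means when the
    source grid nests in the target, area-weighted resampling otherwise.
    """
    slon = np.asarray(layer["lon"], dtype=float)
    slat = np.asarray(layer["lat"], dtype=float)
    src_cell = float(np.median(np.diff(slon)))
    if src_cell > cell + 1e-9:
        raise ValueError("source grid is coarser than the target cell size")
    if extent is None:
        extent = (
            slon[0] - src_cell / 2,
            slon[-1] + src_cell / 2,
            slat[0] - src_cell / 2,
            slat[-1] + src_cell / 2,
        )
    dlon, dlat = make_grid(extent, cell)
    wlon = _axis_weights(slon, dlon)
    wlat = _axis_weights(slat, dlat)

    def _agg2d(a):
        good = np.isfinite(a)
        num = wlat.T @ np.where(good, a, 0.0) @ wlon
        den = wlat.T @ good.astype(float) @ wlon
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    data = np.asarray(layer, dtype=float)
    if data.ndim == 2:
        out = _agg2d(data)
        dims = ("lat", "lon")
        coords = {"lat": dlat, "lon": dlon}
    else:
        out = np.stack([_agg2d(data[k]) for k in range(data.shape[0])])
        lead = layer.dims[0]
        dims = (lead, "lat", "lon")
        coords = {lead: layer[lead].values, "lat": dlat, "lon": dlon}
    return xr.DataArray(out, coords=coords, dims=dims)


def monthly_composite(layer: xr.DataArray, time_dim: str = "time") -> xr.DataArray:
    """Per-cell monthly mean of a time-resolved layer (missing-aware)."""
    out = layer.groupby(layer[time_dim].dt.month).mean(time_dim, skipna=True)
    return out  # grouped dim is named "month"


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in kilometres (array-aware)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M / 1000.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def distance_to_colony(lon, lat, colony_lonlat) -> xr.DataArray:
    """Great-circle distance (metres) from each cell centre to the colony.

    The colony is snapped to its grid cell centre so the colony cell is
    exactly 0 m (the layer is a gridded product, not a point geometry).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    clon, clat = colony_lonlat
    if not (lon.min() - 0.5 <= clon <= lon.max() + 0.5 and lat.min() - 0.5 <= clat <= lat.max() + 0.5):
        raise ValueError(f"colony ({clon}, {clat}) outside grid extent")
    clon = lon[np.argmin(np.abs(lon - clon))]
    clat = lat[np.argmin(np.abs(lat - clat))]
    d = great_circle_km(lon[None, :], lat[:, None], clon, clat) * 1000.0
    return xr.DataArray(d, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))


def add_gradients(env: xr.Dataset) -> xr.Dataset:
    """Attach BATG, SSTG, CHLG to a predictor stack.

    BAT is interpreted as positive depth (m).  Fields already present are
    overwritten.
    """
    env = env.copy()
    env["BATG"] = window_gradient(env["BAT"])
    env["SSTG"] = window_gradient(env["SST"])
    env["CHLG"] = window_gradient(env["CHL"])
    return env
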