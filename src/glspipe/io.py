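"""File interchange: logger CSV dialects, NetCDF rasters, GeoJSON exports.

Light is ``timestamp_utc,light`` per minute and immersion
``block_start_utc,wet_count`` per 10 min (text analogues of the BAS .lig
and .act files).  Rasters go to CF-style NetCDF (classic NetCDF3 via the
scipy engine, with lon/lat coordinate variables).  Fixes export as CSV and
as one GeoJSON LineString per bird; isopleths as GeoJSON polygons.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import xarray as xr
from shapely import unary_union
from shapely.geometry import box, mapping

__all__ = [
    "write_raster",
    "read_raster",
    "fixes_to_csv",
    "fixes_to_geojson",
    "isopleth_to_geojson",
]


def write_raster(ds: xr.Dataset | xr.DataArray, path) -> None:
    """Write a raster stack as classic NetCDF with lon/lat coordinates."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "layer")
    ds = ds.copy()
    ds["lon"].attrs.setdefault("units", "degrees_east")
    ds["lat"].attrs.setdefault("units", "degrees_north")
    enc = {k: {"dtype": "float64"} for k in ds.data_vars}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_raster(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def fixes_to_csv(track, path) -> None:
    """`time_utc,lon,lat,valid,reason` rows for every fix of a track."""
    pd.DataFrame(
        {
            "time_utc": [f.time_utc for f in track.fixes],
            "lon": [f.lon for f in track.fixes],
            "lat": [f.lat for f in track.fixes],
            "valid": [f.valid for f in track.fixes],
            "reason": [f.reason for f in track.fixes],
        }
    ).to_csv(path, index=False)


def fixes_to_geojson(track, path=None) -> dict:
    """Valid fixes of one bird as a GeoJSON LineString feature."""
    coords = [[f.lon, f.lat] for f in track.fixes if f.valid]
    feature = {
        "type": "Feature",
        "properties": {"bird": track.bird_id, "colony": track.colony},
        "geometry": {"type": "LineString", "coordinates": coords},
    }
    obj = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh)
    return obj


def isopleth_to_geojson(iso, path=None) -> dict:
    """Isopleth cell mask as a (Multi)Polygon of merged cell boxes."""
    mask = iso.mask
    lon = np.asarray(mask["lon"], dtype=float)
    lat = np.asarray(mask["lat"], dtype=float)
    cell = float(lon[1] - lon[0]) if lon.size > 1 else 0.25
    ii, jj = np.nonzero(np.asarray(mask))
    boxes = [
        box(lon[j] - cell / 2, lat[i] - cell / 2, lon[j] + cell / 2, lat[i] + cell / 2)
        for i, j in zip(ii, jj)
    ]
    geom = unary_union(boxes) if boxes else None
    feature = {
        "type": "Feature",
        "properties": {"level": iso.level, "source": iso.source},
        "geometry": mapping(geom) if geom is not None else None,
    }
    obj = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh)
    return obj
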