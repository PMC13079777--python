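"""Readers and writers for the pipeline's on-disk formats.

Gridded fields travel as NetCDF (classic format via xarray's scipy engine)
or long CSV (time, x, y, variable, value); ward maps as GeoJSON
FeatureCollections with one feature per ward and a ``ward_id`` property
(plus a top-level ``grid`` member recording the raster geometry so the
cell membership can be rebuilt); tables as headed CSV; reports as JSON
with sorted keys so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape
from shapely.prepared import prep

from heatrisk.synthetic import GridSpec, WardMap


def write_meteo_netcdf(ds: xr.Dataset, path) -> None:
    out = ds.copy()
    for name, da in out.data_vars.items():
        if da.dtype == bool:  # classic NetCDF has no boolean type
            out[name] = da.astype("i1")
    out.to_netcdf(path, engine="scipy")


def read_meteo_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def dataset_to_long_csv(ds: xr.Dataset, path, variables=None) -> None:
    """Write grid variables as a long (time, x, y, variable, value) CSV."""
    variables = variables or [v for v in ds.data_vars if ds[v].dtype != bool]
    frames = []
    for var in variables:
        df = ds[var].to_dataframe(name="value").reset_index()
        df["variable"] = var
        frames.append(df[["time", "x", "y", "variable", "value"]])
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(path, index=False, float_format="%.10g")


def dataset_from_long_csv(path, attrs: dict | None = None) -> xr.Dataset:
    long = pd.read_csv(path, parse_dates=["time"])
    ds = xr.Dataset(
        {
            var: g.set_index(["time", "y", "x"])["value"].to_xarray()
            for var, g in long.groupby("variable")
        }
    )
    if attrs:
        ds.attrs.update(attrs)
    return ds


def wards_to_geojson(wards: WardMap, path, properties: pd.DataFrame | None = None) -> None:
    """One feature per ward; optional per-ward property columns joined on ward_id."""
    features = []
    polys = wards.polygons()
    for wid in wards.ward_ids:
        props = {"ward_id": wid}
        if properties is not None and wid in properties.index:
            props.update(
                {k: _jsonable(v) for k, v in properties.loc[wid].items()}
            )
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(polys[wid])}
        )
    doc = {
        "type": "FeatureCollection",
        "grid": {
            "nx": wards.grid.nx,
            "ny": wards.grid.ny,
            "cell_size": wards.grid.cell_size,
            "origin": list(wards.grid.origin),
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def wards_from_geojson(path) -> WardMap:
    """Rebuild the ward partition by locating cell centers in the polygons."""
    doc = json.loads(Path(path).read_text())
    g = doc["grid"]
    spec = GridSpec(
        nx=g["nx"], ny=g["ny"], cell_size=g["cell_size"], origin=tuple(g["origin"])
    )
    ward_ids = [f["properties"]["ward_id"] for f in doc["features"]]
    prepared = [prep(shape(f["geometry"])) for f in doc["features"]]
    labels = np.full((spec.ny, spec.nx), -1, dtype=int)
    from shapely.geometry import Point

    for r, yc in enumerate(spec.y_centers):
        for c, xc in enumerate(spec.x_centers):
            pt = Point(xc, yc)
            for k, geom in enumerate(prepared):
                if geom.covers(pt):
                    labels[r, c] = k
                    break
    if (labels < 0).any():
        raise ValueError("some grid cells fall outside every ward polygon")
    return WardMap(labels=labels, ward_ids=ward_ids, grid=spec)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, default=_jsonable))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
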