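"""Readers and writers for the pipeline's on-disk formats.

Climate and occupancy stacks go to NetCDF (via xarray), tabular data
(pollen archives, binned abundances, presence states, performance records) to
CSV, range polygons to GeoJSON, and configurations to YAML.  Every writer has
a reader that inverts it on the data model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .dispersal import OccupancyGrid
from .pollen import PresenceGrid
from .synthetic_world import COVARIATE_NAMES, ClimateSlice

__all__ = [
    "write_climate_netcdf", "read_climate_netcdf",
    "write_occupancy_netcdf", "read_occupancy_netcdf",
    "write_pollen_csv", "read_pollen_csv",
    "write_presence_csv", "read_presence_csv",
    "write_geojson_polygon", "read_geojson_polygon",
    "write_yaml", "read_yaml",
]


def write_climate_netcdf(slices: list[ClimateSlice], path) -> None:
    """Write a climate series as NetCDF: one variable per covariate plus the
    per-year seasonal summaries, with a time dimension in years BP."""
    times = [s.time_bp for s in slices]
    data = {
        name: (("time", "row", "col"),
               np.stack([s.covariates()[name] for s in slices]))
        for name in COVARIATE_NAMES
    }
    data["seasonal_tmean"] = (("time", "year", "season", "row", "col"),
                              np.stack([s.seasonal_tmean for s in slices]))
    data["seasonal_prec"] = (("time", "year", "season", "row", "col"),
                             np.stack([s.seasonal_prec for s in slices]))
    ds = xr.Dataset(data, coords={"time": times})
    ds.time.attrs["units"] = "model-years BP"
    ds.to_netcdf(path)


def read_climate_netcdf(path) -> list[ClimateSlice]:
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    out = []
    for t in ds.time.values:
        sel = ds.sel(time=t)
        out.append(ClimateSlice(
            time_bp=int(t),
            **{name: sel[name].values for name in COVARIATE_NAMES},
            seasonal_tmean=sel["seasonal_tmean"].values,
            seasonal_prec=sel["seasonal_prec"].values,
        ))
    return out


def write_occupancy_netcdf(series: list[OccupancyGrid], path) -> None:
    """Boolean occupancy stack as int8 NetCDF (NetCDF has no bool type)."""
    times = [s.time_bp if s.time_bp is not None else -i
             for i, s in enumerate(series)]
    ds = xr.Dataset(
        {"occupied": (("time", "row", "col"),
                      np.stack([s.occupied for s in series]).astype(np.int8))},
        coords={"time": times},
    )
    ds.to_netcdf(path)


def read_occupancy_netcdf(path) -> list[OccupancyGrid]:
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    return [OccupancyGrid(occupied=ds["occupied"].sel(time=t).values.astype(bool),
                          time_bp=int(t))
            for t in ds.time.values]


def write_pollen_csv(archive: pd.DataFrame, path) -> None:
    archive.to_csv(path, index=False)


def read_pollen_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"site_id", "sample_age_bp", "age_uncertainty_yr",
                "depositional_env", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pollen archive is missing columns {sorted(missing)}")
    return df


def write_presence_csv(grids: list[PresenceGrid], path) -> None:
    """Presence states as long-form CSV (cell_row, cell_col, bin, taxon, state)."""
    rows = []
    for g in grids:
        nr, nc = g.state.shape
        r, c = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        rows.append(pd.DataFrame({
            "cell_row": r.ravel(), "cell_col": c.ravel(),
            "bin_bp": g.bin_bp, "taxon": g.taxon, "state": g.state.ravel(),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_presence_csv(path) -> list[PresenceGrid]:
    df = pd.read_csv(path)
    out = []
    for (taxon, b), grp in df.groupby(["taxon", "bin_bp"], sort=True):
        nr = grp["cell_row"].max() + 1
        nc = grp["cell_col"].max() + 1
        state = np.full((nr, nc), -1, dtype=np.int8)
        state[grp["cell_row"], grp["cell_col"]] = grp["state"]
        out.append(PresenceGrid(state=state, taxon=taxon, bin_bp=int(b)))
    return out


def write_geojson_polygon(geom: BaseGeometry, path) -> None:
    Path(path).write_text(json.dumps({
        "type": "Feature", "properties": {}, "geometry": mapping(geom),
    }))


def read_geojson_polygon(path) -> BaseGeometry:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    geom = shape(obj["geometry"] if obj.get("type") == "Feature" else obj)
    if not geom.is_valid:
        raise ValueError(f"{path}: invalid geometry")
    return geom


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
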