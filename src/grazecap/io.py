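"""Disk formats: multi-page TIFF raster stacks with JSON sidecars, CSV
tables, YAML configs.

Raster layers are written as plain (non-georeferenced) float32 TIFFs, one
page per time step, with a ``<name>.json`` sidecar recording the time axis,
units and nodata convention so a stack round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from grazecap.grids import make_raster, make_series

HERD_COLUMNS = ["county_id", "year", "species", "count"]


def write_raster(da: xr.DataArray, path) -> Path:
    """Write a static or (time, y, x) raster layer as TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if np.issubdtype(da.dtype, np.floating):
        data = da.values.astype(np.float32)
    else:
        data = da.values.astype(np.int32)
    tifffile.imwrite(path, data)
    meta = {
        "name": da.name or path.stem,
        "units": da.attrs.get("units", ""),
        "dtype": str(data.dtype),
    }
    if "time" in da.dims:
        meta["time"] = [str(pd.Timestamp(t).date()) for t in da.time.values]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path) -> xr.DataArray:
    """Read a TIFF written by :func:`write_raster` (sidecar optional)."""
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    name = meta.get("name", path.stem)
    units = meta.get("units", "")
    if data.ndim == 3:
        time = pd.DatetimeIndex(meta["time"])
        return make_series(data, time, name, units)
    return make_raster(data, name, units)


def write_herds(herds: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    herds[HERD_COLUMNS].to_csv(path, index=False)
    return path


def read_herds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(HERD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"herd table missing columns {sorted(missing)}")
    return df


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
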