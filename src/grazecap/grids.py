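"""Shared raster conventions.

Every gridded layer in the pipeline is an :class:`xarray.DataArray` on one
common grid: static rasters have dims ``("y", "x")``, monthly stacks have
dims ``("time", "y", "x")`` with a month-start :class:`pandas.DatetimeIndex`
time axis. Nodata is NaN in float layers and a negative sentinel in integer
label layers (grassland types, county ids).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

#: Integer codes for the five grassland classes, ordered by typical
#: productivity (descending), plus 0 for non-grassland. Label rasters use
#: -1 for nodata.
GRASSLAND_CLASSES = {
    1: "meadow",
    2: "alpine_subalpine_meadow",
    3: "plain_grassland",
    4: "desert_grassland",
    5: "alpine_subalpine_grassland",
}

NON_GRASSLAND = 0
LABEL_NODATA = -1


class GridMismatchError(ValueError):
    """Raised when layers that must share a grid do not."""


def monthly_index(year_start: int, year_end: int) -> pd.DatetimeIndex:
    """Month-start time axis covering ``year_start``..``year_end`` inclusive."""
    if year_end < year_start:
        raise ValueError(f"empty year range {year_start}..{year_end}")
    return pd.date_range(f"{year_start}-01-01", f"{year_end}-12-01", freq="MS")


def make_raster(values: np.ndarray, name: str = "raster", units: str = "") -> xr.DataArray:
    """Wrap a 2-D array as a static raster layer."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"expected 2-D array, got shape {values.shape}")
    da = xr.DataArray(values, dims=("y", "x"), name=name)
    if units:
        da.attrs["units"] = units
    return da


def make_series(
    values: np.ndarray, time: pd.DatetimeIndex, name: str = "series", units: str = ""
) -> xr.DataArray:
    """Wrap a (time, y, x) array as a monthly raster series."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected 3-D array, got shape {values.shape}")
    if len(time) != values.shape[0]:
        raise ValueError(f"time axis length {len(time)} != leading dim {values.shape[0]}")
    da = xr.DataArray(values, dims=("time", "y", "x"), coords={"time": time}, name=name)
    if units:
        da.attrs["units"] = units
    return da


def check_aligned(*layers: xr.DataArray, time: bool = False) -> None:
    """Require identical (y, x) shape on every layer.

    With ``time=True``, layers carrying a time axis must also agree on its
    length (stacks that are combined elementwise). Raises
    :class:`GridMismatchError` otherwise.
    """
    if not layers:
        return
    ref = layers[0]
    ref_yx = (ref.sizes["y"], ref.sizes["x"])
    for layer in layers[1:]:
        yx = (layer.sizes["y"], layer.sizes["x"])
        if yx != ref_yx:
            raise GridMismatchError(f"grid mismatch: {yx} vs {ref_yx}")
        if time and "time" in ref.dims and "time" in layer.dims:
            if layer.sizes["time"] != ref.sizes["time"]:
                raise GridMismatchError(
                    f"time mismatch: {layer.sizes['time']} vs {ref.sizes['time']}"
                )


def valid_mask(layer: xr.DataArray) -> xr.DataArray:
    """Boolean mask of valid (non-nodata) pixels for float or label layers."""
    if np.issubdtype(layer.dtype, np.floating):
        if "time" in layer.dims:
            return layer.notnull().all("time")
        return layer.notnull()
    return layer >= 0
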