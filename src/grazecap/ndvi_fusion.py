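"""Cross-sensor NDVI calibration and series harmonization.

Long NDVI records are typically stitched from a coarse legacy sensor and a
modern sensor whose archives overlap for some years. Over the overlap window
the legacy value G at a pixel is modelled as a linear function of the modern
value V,

    G = a + b * V + error,

fitted per pixel by ordinary least squares pooled over all overlap months.
The harmonized record then keeps the modern sensor where it exists and maps
legacy months onto the modern scale through the pixel's own fit,
V_hat = (G - a) / b, clipped to the physical NDVI range [-0.2, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from grazecap.grids import check_aligned

NDVI_MIN = -0.2
NDVI_MAX = 1.0

# |slope| below this is treated as a degenerate fit: the legacy record
# carries no usable signal about the modern scale at that pixel.
_MIN_ABS_SLOPE = 1e-8


class DegenerateRegressorError(ValueError):
    """Regressor series is constant (zero variance) or has < 2 valid pairs."""


@dataclass(frozen=True)
class PixelRegression:
    """Per-pixel calibration fit: legacy = intercept + slope * modern."""

    intercept: float
    slope: float
    n_overlap: int
    residual_sd: float

    def predict_modern(self, legacy: np.ndarray) -> np.ndarray:
        """Map legacy-era values onto the modern sensor's scale."""
        return (np.asarray(legacy, dtype=float) - self.intercept) / self.slope


def fit_pixel_regression(g, v) -> PixelRegression:
    """OLS fit of paired overlap samples: g = a + b*v.

    Uses the textbook estimators b = sum((v-vbar)(g-gbar)) / sum((v-vbar)^2)
    and a = gbar - b*vbar on the pairs where both series are valid.

    Raises
    ------
    DegenerateRegressorError
        Fewer than 2 valid pairs, or v has zero variance.
    """
    g = np.asarray(g, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if g.shape != v.shape:
        raise ValueError(f"paired series length mismatch: {g.shape} vs {v.shape}")
    ok = np.isfinite(g) & np.isfinite(v)
    n = int(ok.sum())
    if n < 2:
        raise DegenerateRegressorError(f"need >= 2 valid pairs, got {n}")
    g, v = g[ok], v[ok]
    vbar = v.mean()
    gbar = g.mean()
    dv = v - vbar
    ssv = float(dv @ dv)
    if ssv == 0.0:
        raise DegenerateRegressorError("degenerate regressor: constant v")
    b = float(dv @ (g - gbar)) / ssv
    a = gbar - b * vbar
    resid = g - (a + b * v)
    # unbiased residual SD; 0 for a perfect 2-point fit
    residual_sd = float(np.sqrt(resid @ resid / (n - 2))) if n > 2 else 0.0
    return PixelRegression(intercept=a, slope=b, n_overlap=n, residual_sd=residual_sd)


def _overlap_times(long_series: xr.DataArray, modern_series: xr.DataArray, overlap=None):
    long_t = pd.DatetimeIndex(long_series.time.values)
    modern_t = pd.DatetimeIndex(modern_series.time.values)
    times = long_t.intersection(modern_t)
    if overlap is not None:
        start, end = overlap
        times = times[(times >= pd.Timestamp(start)) & (times <= pd.Timestamp(end))]
    if len(times) == 0:
        raise ValueError("empty overlap window between the two NDVI series")
    return times


def fit_regression_grid(
    long_series: xr.DataArray, modern_series: xr.DataArray, overlap=None
) -> xr.Dataset:
    """Fit the per-pixel calibration over the overlap window, vectorized.

    Parameters
    ----------
    long_series, modern_series
        Monthly NDVI stacks on a shared grid (legacy sensor is the response).
    overlap
        Optional ``(start, end)`` timestamps restricting the shared months.

    Returns
    -------
    xarray.Dataset
        ``intercept``, ``slope``, ``n_overlap``, ``residual_sd``, ``r2`` and a
        boolean ``valid`` layer. Pixels with a constant regressor or < 2
        valid pairs are flagged invalid (NaN coefficients).
    """
    check_aligned(long_series, modern_series)
    times = _overlap_times(long_series, modern_series, overlap)
    g = long_series.sel(time=times).values.astype(float)
    v = modern_series.sel(time=times).values.astype(float)

    ok = np.isfinite(g) & np.isfinite(v)
    n = ok.sum(axis=0)
    g = np.where(ok, g, 0.0)
    v = np.where(ok, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_n = np.where(n > 0, n, 1)
        vbar = v.sum(axis=0) / safe_n
        gbar = g.sum(axis=0) / safe_n
        dv = np.where(ok, v - vbar, 0.0)
        dg = np.where(ok, g - gbar, 0.0)
        ssv = (dv * dv).sum(axis=0)
        ssg = (dg * dg).sum(axis=0)
        spv = (dv * dg).sum(axis=0)
        slope = spv / ssv
        intercept = gbar - slope * vbar
        sse = ssg - slope * spv
        sse = np.clip(sse, 0.0, None)
        residual_sd = np.sqrt(sse / np.clip(n - 2, 1, None))
        r2 = np.where(ssg > 0, 1.0 - sse / ssg, np.nan)

    valid = (n >= 2) & (ssv > 0) & np.isfinite(slope) & (np.abs(slope) >= _MIN_ABS_SLOPE)
    slope = np.where(valid, slope, np.nan)
    intercept = np.where(valid, intercept, np.nan)
    residual_sd = np.where(valid, residual_sd, np.nan)
    r2 = np.where(valid, r2, np.nan)

    dims = ("y", "x")
    return xr.Dataset(
        {
            "intercept": (dims, intercept),
            "slope": (dims, slope),
            "n_overlap": (dims, n.astype(np.int32)),
            "residual_sd": (dims, residual_sd),
            "r2": (dims, r2),
            "valid": (dims, valid),
        },
        attrs={"n_overlap_months": len(times)},
    )


def harmonize_series(
    long_series: xr.DataArray,
    modern_series: xr.DataArray,
    overlap=None,
    fit: xr.Dataset | None = None,
) -> xr.DataArray:
    """Produce one continuous monthly NDVI series on the modern sensor's scale.

    Months covered by the modern sensor are taken from it verbatim; earlier
    months are the legacy values mapped through each pixel's calibration fit
    and clipped to [-0.2, 1]. Pixels flagged degenerate by the fit are nodata
    in the pre-modern era.
    """
    check_aligned(long_series, modern_series)
    if fit is None:
        fit = fit_regression_grid(long_series, modern_series, overlap)
    # pixels with overlap data that still failed to calibrate (constant or
    # near-zero-slope regressor); plain nodata pixels are not reported
    n_degenerate = int(((~fit["valid"].values) & (fit["n_overlap"].values >= 2)).sum())
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate calibration pixel(s) set to nodata")

    long_t = pd.DatetimeIndex(long_series.time.values)
    modern_t = pd.DatetimeIndex(modern_series.time.values)
    union = long_t.union(modern_t)

    a = fit["intercept"].values
    b = fit["slope"].values
    pre_t = long_t.difference(modern_t)
    out = xr.DataArray(
        np.full((len(union), long_series.sizes["y"], long_series.sizes["x"]), np.nan),
        dims=("time", "y", "x"),
        coords={"time": union},
        name="ndvi",
        attrs={"units": "", "scale": "modern-sensor equivalent"},
    )
    out.loc[{"time": modern_t}] = modern_series.values
    if len(pre_t):
        mapped = (long_series.sel(time=pre_t).values - a) / b
        out.loc[{"time": pre_t}] = np.clip(mapped, NDVI_MIN, NDVI_MAX)
    return out
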