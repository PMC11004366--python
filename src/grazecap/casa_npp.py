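"""CASA light-use-efficiency NPP model.

Monthly net primary productivity is the product of absorbed
photosynthetically active radiation and the realized light-use efficiency,

    NPP(x, t) = APAR(x, t) * eps(x, t)        [gC m-2 month-1]

with APAR = SOL * FPAR * 0.5 (half of incoming shortwave is
photosynthetically active) and

    eps = Teps1 * Teps2 * Weps * eps_max,

where eps_max (gC/MJ) is the biome maximum light-use efficiency, Teps1 and
Teps2 are the standard CASA temperature stress terms around the pixel's
optimum temperature (the mean temperature of its peak-NDVI month), and Weps
is a water-stress scalar driven by the ratio of actual to potential
evapotranspiration. No soil-moisture bucket is carried: the shipped closure
estimates E/Ep as precipitation over Thornthwaite potential
evapotranspiration, clipped to [0, 1], which is adequate for the arid and
semi-arid rangelands this pipeline targets and can be swapped via
``et_ratio``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from grazecap.grids import check_aligned

#: Fraction of incoming solar radiation that is photosynthetically active.
PAR_FRACTION = 0.5

#: Global fallback maximum light-use efficiency, gC/MJ (common grassland
#: class value in Chinese CASA applications).
DEFAULT_EPSILON_MAX = 0.542


@dataclass(frozen=True)
class CasaParams:
    """Tunable CASA parameters.

    epsilon_max maps grassland-type code -> gC/MJ; types missing from the
    map fall back to ``epsilon_max_default``. FPAR ramps linearly between
    the per-type NDVI percentiles ``ndvi_percentile_lo/hi`` and is clipped
    to [fpar_min, fpar_max].
    """

    epsilon_max: dict = field(default_factory=dict)
    epsilon_max_default: float = DEFAULT_EPSILON_MAX
    fpar_min: float = 0.001
    fpar_max: float = 0.95
    ndvi_percentile_lo: float = 5.0
    ndvi_percentile_hi: float = 95.0
    water_stress_floor: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.fpar_min < self.fpar_max <= 1.0):
            raise ValueError("require 0 <= fpar_min < fpar_max <= 1")
        if self.epsilon_max_default <= 0 or any(v <= 0 for v in self.epsilon_max.values()):
            raise ValueError("epsilon_max must be positive")
        if not (0.0 <= self.water_stress_floor < 1.0):
            raise ValueError("water_stress_floor must be in [0, 1)")

    def epsilon_max_for(self, type_code: int) -> float:
        return float(self.epsilon_max.get(int(type_code), self.epsilon_max_default))


def _per_type_ndvi_bounds(ndvi: xr.DataArray, types: xr.DataArray | None, params: CasaParams):
    """NDVI (min, max) maps from per-type history percentiles."""
    vals = ndvi.values
    lo = np.full(vals.shape[1:], np.nan)
    hi = np.full(vals.shape[1:], np.nan)
    if types is None:
        groups = [np.ones(vals.shape[1:], dtype=bool)]
    else:
        codes = types.values
        groups = [codes == c for c in np.unique(codes[codes > 0])]
    for sel in groups:
        if not sel.any():
            continue
        sample = vals[:, sel]
        sample = sample[np.isfinite(sample)]
        if sample.size == 0:
            continue
        lo[sel] = np.percentile(sample, params.ndvi_percentile_lo)
        hi[sel] = np.percentile(sample, params.ndvi_percentile_hi)
    return lo, hi


def compute_fpar(
    ndvi: xr.DataArray, params: CasaParams, types: xr.DataArray | None = None
) -> xr.DataArray:
    """Fraction of PAR absorbed by the canopy: linear ramp in NDVI.

    The ramp spans the per-grassland-type NDVI envelope (percentiles of the
    type's full monthly history) and is clipped to [fpar_min, fpar_max].
    """
    lo, hi = _per_type_ndvi_bounds(ndvi, types, params)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (ndvi.values - lo) / np.where(span > 0, span, np.nan)
    fpar = params.fpar_min + frac * (params.fpar_max - params.fpar_min)
    fpar = np.clip(fpar, params.fpar_min, params.fpar_max)
    fpar = np.where(np.isfinite(ndvi.values), fpar, np.nan)
    return xr.DataArray(fpar, dims=ndvi.dims, coords=ndvi.coords, name="fpar")


def compute_apar(
    ndvi: xr.DataArray,
    solar: xr.DataArray,
    params: CasaParams,
    types: xr.DataArray | None = None,
) -> xr.DataArray:
    """Absorbed PAR, MJ m-2 month-1: APAR = SOL * FPAR * 0.5."""
    check_aligned(ndvi, solar, time=True)
    if np.nanmin(solar.values) < 0:
        raise ValueError("negative solar radiation")
    fpar = compute_fpar(ndvi, params, types)
    apar = solar * fpar * PAR_FRACTION
    apar.name = "apar"
    apar.attrs["units"] = "MJ m-2 month-1"
    return apar


def _monthly_climatology(stack: xr.DataArray) -> np.ndarray:
    """(12, y, x) multi-year mean per calendar month; all-NaN pixels stay NaN."""
    months = pd.DatetimeIndex(stack.time.values).month
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.stack(
            [np.nanmean(stack.values[months == m], axis=0) for m in range(1, 13)]
        )


def _optimum_temperature(ndvi: xr.DataArray, temperature: xr.DataArray) -> np.ndarray:
    """Per-pixel Topt: multi-year mean temperature of the peak-NDVI month."""
    ndvi_clim = _monthly_climatology(ndvi)
    temp_clim = _monthly_climatology(temperature)
    all_nan = np.all(~np.isfinite(ndvi_clim), axis=0)
    peak = np.nanargmax(np.where(np.isfinite(ndvi_clim), ndvi_clim, -np.inf), axis=0)
    topt = np.take_along_axis(temp_clim, peak[None], axis=0)[0]
    return np.where(all_nan, np.nan, topt)


def thornthwaite_pet(temperature: xr.DataArray) -> xr.DataArray:
    """Monthly potential evapotranspiration (mm) by Thornthwaite's formula.

    The annual heat index is computed from the climatological mean monthly
    temperatures at each pixel; months at or below 0 degC evaporate nothing.
    Day-length correction is omitted (monthly 30-day basis), which is
    immaterial for the ratio-based water-stress scalar used here.
    """
    temp_clim = _monthly_climatology(temperature)
    heat = np.where(temp_clim > 0, (np.clip(temp_clim, 0, None) / 5.0) ** 1.514, 0.0)
    index = heat.sum(axis=0)
    a = 6.75e-7 * index**3 - 7.71e-5 * index**2 + 1.792e-2 * index + 0.49239
    t = np.clip(temperature.values, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        pet = np.where(
            (t > 0) & (index > 0), 16.0 * (10.0 * t / np.where(index > 0, index, np.nan)) ** a, 0.0
        )
    out = xr.DataArray(pet, dims=temperature.dims, coords=temperature.coords, name="pet")
    out.attrs["units"] = "mm month-1"
    return out


def precipitation_et_ratio(
    temperature: xr.DataArray, precipitation: xr.DataArray, solar: xr.DataArray
) -> xr.DataArray:
    """Default E/Ep closure: precipitation over Thornthwaite PET, in [0, 1]."""
    pet = thornthwaite_pet(temperature)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(pet.values > 0, precipitation.values / pet.values, 0.0)
    ratio = np.clip(ratio, 0.0, 1.0)
    ratio = np.where(
        np.isfinite(precipitation.values) & np.isfinite(temperature.values), ratio, np.nan
    )
    return xr.DataArray(ratio, dims=temperature.dims, coords=temperature.coords, name="et_ratio")


def compute_epsilon(
    temperature: xr.DataArray,
    precipitation: xr.DataArray,
    solar: xr.DataArray,
    params: CasaParams,
    ndvi: xr.DataArray,
    types: xr.DataArray | None = None,
    et_ratio=None,
    return_factors: bool = False,
):
    """Realized light-use efficiency, gC/MJ.

    eps = Teps1 * Teps2 * Weps * eps_max with

    * Teps1 = 0.8 + 0.02*Topt - 0.0005*Topt^2  (clipped at 0),
    * Teps2 = 1.1814 / [(1 + e^{0.2(Topt-10-T)}) (1 + e^{0.3(-Topt-10+T)})],
    * Weps  = floor + (1 - floor) * E/Ep.

    Topt is the pixel's mean temperature in its peak-NDVI month. ``et_ratio``
    may be a precomputed DataArray or a callable ``f(temperature,
    precipitation, solar)``; the default is the precipitation/PET closure.
    """
    check_aligned(temperature, precipitation, solar, ndvi, time=True)
    topt = _optimum_temperature(ndvi, temperature)
    te1 = np.clip(0.8 + 0.02 * topt - 0.0005 * topt**2, 0.0, None)

    t = temperature.values
    with np.errstate(over="ignore", invalid="ignore"):
        te2 = 1.1814 / (
            (1.0 + np.exp(0.2 * (topt - 10.0 - t))) * (1.0 + np.exp(0.3 * (-topt - 10.0 + t)))
        )

    if et_ratio is None:
        ratio = precipitation_et_ratio(temperature, precipitation, solar)
    elif callable(et_ratio):
        ratio = et_ratio(temperature, precipitation, solar)
    else:
        ratio = et_ratio
    floor = params.water_stress_floor
    we = floor + (1.0 - floor) * np.clip(ratio.values, 0.0, 1.0)

    if types is None:
        emax = np.full(t.shape[1:], params.epsilon_max_default)
    else:
        codes = types.values
        emax = np.full(codes.shape, np.nan)
        for c in np.unique(codes[codes > 0]):
            emax[codes == c] = params.epsilon_max_for(c)

    eps = np.clip(te1 * te2 * we * emax, 0.0, emax)
    eps = np.where(np.isfinite(t), eps, np.nan)
    epsilon = xr.DataArray(
        eps, dims=temperature.dims, coords=temperature.coords, name="epsilon"
    )
    epsilon.attrs["units"] = "gC/MJ"
    if not return_factors:
        return epsilon
    dims2 = ("y", "x")
    factors = xr.Dataset(
        {
            "topt": (dims2, topt),
            "te1": (dims2, te1),
            "te2": (temperature.dims, te2),
            "we": (temperature.dims, we),
        },
        coords=temperature.coords,
    )
    return epsilon, factors


def compute_npp(apar: xr.DataArray, epsilon: xr.DataArray) -> xr.DataArray:
    """NPP = APAR * eps, gC m-2 month-1, non-negative where valid."""
    check_aligned(apar, epsilon, time=True)
    npp = np.clip(apar.values * epsilon.values, 0.0, None)
    out = xr.DataArray(npp, dims=apar.dims, coords=apar.coords, name="npp")
    out.attrs["units"] = "gC m-2 month-1"
    return out
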