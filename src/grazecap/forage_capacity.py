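"""From NPP to forage yield and theoretical livestock carrying capacity.

The aboveground share of monthly NPP follows a linear function of monthly
mean temperature,

    fANPP = 0.171 + 0.0129 * MAT        (clamped to [0, 1]),

and dry-forage yield converts the carbon flux back to dry matter with the
0.47 gC per g carbon content:

    F = NPP * fANPP / 0.47              [g m-2],  1 g m-2 = 10 kg hm-2.

The theoretical carrying capacity of a pixel is then the stocking rate the
standing forage can sustain,

    CC = AGB * G_i / (L * D)            [SU hm-2],

with AGB in kg/hm2, G_i the utilization rate of grassland type i, L the
standard daily intake per sheep unit (1.8 kg/d) and D the grazing days of
the accounting window.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from grazecap.grids import GRASSLAND_CLASSES, check_aligned

G_M2_TO_KG_HM2 = 10.0

#: Calendar months per named season. Winter pools December with the January
#: and February of the same calendar year (within-year accounting).
SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
    "growing_season": (4, 5, 6, 7, 8, 9, 10),
}

#: Grazing days per accounting window. Seasonal windows (including the
#: growing season) share a common 92-day normalization so their stocking
#: rates are comparable; see the methods note.
DEFAULT_SEASON_DAYS = 92.0
DEFAULT_YEAR_DAYS = 365.0


@dataclass(frozen=True)
class PartitionModel:
    """Linear aboveground-partition model and carbon-content coefficient."""

    intercept: float = 0.171
    mat_coeff: float = 0.0129
    carbon_coeff: float = 0.47


@dataclass(frozen=True)
class CapacityParams:
    """Utilization rates per grassland type, intake, and window day counts.

    ``utilization`` has no silent default: the mapping type-code -> G_i must
    cover every grassland type present in the scene.
    """

    utilization: dict
    intake: float = 1.8
    season_days: float = DEFAULT_SEASON_DAYS
    year_days: float = DEFAULT_YEAR_DAYS

    def __post_init__(self):
        if self.intake <= 0:
            raise ValueError("intake L must be positive")
        for code, gi in self.utilization.items():
            if not (0 < gi <= 1):
                raise ValueError(f"utilization rate for type {code} must be in (0, 1]")


def default_utilization() -> dict:
    """A plausible utilization-rate table for the five grassland classes.

    Values reflect common Chinese rangeland practice (higher for meadows,
    lower for desert and alpine grassland); they are explicit configuration,
    not hidden model constants.
    """
    return {1: 0.60, 2: 0.55, 3: 0.50, 4: 0.40, 5: 0.45}


def partition_fraction(mat, model: PartitionModel = PartitionModel()):
    """Aboveground fraction of NPP at monthly mean temperature ``mat`` (degC).

    Clamped to [0, 1]: the linear form goes negative in cold winters, and
    negative biomass is unphysical.
    """
    return np.clip(model.intercept + model.mat_coeff * np.asarray(mat, dtype=float), 0.0, 1.0)


def npp_to_yield(
    npp: xr.DataArray, mat: xr.DataArray, model: PartitionModel = PartitionModel()
) -> xr.DataArray:
    """Dry-forage yield in g/m2: F = NPP * fANPP(MAT) / 0.47.

    The kg/hm2 view is exactly 10x this layer (`G_M2_TO_KG_HM2`).
    """
    check_aligned(npp, mat, time=True)
    fanpp = partition_fraction(mat.values, model)
    out = xr.DataArray(
        npp.values * fanpp / model.carbon_coeff, dims=npp.dims, coords=npp.coords, name="yield"
    )
    out.attrs["units"] = "g m-2"
    return out


@dataclass
class CapacityGrid:
    """Yield and carrying capacity for one accounting window."""

    window: str
    days: float
    agb_g_m2: xr.DataArray
    cc: xr.DataArray  # SU hm-2

    @property
    def agb_kg_hm2(self) -> xr.DataArray:
        view = self.agb_g_m2 * G_M2_TO_KG_HM2
        view.attrs["units"] = "kg hm-2"
        return view

    def type_summary(self, types: xr.DataArray, pixel_area_hm2: float = 100.0) -> pd.DataFrame:
        """Per-grassland-type means and totals (yield also as t/km2 = g/m2)."""
        codes = types.values
        rows = []
        for code, name in GRASSLAND_CLASSES.items():
            sel = (codes == code) & np.isfinite(self.cc.values)
            if not sel.any():
                continue
            agb = self.agb_g_m2.values[sel]
            cc = self.cc.values[sel]
            rows.append(
                {
                    "type_code": code,
                    "type": name,
                    "n_pixels": int(sel.sum()),
                    "mean_yield_t_km2": float(np.mean(agb)),
                    "mean_cc_su_hm2": float(np.mean(cc)),
                    "total_yield_t": float(np.sum(agb) * pixel_area_hm2 / 100.0),
                    "total_capacity_su": float(np.sum(cc) * pixel_area_hm2),
                }
            )
        return pd.DataFrame(rows)


def yield_to_capacity(
    agb_kg_hm2: xr.DataArray,
    types: xr.DataArray,
    params: CapacityParams,
    days: float,
    window: str = "window",
) -> CapacityGrid:
    """Theoretical carrying capacity CC = AGB * G_i / (L * D), SU/hm2.

    Non-grassland pixels are nodata. A grassland type present in ``types``
    but absent from the utilization table is an error.
    """
    check_aligned(agb_kg_hm2, types)
    if days < 1:
        raise ValueError("grazing days D must be >= 1")
    codes = types.values
    observed = np.unique(codes[codes > 0])
    missing = [int(c) for c in observed if int(c) not in params.utilization]
    if missing:
        raise KeyError(f"no utilization rate for grassland type(s) {missing}")
    gi = np.full(codes.shape, np.nan)
    for c in observed:
        gi[codes == c] = params.utilization[int(c)]
    cc = agb_kg_hm2.values * gi / (params.intake * days)
    cc = np.where(codes > 0, cc, np.nan)
    cc_da = xr.DataArray(cc, dims=agb_kg_hm2.dims, coords=agb_kg_hm2.coords, name="cc")
    cc_da.attrs["units"] = "SU hm-2"
    agb = xr.DataArray(
        np.where(codes > 0, agb_kg_hm2.values / G_M2_TO_KG_HM2, np.nan),
        dims=agb_kg_hm2.dims,
        coords=agb_kg_hm2.coords,
        name="agb",
    )
    agb.attrs["units"] = "g m-2"
    return CapacityGrid(window=window, days=float(days), agb_g_m2=agb, cc=cc_da)


def _window_days(scheme: str, window_key, params: CapacityParams) -> float:
    if scheme == "month":
        ts = pd.Timestamp(window_key)
        return float(calendar.monthrange(ts.year, ts.month)[1])
    if scheme == "year":
        return params.year_days
    return params.season_days


def aggregate_windows(
    monthly_yield: xr.DataArray,
    types: xr.DataArray,
    params: CapacityParams,
    scheme: str = "year",
) -> list[CapacityGrid]:
    """Aggregate monthly yield into windows and recompute capacity.

    ``scheme`` is one of ``month``, ``season`` (the four seasons plus the
    April-October growing season, per calendar year), or ``year``. Window
    yield is the sum of its monthly yields; capacity uses the
    window-appropriate grazing days D (days-in-month, the common seasonal
    day count, or the full year).
    """
    times = pd.DatetimeIndex(monthly_yield.time.values)
    windows: list[tuple[str, np.ndarray]] = []
    if scheme == "month":
        for t in times:
            windows.append((t.strftime("%Y-%m"), times == t))
    elif scheme == "year":
        for year in sorted(set(times.year)):
            sel = times.year == year
            if sel.sum() < 12:
                raise ValueError(f"incomplete year {year}: {int(sel.sum())} months")
            windows.append((str(year), sel))
    elif scheme == "season":
        for year in sorted(set(times.year)):
            for season, months in SEASON_MONTHS.items():
                sel = (times.year == year) & np.isin(times.month, months)
                if sel.sum() < len(months):
                    raise ValueError(f"incomplete window {season} {year}")
                windows.append((f"{year}-{season}", sel))
    else:
        raise ValueError(f"unknown aggregation scheme {scheme!r}")

    out = []
    for label, sel in windows:
        agb_g = monthly_yield.values[sel].sum(axis=0)
        agb_kg = xr.DataArray(
            agb_g * G_M2_TO_KG_HM2,
            dims=("y", "x"),
            coords={k: v for k, v in monthly_yield.coords.items() if k in ("y", "x")},
        )
        days = _window_days(scheme, label if scheme == "month" else label, params)
        out.append(yield_to_capacity(agb_kg, types, params, days=days, window=label))
    return out
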