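"""County-level grass-livestock balance accounting.

Year-end livestock inventories are converted to standard sheep units (SU),
summed per county-year, and compared with the county's theoretical carrying
capacity CA (zonal sum of the capacity raster over its grassland pixels).
The balance index

    Ip = (A - CA) / CA * 100%

is graded I-IV: I not overloaded (Ip <= 0), II slight overload
(0 < Ip <= 25), III moderate overload (25 < Ip <= 50), IV severe overload
(Ip > 50). Ip = 0 means the load exactly meets capacity and is assigned to
grade I (capacity is not exceeded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from grazecap.grids import check_aligned

#: Sheep units per head by species.
DEFAULT_SHEEP_UNITS = {
    "cattle": 5.0,
    "horse": 5.0,
    "mule": 5.0,
    "donkey": 2.5,
    "camel": 8.0,
    "sheep": 1.2,
    "goat": 0.8,
}

GRADE_LABELS = {
    "I": "not overloaded",
    "II": "slight overload",
    "III": "moderate overload",
    "IV": "severe overload",
}


def grade_of(ip: float) -> str:
    """Grade code for a finite balance index (percent)."""
    if not np.isfinite(ip):
        raise ValueError("balance index must be finite")
    if ip <= 0:
        return "I"
    if ip <= 25:
        return "II"
    if ip <= 50:
        return "III"
    return "IV"


def balance_index(actual_su: float, theoretical_su: float):
    """Balance index Ip (percent) and grade for one county-year.

    Returns ``(nan, None)`` with a warning when the theoretical capacity is
    not positive (undefined index).
    """
    if theoretical_su <= 0:
        warnings.warn("theoretical capacity <= 0: balance index undefined")
        return float("nan"), None
    ip = (actual_su - theoretical_su) / theoretical_su * 100.0
    return float(ip), grade_of(ip)


def herd_to_sheep_units(
    herds: pd.DataFrame, table: dict | None = None
) -> pd.DataFrame:
    """Sum herd inventories to sheep units per county-year.

    ``herds`` has columns county_id, year, species, count. Unknown species
    or negative counts are errors.
    """
    table = dict(DEFAULT_SHEEP_UNITS if table is None else table)
    if any(f <= 0 for f in table.values()):
        raise ValueError("sheep-unit factors must be positive")
    unknown = set(herds["species"]) - set(table)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    if (herds["count"] < 0).any():
        raise ValueError("negative livestock count")
    su = herds["count"] * herds["species"].map(table)
    out = (
        herds.assign(su=su)
        .groupby(["county_id", "year"], as_index=False)["su"]
        .sum()
        .rename(columns={"su": "actual_su"})
    )
    return out


def zonal_theoretical_capacity(
    cc: xr.DataArray, counties: xr.DataArray, pixel_area_hm2: float = 100.0
) -> pd.DataFrame:
    """Theoretical capacity per county: sum of CC * pixel area over grassland.

    ``cc`` is an annual capacity raster (SU/hm2, nodata outside grassland);
    ``counties`` a county-id label raster (negative = nodata). Counties with
    no grassland pixel get CA = 0 and a flag.
    """
    check_aligned(cc, counties)
    labels = counties.values
    vals = cc.values
    rows = []
    for cid in np.unique(labels[labels >= 0]):
        sel = labels == cid
        valid = sel & np.isfinite(vals)
        ca = float(np.sum(vals[valid]) * pixel_area_hm2)
        n = int(valid.sum())
        if n == 0:
            warnings.warn(f"county {int(cid)} has no grassland pixels")
        rows.append(
            {
                "county_id": int(cid),
                "theoretical_su": ca,
                "n_grassland_pixels": n,
                "flag": "no_grassland" if n == 0 else "",
            }
        )
    return pd.DataFrame(rows)


def compute_balance(
    actual: pd.DataFrame, theoretical: pd.DataFrame
) -> pd.DataFrame:
    """Join actual SU loads with theoretical capacity and grade each record.

    ``actual`` is the output of :func:`herd_to_sheep_units`; ``theoretical``
    has county_id, theoretical_su and optionally year (a static table is
    broadcast over years). Counties with zero herds in a year but a defined
    capacity get A = 0 (index -100%).
    """
    if "year" in theoretical.columns:
        merged = theoretical.merge(actual, on=["county_id", "year"], how="left")
    else:
        years = sorted(actual["year"].unique())
        merged = (
            theoretical.assign(key=1)
            .merge(pd.DataFrame({"year": years, "key": 1}), on="key")
            .drop(columns="key")
            .merge(actual, on=["county_id", "year"], how="left")
        )
    merged["actual_su"] = merged["actual_su"].fillna(0.0)
    records = []
    for row in merged.itertuples(index=False):
        ip, grade = balance_index(row.actual_su, row.theoretical_su)
        records.append(
            {
                "county_id": row.county_id,
                "year": row.year,
                "actual_su": row.actual_su,
                "theoretical_su": row.theoretical_su,
                "balance_index_pct": ip,
                "grade": grade,
            }
        )
    return pd.DataFrame(records)


def summarize_region(records: pd.DataFrame) -> pd.DataFrame:
    """Interannual regional summary of balance records.

    Per year: capacity-weighted regional index (sum A - sum CA over sum CA),
    the unweighted county mean, county counts per grade, and the overloaded
    count (grades II-IV). The returned frame carries the linear trend of the
    weighted index over years in ``attrs['ip_trend_pct_per_year']``.
    """
    if records.empty:
        raise ValueError("no balance records")
    rows = []
    for year, grp in records.groupby("year"):
        defined = grp[np.isfinite(grp["balance_index_pct"])]
        tot_ca = defined["theoretical_su"].sum()
        tot_a = defined["actual_su"].sum()
        weighted = (tot_a - tot_ca) / tot_ca * 100.0 if tot_ca > 0 else float("nan")
        counts = defined["grade"].value_counts()
        rows.append(
            {
                "year": year,
                "mean_ip_weighted_pct": weighted,
                "mean_ip_county_pct": float(defined["balance_index_pct"].mean()),
                "n_counties": len(defined),
                "n_grade_I": int(counts.get("I", 0)),
                "n_grade_II": int(counts.get("II", 0)),
                "n_grade_III": int(counts.get("III", 0)),
                "n_grade_IV": int(counts.get("IV", 0)),
                "n_overloaded": int(counts.reindex(["II", "III", "IV"]).fillna(0).sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    if len(out) >= 2 and np.isfinite(out["mean_ip_weighted_pct"]).all():
        slope = float(np.polyfit(out["year"], out["mean_ip_weighted_pct"], 1)[0])
    else:
        slope = float("nan")
    out.attrs["ip_trend_pct_per_year"] = slope
    return out
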