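"""Pixel-wise long-series diagnostics.

Theil-Sen slope, the Mann-Kendall monotone-trend test with tie-corrected
variance, four-way trend classes, coefficient-of-variation stability
classes, and rescaled-range (R/S) Hurst persistence. Per-series functions
operate on 1-D arrays; ``*_stack`` wrappers map them over (time, y, x)
raster stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.stats import norm

TREND_CODES = {1: "SD", 2: "NSD", 3: "NSI", 4: "SI"}
TREND_NAMES = {
    "SD": "significant decrease",
    "NSD": "non-significant decrease",
    "NSI": "non-significant increase",
    "SI": "significant increase",
}

STABILITY_LABELS = ("stable", "relatively_stable", "unstable", "highly_unstable")
DEFAULT_CV_BREAKS = (0.1, 0.2, 0.3)

MIN_HURST_LENGTH = 32


def sen_slope(series) -> float:
    """Theil-Sen estimator: median of all pairwise slopes (xj-xi)/(j-i).

    Indices are the series' own time steps (years for an annual stack).
    Returns NaN for fewer than 2 valid points.
    """
    x = np.asarray(series, dtype=float)
    idx = np.arange(len(x))
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return float("nan")
    x, idx = x[ok], idx[ok]
    i, j = np.triu_indices(len(x), k=1)
    return float(np.median((x[j] - x[i]) / (idx[j] - idx[i])))


def mk_test(series, alpha: float = 0.05):
    """Mann-Kendall test: returns (S, Z, significant).

    S = sum of signs of all forward differences; Var(S) carries the standard
    tie correction; Z uses the +/-1 continuity correction. Requires >= 4
    valid points (returns NaNs otherwise).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        return float("nan"), float("nan"), False
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(x[j] - x[i]).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return float(s), 0.0, False
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return float(s), float(z), bool(abs(z) >= norm.ppf(1 - alpha / 2))


def classify_trend(sen: float, z: float, alpha: float = 0.05) -> str:
    """Four-way trend class from the Sen slope sign and MK significance.

    SI / NSI for increases, SD / NSD for decreases; a slope of exactly zero
    goes to NSI by (deterministic) convention.
    """
    if not (np.isfinite(sen) and np.isfinite(z)):
        return "nodata"
    sig = abs(z) >= norm.ppf(1 - alpha / 2)
    if sen > 0:
        return "SI" if sig else "NSI"
    if sen < 0:
        return "SD" if sig else "NSD"
    return "NSI"


def coefficient_of_variation(series, breaks=DEFAULT_CV_BREAKS):
    """(cv, stability class): sample-SD over mean, classed by breakpoints.

    Undefined (NaN, None) for a non-positive mean.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2 or x.mean() <= 0:
        return float("nan"), None
    cv = float(np.std(x, ddof=1) / x.mean())
    label = STABILITY_LABELS[int(np.searchsorted(np.asarray(breaks), cv, side="left"))]
    return cv, label


def hurst_exponent(series, min_window: int = 8) -> float:
    """Hurst exponent by classical rescaled-range (R/S) analysis.

    The series is split into contiguous blocks for each dyadic window length
    (min_window, 2*min_window, ..., n/2); per block, R is the range of
    cumulative deviations from the block mean and S the block standard
    deviation. H is the slope of log(mean R/S) against log(window). Returns
    NaN for series shorter than ``MIN_HURST_LENGTH`` or with no usable
    blocks.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < MIN_HURST_LENGTH:
        return float("nan")
    sizes = []
    w = min_window
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    log_w, log_rs = [], []
    for w in sizes:
        rs_vals = []
        for start in range(0, n - w + 1, w):
            block = x[start : start + w]
            dev = np.cumsum(block - block.mean())
            r = dev.max() - dev.min()
            s = block.std()
            if s > 0:
                rs_vals.append(r / s)
        if rs_vals:
            log_w.append(np.log(w))
            log_rs.append(np.log(np.mean(rs_vals)))
    if len(log_w) < 2:
        return float("nan")
    return float(np.polyfit(log_w, log_rs, 1)[0])


def persistence_label(hurst: float, sen: float, tol: float = 0.05) -> str:
    """Future-trend label from Hurst persistence and the current Sen sign."""
    if not np.isfinite(hurst):
        return "nodata"
    if abs(hurst - 0.5) <= tol:
        return "random"
    persistent = hurst > 0.5
    if sen > 0:
        return "continued_increase" if persistent else "reversal_to_decrease"
    if sen < 0:
        return "continued_decrease" if persistent else "reversal_to_increase"
    return "random"


@dataclass
class TrendStackResult:
    """Raster layers of the per-pixel diagnostics plus class summaries."""

    sen: xr.DataArray
    mk_s: xr.DataArray
    mk_z: xr.DataArray
    trend_class: xr.DataArray  # integer codes per TREND_CODES, 0 = nodata
    cv: xr.DataArray
    stability_class: xr.DataArray  # 1..4 per STABILITY_LABELS, 0 = nodata
    hurst: xr.DataArray

    def class_area_summary(self) -> dict:
        """Percent of valid pixels per trend class and stability class."""
        out = {}
        codes = self.trend_class.values
        valid = codes > 0
        total = valid.sum()
        for code, name in TREND_CODES.items():
            out[f"trend_{name}"] = float(100.0 * (codes == code).sum() / total) if total else 0.0
        scodes = self.stability_class.values
        valid = scodes > 0
        total = valid.sum()
        for i, name in enumerate(STABILITY_LABELS, start=1):
            out[f"stability_{name}"] = (
                float(100.0 * (scodes == i).sum() / total) if total else 0.0
            )
        return out


def trend_summary(
    stack: xr.DataArray,
    alpha: float = 0.05,
    cv_breaks=DEFAULT_CV_BREAKS,
    hurst_stack: xr.DataArray | None = None,
) -> TrendStackResult:
    """Run all per-pixel diagnostics over a (time, y, x) stack.

    ``stack`` is typically the annual capacity series; the Hurst exponent
    needs long records, so ``hurst_stack`` (e.g. the monthly series) may be
    supplied separately and defaults to ``stack``.
    """
    vals = stack.values
    ny, nx = vals.shape[1:]
    sen = np.full((ny, nx), np.nan)
    mks = np.full((ny, nx), np.nan)
    mkz = np.full((ny, nx), np.nan)
    tclass = np.zeros((ny, nx), dtype=np.int8)
    cv = np.full((ny, nx), np.nan)
    sclass = np.zeros((ny, nx), dtype=np.int8)
    hurst = np.full((ny, nx), np.nan)
    hvals = (hurst_stack if hurst_stack is not None else stack).values

    label_to_code = {v: k for k, v in TREND_CODES.items()}
    for iy in range(ny):
        for ix in range(nx):
            series = vals[:, iy, ix]
            if np.isfinite(series).sum() < 2:
                continue
            sen[iy, ix] = sen_slope(series)
            s, z, _ = mk_test(series, alpha)
            mks[iy, ix], mkz[iy, ix] = s, z
            cls = classify_trend(sen[iy, ix], z, alpha)
            if cls in label_to_code:
                tclass[iy, ix] = label_to_code[cls]
            c, lab = coefficient_of_variation(series, cv_breaks)
            cv[iy, ix] = c
            if lab is not None:
                sclass[iy, ix] = STABILITY_LABELS.index(lab) + 1
            hurst[iy, ix] = hurst_exponent(hvals[:, iy, ix])

    coords = {k: v for k, v in stack.coords.items() if k in ("y", "x")}
    mk2 = lambda a, name: xr.DataArray(a, dims=("y", "x"), coords=coords, name=name)
    return TrendStackResult(
        sen=mk2(sen, "sen_slope"),
        mk_s=mk2(mks, "mk_s"),
        mk_z=mk2(mkz, "mk_z"),
        trend_class=mk2(tclass, "trend_class"),
        cv=mk2(cv, "cv"),
        stability_class=mk2(sclass, "stability_class"),
        hurst=mk2(hurst, "hurst"),
    )
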