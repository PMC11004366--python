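"""Geographical detector: factor and interaction q statistics.

The factor detector measures how much of the spatial variance of a
continuous response y is explained by a categorical stratification X:

    q = 1 - sum_h N_h sigma_h^2 / (N sigma^2),

with population variances, so q = 1 - SSW/SST in (exactly) the ANOVA
decomposition sense, q in [0, 1]. The interaction detector overlays two
stratifications (their cross-classification) and compares q(a AND b) with
the marginal q values to categorize how the factors combine. Since the
overlay refines both marginal partitions, SSW can only shrink:
q_ab >= max(q_a, q_b) holds exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

INTERACTION_CATEGORIES = (
    "nonlinear-weaken",
    "univariate-weaken",
    "bivariate-enhance",
    "independent",
    "nonlinear-enhance",
)


def discretize(values, method: str = "quantile", k: int = 5):
    """Bin a continuous driver into k classes; returns (labels, boundaries).

    ``labels`` is an integer array (NaN inputs -> -1). Methods: ``quantile``
    (equal-frequency), ``equal-interval``, ``natural-breaks`` (1-D k-means on
    the values). If fewer distinct values than k exist, k is reduced with a
    warning; an already-categorical array (integer dtype) passes through.
    """
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.copy(), None
    arr = arr.astype(float)
    finite = arr[np.isfinite(arr)]
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = len(np.unique(finite))
    if n_distinct < k:
        warnings.warn(f"only {n_distinct} distinct values; reducing k from {k}")
        k = max(2, n_distinct)
    if method == "quantile":
        edges = np.unique(np.quantile(finite, np.linspace(0, 1, k + 1)[1:-1]))
    elif method == "equal-interval":
        edges = np.linspace(finite.min(), finite.max(), k + 1)[1:-1]
    elif method == "natural-breaks":
        edges = _kmeans_breaks(finite, k)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    labels = np.digitize(arr, edges)
    labels = np.where(np.isfinite(arr), labels, -1).astype(np.int32)
    return labels, np.asarray(edges)


def _kmeans_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Class edges from 1-D k-means (Jenks-style natural breaks)."""
    centers = np.quantile(values, np.linspace(0, 1, k))
    for _ in range(50):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[assign == i].mean() if (assign == i).any() else centers[i] for i in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    sorted_vals = np.sort(values)
    assign = np.argmin(np.abs(sorted_vals[:, None] - centers[order][None, :]), axis=1)
    edges = [
        (sorted_vals[assign == i].max() + sorted_vals[assign == i + 1].min()) / 2
        for i in range(k - 1)
        if (assign == i).any() and (assign == i + 1).any()
    ]
    return np.asarray(edges)


def _clean(y, strata):
    y = np.asarray(y, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    if y.shape != strata.shape:
        raise ValueError("y and strata must have equal length")
    ok = np.isfinite(y) & (strata >= 0 if np.issubdtype(strata.dtype, np.integer) else ~pd.isna(strata))
    return y[ok], strata[ok]


def factor_q(y, strata, validate: bool = True) -> float:
    """Explanatory power q = 1 - SSW/SST of a stratification for y.

    Population variances throughout, so the sum-of-squares identity is
    exact. ``validate`` enforces >= 2 strata with >= 2 samples each (overlay
    partitions produced internally may legitimately contain singletons).
    """
    y, strata = _clean(y, strata)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    codes, counts = np.unique(strata, return_counts=True)
    if validate:
        if len(codes) < 2:
            raise ValueError("need >= 2 strata")
        if (counts < 2).any():
            raise ValueError("every stratum needs >= 2 samples")
    sst = float(np.var(y) * n)
    if sst == 0:
        raise ValueError("zero overall variance: q undefined")
    ssw = 0.0
    for c in codes:
        grp = y[strata == c]
        ssw += float(np.var(grp) * len(grp))
    return 1.0 - ssw / sst


def permutation_pvalue(y, strata, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation-test p-value for q (labels shuffled against y)."""
    y, strata = _clean(y, strata)
    obs = factor_q(y, strata, validate=False)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        if factor_q(y, rng.permutation(strata), validate=False) >= obs:
            hits += 1
    return hits / (n_perm + 1)


def _overlay(strata_a, strata_b):
    pair = strata_a.astype(np.int64) * (strata_b.max() + 1) + strata_b.astype(np.int64)
    _, labels = np.unique(pair, return_inverse=True)
    return labels


def interaction_q(y, strata_a, strata_b, rtol: float = 1e-9):
    """Interaction q of two stratifications and its category.

    The overlay is the cross-classification of (a, b). Categories follow the
    standard comparison rules against q_a, q_b, their max and their sum;
    a tie with max(q_a, q_b) is labelled ``univariate-weaken`` with a
    ``boundary`` flag in the returned dict.
    """
    y = np.asarray(y, dtype=float).ravel()
    sa = np.asarray(strata_a).ravel()
    sb = np.asarray(strata_b).ravel()
    ok = np.isfinite(y) & (sa >= 0) & (sb >= 0)
    y, sa, sb = y[ok], sa[ok], sb[ok]
    q_a = factor_q(y, sa, validate=False)
    q_b = factor_q(y, sb, validate=False)
    q_ab = factor_q(y, _overlay(sa, sb), validate=False)

    lo, hi = min(q_a, q_b), max(q_a, q_b)
    boundary = np.isclose(q_ab, hi, rtol=rtol, atol=1e-12)
    if np.isclose(q_ab, q_a + q_b, rtol=rtol, atol=1e-12):
        category = "independent"
    elif q_ab < lo:
        category = "nonlinear-weaken"
    elif q_ab <= hi or boundary:
        category = "univariate-weaken"
    elif q_ab < q_a + q_b:
        category = "bivariate-enhance"
    else:
        category = "nonlinear-enhance"
    return {
        "q_a": q_a,
        "q_b": q_b,
        "q_ab": q_ab,
        "category": category,
        "boundary": bool(boundary),
    }


def rank_drivers(q_values: dict) -> list:
    """Driver names by descending q; exact ties broken alphabetically."""
    return [name for name, _ in sorted(q_values.items(), key=lambda kv: (-kv[1], kv[0]))]


@dataclass
class DetectorResult:
    """Factor-detector q per driver plus the pairwise interaction table."""

    q: dict
    pvalue: dict = field(default_factory=dict)
    interactions: pd.DataFrame | None = None
    bin_edges: dict = field(default_factory=dict)

    @property
    def ranking(self) -> list:
        return rank_drivers(self.q)


def run_detector(
    response: xr.DataArray,
    drivers: dict,
    method: str = "quantile",
    k: int = 5,
    max_samples: int = 50_000,
    seed: int = 0,
    n_perm: int = 0,
    interactions: bool = True,
) -> DetectorResult:
    """Factor and interaction detection of drivers on a response raster.

    ``drivers`` maps names to static rasters on the response grid.
    Continuous drivers are discretized (``method``, ``k``); integer rasters
    pass through as given strata. Pixels are subsampled (seeded) to at most
    ``max_samples``. ``n_perm > 0`` adds seeded permutation p-values.
    """
    y = response.values.ravel()
    strata = {}
    edges = {}
    for name, layer in drivers.items():
        vals = layer.values if isinstance(layer, xr.DataArray) else np.asarray(layer)
        labels, e = discretize(vals.ravel(), method=method, k=k)
        strata[name] = labels
        if e is not None:
            edges[name] = e

    ok = np.isfinite(y)
    for labels in strata.values():
        ok &= labels >= 0
    idx = np.flatnonzero(ok)
    if len(idx) > max_samples:
        idx = np.random.default_rng(seed).choice(idx, size=max_samples, replace=False)
    y_s = y[idx]

    q = {name: factor_q(y_s, labels[idx], validate=False) for name, labels in strata.items()}
    pvals = {}
    if n_perm > 0:
        for name, labels in strata.items():
            pvals[name] = permutation_pvalue(y_s, labels[idx], n_perm=n_perm, seed=seed)

    inter = None
    if interactions:
        rows = []
        for a, b in itertools.combinations(sorted(strata), 2):
            res = interaction_q(y_s, strata[a][idx], strata[b][idx])
            rows.append({"driver_a": a, "driver_b": b, **res})
        inter = pd.DataFrame(rows)
    return DetectorResult(q=q, pvalue=pvals, interactions=inter, bin_edges=edges)
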