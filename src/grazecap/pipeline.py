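"""End-to-end orchestration: simulate/load -> fuse -> npp -> capacity ->
balance -> trends -> detect, driven by one configuration object.

Each stage consumes the previous stage's in-memory artifacts, writes its
disk outputs under the run directory, and contributes a summary block to the
run manifest. Disabled stages are skipped; a stage whose inputs are missing
raises a clear dependency error.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import grazecap
from grazecap.casa_npp import CasaParams, compute_apar, compute_epsilon, compute_npp
from grazecap.forage_capacity import (
    CapacityParams,
    aggregate_windows,
    default_utilization,
    npp_to_yield,
)
from grazecap.geodetector import run_detector
from grazecap.io import write_herds, write_raster, write_yaml
from grazecap.livestock_balance import (
    compute_balance,
    herd_to_sheep_units,
    summarize_region,
    zonal_theoretical_capacity,
)
from grazecap.ndvi_fusion import fit_regression_grid, harmonize_series
from grazecap.synthetic_scene import SceneConfig, generate_scene
from grazecap.trend_stack import trend_summary

STAGES = ("fuse", "npp", "capacity", "balance", "trends", "detect")


class DependencyError(RuntimeError):
    """A stage was requested whose upstream artifact is missing."""


@dataclass
class RunConfig:
    """One-file configuration of a full pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    stages: tuple = STAGES
    casa: CasaParams = field(default_factory=CasaParams)
    capacity: CapacityParams = field(
        default_factory=lambda: CapacityParams(utilization=default_utilization())
    )
    sheep_units: dict | None = None
    alpha: float = 0.05
    detector_k: int = 5
    detector_method: str = "quantile"
    seed: int = 0
    out_dir: str = "grazecap_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "scene" in raw:
            scene = dict(raw["scene"])
            if "years" in scene:
                scene["years"] = tuple(scene["years"])
            kwargs["scene"] = SceneConfig(**scene)
        if "casa" in raw:
            casa = dict(raw["casa"])
            if "epsilon_max" in casa:
                casa["epsilon_max"] = {int(k): v for k, v in casa["epsilon_max"].items()}
            kwargs["casa"] = CasaParams(**casa)
        if "capacity" in raw:
            cap = dict(raw["capacity"])
            cap["utilization"] = {int(k): v for k, v in cap.get("utilization", {}).items()}
            kwargs["capacity"] = CapacityParams(**cap)
        for key in ("stages", "sheep_units", "alpha", "detector_k", "detector_method", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "stages" else raw[key]
        return cls(**kwargs)


def _param_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(
        {
            "scene": asdict(config.scene),
            "casa": asdict(config.casa),
            "capacity": asdict(config.capacity),
            "alpha": config.alpha,
            "detector_k": config.detector_k,
            "detector_method": config.detector_method,
            "seed": config.seed,
        },
        sort_keys=True,
        default_flow_style=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, bundle=None) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    ``bundle`` may carry a pre-generated scene; otherwise one is simulated
    from ``config.scene`` (with the run seed folded in).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": grazecap.__version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": {},
    }

    if bundle is None:
        scene_cfg = SceneConfig(**{**asdict(config.scene), "seed": config.seed})
        bundle = generate_scene(scene_cfg)
    write_herds(bundle.herds, out / "herds.csv")
    write_yaml(bundle.truth["config"], out / "scene_config.yaml")

    artifacts: dict = {"bundle": bundle}
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"][stage] = _STAGE_FUNCS[stage](config, artifacts, out)

    write_yaml(manifest, out / "manifest.yaml")
    return manifest


def _need(artifacts: dict, key: str, stage: str, produced_by: str):
    if key not in artifacts:
        raise DependencyError(
            f"stage {stage!r} needs {key!r}, produced by the {produced_by!r} stage"
        )
    return artifacts[key]


def _stage_fuse(config, artifacts, out):
    bundle = artifacts["bundle"]
    fit = fit_regression_grid(bundle.ndvi_a, bundle.ndvi_b)
    ndvi = harmonize_series(bundle.ndvi_a, bundle.ndvi_b, fit=fit)
    artifacts["ndvi"] = ndvi
    write_raster(ndvi, out / "ndvi_harmonized.tif")
    write_raster(fit["slope"], out / "calibration_slope.tif")
    write_raster(fit["intercept"], out / "calibration_intercept.tif")
    valid = fit["valid"].values
    return {
        "n_months": int(ndvi.sizes["time"]),
        "mean_slope": float(np.nanmean(fit["slope"].values)),
        "mean_intercept": float(np.nanmean(fit["intercept"].values)),
        "mean_r2": float(np.nanmean(fit["r2"].values)),
        "n_degenerate_pixels": int((~valid).sum()),
    }


def _stage_npp(config, artifacts, out):
    bundle = artifacts["bundle"]
    ndvi = _need(artifacts, "ndvi", "npp", "fuse")
    types = bundle.grassland_types
    apar = compute_apar(ndvi, bundle.solar_radiation, config.casa, types)
    eps = compute_epsilon(
        bundle.temperature,
        bundle.precipitation,
        bundle.solar_radiation,
        config.casa,
        ndvi,
        types,
    )
    npp = compute_npp(apar, eps)
    artifacts["npp"] = npp
    write_raster(npp, out / "npp_monthly.tif")
    years = pd.DatetimeIndex(npp.time.values).year
    annual = npp.groupby("time.year").sum("time", skipna=False)
    return {
        "mean_annual_npp_gC_m2": float(np.nanmean(annual.mean("year").values)),
        "n_months": int(npp.sizes["time"]),
        "n_years": int(len(set(years))),
    }


def _stage_capacity(config, artifacts, out):
    bundle = artifacts["bundle"]
    npp = _need(artifacts, "npp", "capacity", "npp")
    monthly_yield = npp_to_yield(npp, bundle.temperature)
    artifacts["monthly_yield"] = monthly_yield
    grids = {
        scheme: aggregate_windows(monthly_yield, bundle.grassland_types, config.capacity, scheme)
        for scheme in ("month", "season", "year")
    }
    artifacts["capacity"] = grids
    annual = grids["year"]
    cc_mean = float(np.nanmean([np.nanmean(g.cc.values) for g in annual]))
    summary = annual[-1].type_summary(bundle.grassland_types, config.scene.pixel_area_hm2)
    summary.to_csv(out / "capacity_by_type.csv", index=False)
    for g in annual:
        write_raster(g.cc, out / f"cc_{g.window}.tif")
    monthly_means = {
        g.window: float(np.nanmean(g.cc.values)) for g in grids["month"]
    }
    return {
        "mean_annual_cc_su_hm2": cc_mean,
        "n_windows_month": len(grids["month"]),
        "n_windows_season": len(grids["season"]),
        "n_windows_year": len(grids["year"]),
        "peak_month": max(monthly_means, key=monthly_means.get),
    }


def _stage_balance(config, artifacts, out):
    bundle = artifacts["bundle"]
    grids = _need(artifacts, "capacity", "balance", "capacity")
    rows = []
    for g in grids["year"]:
        ca = zonal_theoretical_capacity(g.cc, bundle.counties, config.scene.pixel_area_hm2)
        ca["year"] = int(g.window)
        rows.append(ca)
    theoretical = pd.concat(rows, ignore_index=True)
    actual = herd_to_sheep_units(bundle.herds, config.sheep_units)
    records = compute_balance(actual, theoretical)
    artifacts["balance"] = records
    records.to_csv(out / "balance_records.csv", index=False)
    summary = summarize_region(records)
    summary.to_csv(out / "balance_summary.csv", index=False)
    last = summary.iloc[-1]
    return {
        "n_county_years": len(records),
        "mean_ip_weighted_pct": float(summary["mean_ip_weighted_pct"].mean()),
        "ip_trend_pct_per_year": summary.attrs["ip_trend_pct_per_year"],
        "n_overloaded_last_year": int(last["n_overloaded"]),
    }


def _stage_trends(config, artifacts, out):
    grids = _need(artifacts, "capacity", "trends", "capacity")
    annual = grids["year"]
    cc_stack = grazecap.make_series(
        np.stack([g.cc.values for g in annual]),
        pd.DatetimeIndex([f"{g.window}-01-01" for g in annual]),
        "cc_annual",
        "SU hm-2",
    )
    monthly = grids["month"]
    cc_monthly = grazecap.make_series(
        np.stack([g.cc.values for g in monthly]),
        pd.DatetimeIndex([f"{g.window}-01" for g in monthly]),
        "cc_monthly",
        "SU hm-2",
    )
    result = trend_summary(cc_stack, alpha=config.alpha, hurst_stack=cc_monthly)
    artifacts["trends"] = result
    for name in ("sen", "mk_z", "trend_class", "cv", "stability_class", "hurst"):
        write_raster(getattr(result, name), out / f"trend_{name}.tif")
    summary = result.class_area_summary()
    pd.DataFrame([summary]).to_csv(out / "trend_class_areas.csv", index=False)
    summary["mean_hurst"] = float(np.nanmean(result.hurst.values))
    return summary


def _stage_detect(config, artifacts, out):
    bundle = artifacts["bundle"]
    grids = _need(artifacts, "capacity", "detect", "capacity")
    annual = grids["year"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cc_mean = np.nanmean(np.stack([g.cc.values for g in annual]), axis=0)
    response = grazecap.make_raster(cc_mean, "cc_mean", "SU hm-2")
    result = run_detector(
        response,
        bundle.drivers,
        method=config.detector_method,
        k=config.detector_k,
        seed=config.seed,
    )
    artifacts["detector"] = result
    pd.DataFrame(
        {"driver": list(result.q), "q": list(result.q.values())}
    ).sort_values("q", ascending=False).to_csv(out / "detector_q.csv", index=False)
    if result.interactions is not None:
        result.interactions.to_csv(out / "detector_interactions.csv", index=False)
    return {"q": {k: float(v) for k, v in result.q.items()}, "ranking": result.ranking}


_STAGE_FUNCS = {
    "fuse": _stage_fuse,
    "npp": _stage_npp,
    "capacity": _stage_capacity,
    "balance": _stage_balance,
    "trends": _stage_trends,
    "detect": _stage_detect,
}
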