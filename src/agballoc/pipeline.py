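"""End-to-end pipeline: simulate -> AGB -> FVC -> height -> trends ->
drivers -> diversity, with a machine-readable JSON report.

Every stage is skippable; later stages that need an earlier product raise
a named error if it was skipped.  All randomness flows from the single
``seed`` in :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as aio
from .agb import AGBEnsembleModel, default_forcings, ensemble_mean_and_sd
from .diversity import bin_and_fit, tipping_point
from .drivers import build_trend_design, fit_stratified_sem, lmm_interactions
from .exceptions import AgballocError, ConfigError
from .fvc import optimize_endmembers, sma_fvc
from .height import compute_ratio, fit_height_scaler, height_cube
from .scene import (
    ScenarioConfig,
    SurveyNoise,
    asymmetric_allocation_config,
    generate_scene,
    sample_surveys,
)
from .trends import (
    area_fraction,
    national_trend,
    pixelwise_trend_map,
    trend_correlation_map,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fit-agb", "fvc", "height", "trends", "drivers",
              "diversity")


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig | None = None   # default: asymmetric preset
    seed: int = 0
    n_plots: int = 800
    survey_noise: SurveyNoise = field(
        default_factory=lambda: SurveyNoise(agb=5.0, fvc=0.02, height=1.0)
    )
    forcings: tuple[str, ...] = ("satellite", "climate", "combined")
    agb_forcing_for_height: str = "ensemble_mean"  # paper-style ensemble average
    rf_params: dict = field(default_factory=dict)
    tau: float = 0.5
    fvc_floor: float = 0.05
    endmember_step: float = 0.01
    alpha: float = 0.05
    interactions: tuple[tuple[str, str], ...] = (("Ta", "Gp"),)
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None

    def resolve_scenario(self) -> ScenarioConfig:
        if self.scenario is not None:
            return self.scenario
        return asymmetric_allocation_config(seed=self.seed)


class PipelineStageError(AgballocError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fit_summary(fit) -> dict:
    return {
        "slope": _f(fit.slope),
        "t": _f(fit.t),
        "p": _f(fit.p),
        "r2": _f(fit.r2),
        "n": int(fit.n),
        "ci95": [_f(v) for v in fit.ci(0.95)],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and return the report dict."""
    on = set(config.stages)
    unknown = on - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": _echo_config(config), "stages": sorted(on)}
    state: dict = {}

    def run_stage(name, fn):
        if name not in on:
            return
        try:
            fn()
        except Exception as e:  # halt with stage name; keep partial report
            raise PipelineStageError(name, e) from e

    # ---- simulate ------------------------------------------------------
    def do_simulate():
        scenario = config.resolve_scenario()
        scene = generate_scene(scenario)
        surveys = sample_surveys(
            scene, config.n_plots, noise=config.survey_noise,
            seed=config.seed + 1,
        )
        state["scene"] = scene
        state["surveys"] = surveys
        if out_dir:
            aio.write_scene(scene, out_dir / "scene.nc")
            aio.write_surveys(surveys, out_dir / "surveys.csv")

    run_stage("simulate", do_simulate)
    if "scene" not in state:
        raise ConfigError("pipeline requires the 'simulate' stage")
    scene, surveys = state["scene"], state["surveys"]

    # ---- fvc -----------------------------------------------------------
    def do_fvc():
        endmembers = optimize_endmembers(surveys, step=config.endmember_step)
        fvc_cube = sma_fvc(scene.ndvi, endmembers, scene.type_map)
        state["endmembers"] = endmembers
        state["fvc"] = fvc_cube
        report["fvc"] = {
            "endmembers": json.loads(endmembers.table.to_json(orient="index")),
        }
        if out_dir:
            endmembers.to_csv(out_dir / "endmembers.csv")
            aio.write_cube(fvc_cube, out_dir / "fvc.nc")

    run_stage("fvc", do_fvc)

    # ---- fit-agb -------------------------------------------------------
    def do_agb():
        wanted = [f for f in default_forcings() if f.label in config.forcings]
        model = AGBEnsembleModel.from_scene(
            scene, surveys, forcings=wanted, rf_params=config.rf_params
        )
        results = model.fit(seed=config.seed + 2)
        from .agb import scene_feature_cubes

        cubes = scene_feature_cubes(scene)
        pred = {
            lbl: results.predict_cube(cubes, lbl) for lbl in results.labels
        }
        state["agb_results"] = results
        state["agb_cubes"] = pred
        mean_cube = sum(pred.values()) / len(pred)
        mean_cube.name = "agb_ensemble_mean"
        state["agb_mean"] = mean_cube
        report["agb"] = {
            lbl: {
                "holdout_r2": _f(results.fits[lbl].holdout_r2),
                "holdout_rmse": _f(results.fits[lbl].holdout_rmse),
                "cv_rmse": _f(results.fits[lbl].cv_rmse),
                "bma_weights": results.fits[lbl].weights.tolist(),
            }
            for lbl in results.labels
        }
        if out_dir:
            results.save_metadata(out_dir / "agb_models.json")
            aio.write_cube(mean_cube, out_dir / "agb_ensemble_mean.nc")

    run_stage("fit-agb", do_agb)

    # ---- height --------------------------------------------------------
    def do_height():
        if "fvc" not in state or "agb_mean" not in state:
            raise ConfigError("height stage needs 'fvc' and 'fit-agb'")
        if config.agb_forcing_for_height == "ensemble_mean":
            agb_cube = state["agb_mean"]
        else:
            agb_cube = state["agb_cubes"][config.agb_forcing_for_height]
        ratio = compute_ratio(agb_cube, state["fvc"], config.fvc_floor)
        scaler = fit_height_scaler(surveys, tau=config.tau,
                                   fvc_floor=config.fvc_floor)
        hcube = height_cube(ratio, scaler, scene.type_map)
        state["ratio"] = ratio
        state["height"] = hcube
        report["height"] = {
            "scaler": json.loads(scaler.table.to_json(orient="index")),
            "mean_height_cm": _f(np.nanmean(hcube.values)),
            "sd_height_cm": _f(np.nanstd(hcube.values)),
        }
        if out_dir:
            scaler.to_csv(out_dir / "height_scaler.csv")
            aio.write_cube(hcube, out_dir / "height.nc")

    run_stage("height", do_height)

    # ---- trends --------------------------------------------------------
    def do_trends():
        tr: dict = {}
        cubes = {}
        if "agb_mean" in state:
            cubes["AGB"] = state["agb_mean"]
        if "fvc" in state:
            cubes["FVC"] = state["fvc"]
        if "height" in state:
            cubes["CH"] = state["height"]
        if not cubes:
            raise ConfigError("trends stage has no cubes to analyse")
        maps = {}
        for name, cube in cubes.items():
            tm = pixelwise_trend_map(cube)
            maps[name] = tm
            nat = national_trend(cube)
            tr[name] = {
                "national": _fit_summary(nat),
                "area_fraction_increasing": area_fraction(tm, "slope>0"),
                "area_fraction_decreasing": area_fraction(tm, "slope<0"),
                "area_fraction_increasing_significant": area_fraction(
                    tm, "slope>0", alpha=config.alpha
                ),
            }
            if out_dir:
                aio.write_dataset(tm, out_dir / f"trend_{name.lower()}.nc")
        state["trend_maps"] = maps
        if "AGB" in cubes and "FVC" in cubes:
            gfit, _ = trend_correlation_map(cubes["FVC"], cubes["AGB"])
            tr["fvc_agb_trend_correlation"] = {
                "r": gfit.slope, "t": gfit.t, "p": gfit.p, "n": gfit.n,
            }
        if "agb_cubes" in state and len(state["agb_cubes"]) >= 2:
            slope_maps = [
                pixelwise_trend_map(c)["slope"]
                for c in state["agb_cubes"].values()
            ]
            mean_map, sd_map = ensemble_mean_and_sd(slope_maps)
            tr["agb_trend_ensemble_sd_mean"] = _f(np.nanmean(sd_map.values))
            if out_dir:
                aio.write_cube(sd_map, out_dir / "agb_trend_ensemble_sd.nc")
        report["trends"] = tr

    run_stage("trends", do_trends)

    # ---- drivers -------------------------------------------------------
    def do_drivers():
        if "trend_maps" not in state or "CH" not in state["trend_maps"]:
            raise ConfigError("drivers stage needs height trends")
        maps = state["trend_maps"]
        driver_maps = {
            d: pixelwise_trend_map(cube) for d, cube in scene.drivers.items()
        }
        responses = {k: maps[k] for k in ("CH", "FVC", "AGB") if k in maps}
        design = build_trend_design(responses, driver_maps, scene.type_map)
        sem = fit_stratified_sem(design)
        rep = {}
        for stratum, res in sem.items():
            rep[stratum] = {
                "n": res.n,
                "r2": {k: _f(v) for k, v in res.r2.items()},
                "paths": json.loads(res.edges.to_json(orient="records")),
            }
        lmm = lmm_interactions(design, pairs=config.interactions)
        report["drivers"] = {
            "sem": rep,
            "lmm_fixed_effects": {
                k: {"coef": _f(r["coef"]), "se": _f(r["se"]), "p": _f(r["p"])}
                for k, r in lmm.iterrows()
            },
            "n_zero_trend_excluded": design.n_zero_trend_excluded,
        }
        state["design"] = design
        if out_dir:
            design.frame.to_csv(out_dir / "trend_design.csv", index=False)

    run_stage("drivers", do_drivers)

    # ---- diversity -----------------------------------------------------
    def do_diversity():
        if "trend_maps" not in state or "CH" not in state["trend_maps"]:
            raise ConfigError("diversity stage needs height trends")
        ch_slope = state["trend_maps"]["CH"]["slope"].values
        div = {}
        for name, grid, kw in (
            ("richness", scene.richness.values, {"integer_bins": True}),
            ("fhd", scene.fhd.values, {"n_bins": 25}),
        ):
            try:
                fit = bin_and_fit(ch_slope, grid, **kw)
            except AgballocError as e:
                div[name] = {"error": str(e)}
                continue
            tp = tipping_point(fit)
            div[name] = {
                "r": _f(fit.r), "t": _f(fit.t), "df": fit.df, "p": _f(fit.p),
                "slope": _f(fit.slope), "intercept": _f(fit.intercept),
                "tipping_point": None if tp is None else _f(tp),
                "n_bins": fit.n_bins,
            }
        report["diversity"] = div

    run_stage("diversity", do_diversity)

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _f(x) -> float | None:
    x = float(x)
    return None if not np.isfinite(x) else x


def _echo_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scenario"] = aio.config_to_dict(config.resolve_scenario())
    d["survey_noise"] = dataclasses.asdict(config.survey_noise)
    d["interactions"] = [list(p) for p in config.interactions]
    return d
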