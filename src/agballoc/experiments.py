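"""Canned recovery experiments on synthetic scenes.

These drive the package end to end under the asymmetric-allocation study
conditions and measure how well known ground truth is recovered.  They
are used by the test suite and the reproduction script; problem sizes
(50x50 grids, 800 plots, 100-tree forests) are desk-scale choices that
keep a full multi-seed experiment in the minutes range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agb import AGBEnsembleModel, scene_feature_cubes
from .drivers import build_trend_design, PiecewiseSEM
from .fvc import optimize_endmembers, sma_fvc
from .height import compute_ratio, fit_height_scaler, height_cube
from .scene import SurveyNoise, asymmetric_allocation_config, generate_scene, sample_surveys
from .trends import national_trend, pixelwise_trend_map

DEFAULT_SURVEY_NOISE = SurveyNoise(agb=5.0, fvc=0.02, height=1.0)


def asymmetric_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    grid: tuple[int, int] = (50, 50),
    n_plots: int = 800,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Full-pipeline trend recovery on the asymmetric-allocation preset.

    For each seed: generate the scene, survey it, fit endmembers and the
    three-forcing AGB ensemble, unmix cover, convert the ensemble-average
    AGB / cover ratio to height, and record the recovered national mean
    trends next to the generator truth.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        scene = generate_scene(
            asymmetric_allocation_config(grid_rows=grid[0], grid_cols=grid[1],
                                         seed=seed)
        )
        surveys = sample_surveys(scene, n_plots, noise=DEFAULT_SURVEY_NOISE,
                                 seed=seed + 1)
        endmembers = optimize_endmembers(surveys)
        fvc = sma_fvc(scene.ndvi, endmembers, scene.type_map)
        model = AGBEnsembleModel.from_scene(
            scene, surveys, rf_params={"n_estimators": n_trees}
        )
        results = model.fit(seed=seed + 2)
        cubes = scene_feature_cubes(scene)
        agb = sum(results.predict_cube(cubes, lbl) for lbl in results.labels)
        agb = agb / len(results.labels)
        scaler = fit_height_scaler(surveys)
        height = height_cube(compute_ratio(agb, fvc), scaler, scene.type_map)
        rows.append(
            {
                "seed": seed,
                "height_trend": national_trend(height).slope,
                "agb_trend": national_trend(agb).slope,
                "fvc_trend": national_trend(fvc).slope,
                "true_height_trend": national_trend(scene.true_height).slope,
                "true_agb_trend": national_trend(scene.true_agb).slope,
                "true_fvc_trend": national_trend(scene.true_fvc).slope,
                "mean_height": float(np.nanmean(height.values)),
                "true_mean_height": float(np.nanmean(scene.true_height.values)),
                "holdout_r2_combined": results.holdout_r2("combined"),
            }
        )
    return pd.DataFrame(rows)


def forcing_ordering(
    n_seeds: int = 10,
    base_seed: int = 0,
    grid: tuple[int, int] = (50, 50),
    n_plots: int = 800,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Holdout R^2 of the satellite / climate / combined forcings per seed."""
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        scene = generate_scene(
            asymmetric_allocation_config(grid_rows=grid[0], grid_cols=grid[1],
                                         seed=seed)
        )
        surveys = sample_surveys(scene, n_plots, noise=DEFAULT_SURVEY_NOISE,
                                 seed=seed + 1)
        model = AGBEnsembleModel.from_scene(
            scene, surveys, rf_params={"n_estimators": n_trees}
        )
        results = model.fit(seed=seed + 2)
        rows.append(
            {
                "seed": seed,
                "satellite": results.holdout_r2("satellite"),
                "climate": results.holdout_r2("climate"),
                "combined": results.holdout_r2("combined"),
            }
        )
    return pd.DataFrame(rows)


def sem_sign_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    grid: tuple[int, int] = (100, 100),
) -> pd.DataFrame:
    """Recovery of the five height path signs from noisy pixel trends.

    Per seed, a 100x100 asymmetric scene (10^4 pixels) is generated with
    all noise on, pixel trends of the true height and the five drivers
    are computed, and the piecewise SEM's height equation is fitted on
    the z-scored design.  The recovered path sign for each driver is
    compared with the sign of the generating height response.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = asymmetric_allocation_config(grid_rows=grid[0],
                                           grid_cols=grid[1], seed=seed)
        scene = generate_scene(cfg)
        responses = {"CH": pixelwise_trend_map(scene.true_height)}
        driver_maps = {d: pixelwise_trend_map(c)
                       for d, c in scene.drivers.items()}
        design = build_trend_design(responses, driver_maps, scene.type_map)
        res = PiecewiseSEM(design, dag={"CH": tuple(driver_maps)}).fit()
        row = {"seed": seed}
        n_correct = 0
        for d, true_beta in cfg.height_response.items():
            beta = res.coef("CH", d)
            ok = np.sign(beta) == np.sign(true_beta)
            row[d] = beta
            n_correct += int(ok)
        row["n_signs_correct"] = n_correct
        rows.append(row)
    return pd.DataFrame(rows)


def endmember_recovery(
    n_seeds: int = 10,
    base_seed: int = 0,
    grid: tuple[int, int] = (40, 40),
    n_plots: int = 500,
    sigma_ndvi: float = 0.02,
) -> pd.DataFrame:
    """Monte-Carlo endmember recovery under NDVI noise.

    Scenes use a single grassland type with on-grid true endmembers
    (0.12, 0.82); surveys carry no measurement noise so the recovery
    error isolates the effect of NDVI noise on the unmixing fit.
    """
    from .scene import ScenarioConfig, TypeParams

    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = ScenarioConfig(
            grid_rows=grid[0], grid_cols=grid[1],
            type_params={1: TypeParams(0.12, 0.82, 10.0, 18.0, 0.45)},
            sigma_ndvi=sigma_ndvi,
            cover_base_field_sigma=0.18,
            height_base_field_sigma=2.0,
            smooth_sigma=3.0,
            seed=seed,
        )
        scene = generate_scene(cfg)
        surveys = sample_surveys(scene, n_plots, seed=seed + 1)
        em = optimize_endmembers(surveys)
        rows.append(
            {
                "seed": seed,
                "soil": em.soil(1),
                "veg": em.veg(1),
                "err_soil": abs(em.soil(1) - 0.12),
                "err_veg": abs(em.veg(1) - 0.82),
            }
        )
    return pd.DataFrame(rows)
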