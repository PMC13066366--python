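"""Gridded aboveground biomass by random-forest ensembles.

Plot AGB is upscaled with random forests under three forcing ensembles —
satellite metrics alone, climate variables alone, and their combination.
Training uses a 10% independent holdout plus five-fold cross-validation
on the remaining 90% (repeated four times with fresh fold splits to
average the validation error), random oversampling of the high-biomass
minority above a quantile threshold, and BIC-approximated Bayesian model
averaging over the five fold models.  Production models for gridded
prediction are refit on the full plot set under the same five-fold
scheme; per-pixel predictions are the BMA-weighted mean of the fold
models, and the spread of the per-forcing trend maps gives the ensemble
SD map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor

from .exceptions import ConfigError, DataError
from .rasters import check_aligned
from .scene import DRIVERS, Scene

log = logging.getLogger(__name__)

# every forced variable enters as its per-pixel long-term mean plus the
# per-year anomaly against it (separating the cross-sectional gradient from
# the temporal signal, as upscaling studies build their climate predictors);
# the static grassland-type grid is a known input of the workflow (endmembers
# and height scalers are fitted per type) and is part of every forcing
SATELLITE_FEATURES = (
    "ndvi_mean", "ndvi_anom", "lai_mean", "lai_anom", "type",
)
CLIMATE_FEATURES = tuple(
    f"{d}_{part}" for d in DRIVERS for part in ("mean", "anom")
) + ("type",)
DEFAULT_RF_PARAMS = {"n_estimators": 200, "n_jobs": 1}


@dataclass(frozen=True)
class ForcingEnsemble:
    label: str
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if not self.feature_names:
            raise ConfigError(f"forcing {self.label!r}: empty feature list")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ConfigError(f"forcing {self.label!r}: duplicate features")


def default_forcings() -> list[ForcingEnsemble]:
    sat = tuple(SATELLITE_FEATURES)
    cli = tuple(CLIMATE_FEATURES)
    combined = sat + tuple(f for f in cli if f not in sat)
    return [
        ForcingEnsemble("satellite", sat),
        ForcingEnsemble("climate", cli),
        ForcingEnsemble("combined", combined),
    ]


@dataclass
class Partition:
    holdout: np.ndarray          # positional indices
    folds: list[np.ndarray]

    def training(self) -> np.ndarray:
        return np.concatenate(self.folds)


def split_holdout_folds(
    n_or_table, holdout_frac: float = 0.10, n_folds: int = 5, seed: int = 0
) -> Partition:
    """Random partition into a holdout set and ``n_folds`` CV folds.

    Covers every record exactly once; fold sizes differ by at most one.
    """
    n = n_or_table if isinstance(n_or_table, int) else len(n_or_table)
    if n < n_folds + 1:
        raise DataError(f"need at least {n_folds + 1} records, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = int(round(holdout_frac * n))
    holdout = perm[:n_hold]
    rest = perm[n_hold:]
    folds = [np.sort(f) for f in np.array_split(rest, n_folds)]
    return Partition(holdout=np.sort(holdout), folds=folds)


def oversample_minority(
    train: pd.DataFrame,
    quantile_cut: float = 0.75,
    seed: int = 0,
    target: str = "agb_g_m2",
) -> pd.DataFrame:
    """Random oversampling of high-biomass records.

    Records with target above the ``quantile_cut`` quantile are duplicated
    with replacement until they are as numerous as the records at or below
    it.  All original records are retained; a degenerate (constant) target
    returns the input unchanged with a logged notice.
    """
    if train.empty:
        raise DataError("empty training table")
    y = train[target].to_numpy(dtype=float)
    if np.ptp(y[np.isfinite(y)]) == 0:
        log.info("oversample_minority: constant target, returning input")
        return train
    thr = np.nanquantile(y, quantile_cut)
    high = np.flatnonzero(y > thr)
    low_count = len(train) - len(high)
    if len(high) == 0 or len(high) >= low_count:
        return train
    rng = np.random.default_rng(seed)
    extra = rng.choice(high, size=low_count - len(high), replace=True)
    return pd.concat(
        [train, train.iloc[extra]], ignore_index=True
    )


def bma_weights(
    fold_validation_errors: Sequence[float], n_val: Sequence[int] | int
) -> np.ndarray:
    """Posterior model weights from fold validation RMSEs.

    Under a Gaussian likelihood of the validation residuals the BIC of
    fold model k is ``n_k * ln(rmse_k^2)`` up to a shared constant, and
    the approximate posterior weight is ``exp(-BIC_k / 2)`` normalized.
    A fold with vanishing error takes all the weight (shared equally
    among zero-error folds).
    """
    err = np.asarray(fold_validation_errors, dtype=float)
    if not np.all(np.isfinite(err)) or np.any(err < 0):
        raise DataError("validation errors must be finite and non-negative")
    n = np.broadcast_to(np.asarray(n_val, dtype=float), err.shape)
    if np.any(n <= 0):
        raise DataError("validation counts must be positive")
    zero = err == 0
    if zero.any():
        w = zero.astype(float)
        return w / w.sum()
    bic = n * np.log(err**2)
    w = np.exp(-0.5 * (bic - bic.min()))
    return w / w.sum()


@dataclass
class ForcingFit:
    """Fitted fold models and metrics for one forcing ensemble."""

    label: str
    feature_names: tuple[str, ...]
    models: list                      # production fold models (full data)
    weights: np.ndarray               # production BMA weights
    holdout_r2: float                 # on the untouched 10%
    holdout_rmse: float
    cv_rmse: float                    # mean over 4 repeats x 5 folds
    fold_rmse: np.ndarray             # first-repeat per-fold validation RMSE

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.models])
        return np.average(preds, axis=0, weights=self.weights)


class AGBEnsembleModel:
    """Random-forest AGB upscaling model over one or more forcings.

    Parameters
    ----------
    data : DataFrame with the target column and every feature column named
        by the forcings.
    forcings : list of :class:`ForcingEnsemble` (default: satellite,
        climate, combined).
    rf_params : passed to ``RandomForestRegressor``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        forcings: list[ForcingEnsemble] | None = None,
        rf_params: Mapping | None = None,
        holdout_frac: float = 0.10,
        n_folds: int = 5,
        oversample_quantile: float = 0.75,
        n_repeats: int = 4,
        target: str = "agb_g_m2",
    ):
        self.forcings = forcings if forcings is not None else default_forcings()
        self.rf_params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
        self.holdout_frac = holdout_frac
        self.n_folds = n_folds
        self.oversample_quantile = oversample_quantile
        self.n_repeats = n_repeats
        self.target = target

        needed = {target}
        for f in self.forcings:
            needed |= set(f.feature_names)
        missing = needed - set(data.columns)
        if missing:
            raise ConfigError(f"missing feature columns: {sorted(missing)}")
        finite = np.isfinite(
            data[sorted(needed)].to_numpy(dtype=float)
        ).all(axis=1)
        if (~finite).any():
            log.info("AGBEnsembleModel: dropped %d non-finite records",
                     int((~finite).sum()))
        self.data = data.loc[finite].reset_index(drop=True)

    @classmethod
    def from_scene(
        cls,
        scene: Scene,
        surveys: pd.DataFrame,
        **kw,
    ) -> "AGBEnsembleModel":
        return cls(attach_plot_features(surveys, scene), **kw)

    # -- fitting ---------------------------------------------------------
    def _rf(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(random_state=seed, **self.rf_params)

    def _train_folds(
        self, df: pd.DataFrame, features, part_folds, seed: int
    ):
        """Train one RF per fold (on the other folds, oversampled) and
        return (models, per-fold validation RMSE, fold sizes)."""
        models, rmses, sizes = [], [], []
        y_all = df[self.target].to_numpy(dtype=float)
        X_all = df[list(features)].to_numpy(dtype=float)
        for k, fold in enumerate(part_folds):
            train_idx = np.concatenate(
                [f for j, f in enumerate(part_folds) if j != k]
            )
            tr = df.iloc[train_idx]
            tr = oversample_minority(
                tr, self.oversample_quantile, seed=seed + 1000 + k,
                target=self.target,
            )
            m = self._rf(seed + k)
            m.fit(tr[list(features)].to_numpy(dtype=float),
                  tr[self.target].to_numpy(dtype=float))
            pred = m.predict(X_all[fold])
            rmses.append(float(np.sqrt(np.mean((pred - y_all[fold]) ** 2))))
            models.append(m)
            sizes.append(len(fold))
        return models, np.asarray(rmses), np.asarray(sizes)

    def fit(self, seed: int = 0) -> "AGBEnsembleResults":
        part = split_holdout_folds(
            len(self.data), self.holdout_frac, self.n_folds, seed
        )
        train_df = self.data.iloc[part.training()].reset_index(drop=True)
        hold_df = self.data.iloc[part.holdout]
        fits: dict[str, ForcingFit] = {}
        for fc in self.forcings:
            feats = fc.feature_names
            # repeat the 5-fold loop with fresh splits to average the
            # validation error; the first repeat supplies the holdout models
            all_rmse = []
            first_models = first_rmse = first_sizes = None
            for rep in range(self.n_repeats):
                rep_seed = seed + 7919 * rep
                rng = np.random.default_rng(rep_seed)
                perm = rng.permutation(len(train_df))
                folds = [np.sort(f) for f in np.array_split(perm, self.n_folds)]
                models, rmses, sizes = self._train_folds(
                    train_df, feats, folds, rep_seed
                )
                all_rmse.append(rmses)
                if rep == 0:
                    first_models, first_rmse, first_sizes = models, rmses, sizes
            w_eval = bma_weights(first_rmse, first_sizes)
            X_hold = hold_df[list(feats)].to_numpy(dtype=float)
            y_hold = hold_df[self.target].to_numpy(dtype=float)
            pred_hold = np.average(
                np.stack([m.predict(X_hold) for m in first_models]),
                axis=0, weights=w_eval,
            )
            resid = pred_hold - y_hold
            holdout_rmse = float(np.sqrt(np.mean(resid**2)))
            var = float(np.var(y_hold))
            holdout_r2 = (
                float(1.0 - np.mean(resid**2) / var) if var > 0 else np.nan
            )
            if var == 0:
                log.info("forcing %s: constant holdout target, R2 undefined",
                         fc.label)

            # production models: full data under the five-fold scheme
            rng = np.random.default_rng(seed + 104729)
            perm = rng.permutation(len(self.data))
            folds = [np.sort(f) for f in np.array_split(perm, self.n_folds)]
            prod_models, prod_rmse, prod_sizes = self._train_folds(
                self.data.reset_index(drop=True), feats, folds, seed + 104729
            )
            fits[fc.label] = ForcingFit(
                label=fc.label,
                feature_names=tuple(feats),
                models=prod_models,
                weights=bma_weights(prod_rmse, prod_sizes),
                holdout_r2=holdout_r2,
                holdout_rmse=holdout_rmse,
                cv_rmse=float(np.mean(all_rmse)),
                fold_rmse=first_rmse,
            )
        return AGBEnsembleResults(
            fits=fits, partition=part, seed=seed, model=self
        )


@dataclass
class AGBEnsembleResults:
    """Fitted per-forcing bundles with metrics and gridded prediction."""

    fits: dict[str, ForcingFit]
    partition: Partition
    seed: int
    model: AGBEnsembleModel = field(repr=False)

    @property
    def labels(self) -> list[str]:
        return list(self.fits)

    def holdout_r2(self, label: str) -> float:
        return self.fits[label].holdout_r2

    def predict(self, X: pd.DataFrame | np.ndarray, forcing: str) -> np.ndarray:
        fit = self.fits[forcing]
        if isinstance(X, pd.DataFrame):
            X = X[list(fit.feature_names)].to_numpy(dtype=float)
        return fit.predict(np.asarray(X, dtype=float))

    def predict_cube(
        self, feature_cubes: Mapping[str, xr.DataArray], forcing: str
    ) -> xr.DataArray:
        return predict_agb_cube(self, feature_cubes, forcing)

    def summary(self) -> pd.DataFrame:
        rows = {
            lbl: {
                "holdout_r2": f.holdout_r2,
                "holdout_rmse": f.holdout_rmse,
                "cv_rmse": f.cv_rmse,
                "n_features": len(f.feature_names),
                "weights": np.array2string(f.weights, precision=3),
            }
            for lbl, f in self.fits.items()
        }
        return pd.DataFrame(rows).T

    def save_metadata(self, path) -> None:
        meta = {
            "seed": self.seed,
            "forcings": {
                lbl: {
                    "features": list(f.feature_names),
                    "weights": f.weights.tolist(),
                    "holdout_r2": None
                    if not np.isfinite(f.holdout_r2)
                    else f.holdout_r2,
                    "holdout_rmse": f.holdout_rmse,
                    "cv_rmse": f.cv_rmse,
                }
                for lbl, f in self.fits.items()
            },
        }
        Path(path).write_text(json.dumps(meta, indent=2))


def scene_feature_cubes(scene: Scene) -> dict[str, xr.DataArray]:
    """Feature cubes by name: long-term mean and anomaly of every satellite
    metric and driver, plus the static grassland-type grid."""
    base = {"ndvi": scene.ndvi, "lai": scene.lai}
    base.update(scene.drivers)
    dims, coords = scene.ndvi.dims, scene.ndvi.coords
    ny = len(scene.years)
    cubes: dict[str, xr.DataArray] = {}
    for name, cube in base.items():
        vals = np.asarray(cube.values, dtype=float)
        mean = np.nanmean(vals, axis=0, keepdims=True)
        cubes[f"{name}_mean"] = xr.DataArray(
            np.broadcast_to(mean, vals.shape).copy(), dims=dims, coords=coords,
            name=f"{name}_mean",
        )
        cubes[f"{name}_anom"] = xr.DataArray(
            vals - mean, dims=dims, coords=coords, name=f"{name}_anom"
        )
        cubes[name] = cube
    tm = np.broadcast_to(
        scene.type_map.values.astype(float), (ny,) + scene.type_map.shape
    )
    cubes["type"] = xr.DataArray(
        tm.copy(), dims=dims, coords=coords, name="type"
    )
    return cubes


def attach_plot_features(surveys: pd.DataFrame, scene: Scene) -> pd.DataFrame:
    """Join per-plot feature values sampled at each record's pixel-year."""
    df = surveys.copy()
    cubes = scene_feature_cubes(scene)
    years = scene.years
    year_index = {int(y): i for i, y in enumerate(years)}
    yi = df["year"].map(year_index).to_numpy()
    ri = df["row"].to_numpy(dtype=int)
    ci = df["col"].to_numpy(dtype=int)
    for name, cube in cubes.items():
        if name in df.columns:
            continue
        df[name] = np.asarray(cube.values, dtype=float)[yi, ri, ci]
    return df


def predict_agb_cube(
    results: AGBEnsembleResults,
    feature_cubes: Mapping[str, xr.DataArray],
    forcing: str,
) -> xr.DataArray:
    """BMA-weighted per-pixel AGB prediction; nodata propagates."""
    fit = results.fits[forcing]
    missing = [f for f in fit.feature_names if f not in feature_cubes]
    if missing:
        raise ConfigError(f"missing feature cubes: {missing}")
    cubes = [feature_cubes[f] for f in fit.feature_names]
    check_aligned(*cubes)
    stack = np.stack([np.asarray(c.values, dtype=float) for c in cubes], axis=-1)
    ny, nr, nc, nf = stack.shape
    flat = stack.reshape(-1, nf)
    ok = np.isfinite(flat).all(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if ok.any():
        out[ok] = fit.predict(flat[ok])
    template = cubes[0]
    return xr.DataArray(
        out.reshape(ny, nr, nc),
        dims=template.dims,
        coords=template.coords,
        name="agb_pred",
    )


def ensemble_mean_and_sd(
    maps: Sequence[xr.DataArray],
) -> tuple[xr.DataArray, xr.DataArray]:
    """Per-pixel mean and population SD across forcing ensembles."""
    if len(maps) < 2:
        raise DataError("need at least two maps")
    check_aligned(*maps)
    arr = np.stack([np.asarray(m.values, dtype=float) for m in maps])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    dims = maps[0].dims
    return (
        xr.DataArray(mean, dims=dims, coords=maps[0].coords, name="ensemble_mean"),
        xr.DataArray(sd, dims=dims, coords=maps[0].coords, name="ensemble_sd"),
    )
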