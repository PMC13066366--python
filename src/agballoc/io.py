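"""Formats, compositing and correction utilities.

NetCDF (via xarray) is the canonical cube container; a directory of
per-year TIFFs is accepted on input; CSV for tables; YAML for configs;
JSON for reports.  Also home to the two dataset-preparation primitives:
maximum value compositing and linear station-based bias correction.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .exceptions import DataError, NumericalError
from .rasters import make_cube
from .scene import Scene, ScenarioConfig, TypeParams

log = logging.getLogger(__name__)

NC_ENGINE = "scipy"


def max_value_composite(layers: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over within-season layers, ignoring nodata.

    All-nodata pixels stay nodata.  Used to suppress clouds/atmosphere in
    the seasonal composite.
    """
    if isinstance(layers, np.ndarray) and layers.ndim >= 2:
        stack = np.asarray(layers, dtype=float)
    else:
        layers = list(layers)
        if not layers:
            raise DataError("empty layer list")
        stack = np.stack([np.asarray(l, dtype=float) for l in layers])
    if stack.shape[0] == 0:
        raise DataError("empty layer list")
    all_nan = np.all(np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        out = np.nanmax(np.where(np.isnan(stack), -np.inf, stack), axis=0)
    out = np.where(all_nan, np.nan, out)
    return out


def linear_bias_correction(
    gridded_series: np.ndarray,
    station_series: np.ndarray,
    cube: xr.DataArray | np.ndarray | None = None,
    floor_zero: bool = True,
):
    """OLS correction of a gridded product against station observations.

    Fits ``station = slope * gridded + intercept`` on the paired series,
    applies it to ``cube`` (if given) and, for precipitation-like
    variables, floors corrected values at 0 (count logged).

    Returns ``(slope, intercept, corrected)`` where ``corrected`` is None
    when no cube is supplied.
    """
    g = np.asarray(gridded_series, dtype=float).ravel()
    s = np.asarray(station_series, dtype=float).ravel()
    ok = np.isfinite(g) & np.isfinite(s)
    g, s = g[ok], s[ok]
    if len(g) < 2:
        raise DataError("need >= 2 paired finite observations")
    if np.ptp(g) == 0:
        raise NumericalError("zero variance in gridded series")
    slope, intercept = np.polyfit(g, s, 1)
    corrected = None
    if cube is not None:
        vals = np.asarray(
            cube.values if isinstance(cube, xr.DataArray) else cube, dtype=float
        )
        corr = slope * vals + intercept
        if floor_zero:
            neg = np.isfinite(corr) & (corr < 0)
            if neg.any():
                log.info("bias correction: floored %d negative values",
                         int(neg.sum()))
            corr = np.where(neg, 0.0, corr)
        if isinstance(cube, xr.DataArray):
            corrected = xr.DataArray(
                corr, dims=cube.dims, coords=cube.coords, name=cube.name
            )
        else:
            corrected = corr
    return float(slope), float(intercept), corrected


# ---------------------------------------------------------------- NetCDF IO

def write_cube(cube: xr.DataArray, path) -> None:
    cube.to_dataset(name=cube.name or "value").to_netcdf(path, engine=NC_ENGINE)


def read_cube(path, var: str | None = None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine=NC_ENGINE).load()
    if var is None:
        var = list(ds.data_vars)[0]
    return ds[var]


def write_dataset(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine=NC_ENGINE)


def read_dataset(path) -> xr.Dataset:
    return xr.open_dataset(path, engine=NC_ENGINE).load()


def write_scene(scene: Scene, path) -> None:
    write_dataset(scene.to_dataset(), path)


def read_scene(path, config: ScenarioConfig | None = None) -> Scene:
    return Scene.from_dataset(read_dataset(path), config=config)


def read_tiff_cube(paths: Sequence[str | Path], years: Sequence[int]) -> xr.DataArray:
    """Stack per-year TIFF layers (plain arrays, no geo-referencing)."""
    import tifffile

    if len(paths) != len(years):
        raise DataError("one TIFF per year required")
    layers = [tifffile.imread(str(p)).astype(float) for p in paths]
    return make_cube(np.stack(layers), years)


# ----------------------------------------------------------------- tables

def write_surveys(surveys: pd.DataFrame, path) -> None:
    surveys.to_csv(path, index=False)


def read_surveys(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------- config

def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["years"] = [int(y) for y in config.years]
    d["type_params"] = {
        int(t): dataclasses.asdict(p) if dataclasses.is_dataclass(p) else dict(p)
        for t, p in config.type_params.items()
    }
    if isinstance(d.get("type_map_spec"), np.ndarray):
        d["type_map_spec"] = d["type_map_spec"].tolist()
    for key in ("driver_trends", "height_response", "cover_response"):
        d[key] = {k: float(v) for k, v in d[key].items()}
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    tp = {int(t): TypeParams(**p) for t, p in d.get("type_params", {}).items()}
    d["type_params"] = tp
    if "years" in d:
        d["years"] = tuple(int(y) for y in d["years"])
    spec = d.get("type_map_spec", "stripes")
    if isinstance(spec, list):
        d["type_map_spec"] = np.asarray(spec, dtype=int)
    return ScenarioConfig(**d)


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def load_config(path) -> ScenarioConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
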