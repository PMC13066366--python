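"""Fractional vegetation cover from NDVI (linear spectral mixture analysis)
or from LAI (Beer-Lambert gap fraction).

The two-endmember linear mixing model treats each pixel's NDVI as a
cover-weighted average of a bare-soil endmember and a full-vegetation
endmember, so cover inverts as

    fvc = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil), clipped to [0, 1].

Endmembers are optimized per grassland type against surveyed cover by an
exhaustive, deterministic grid search minimizing RMSE (ties broken toward
the widest soil-vegetation interval).  The gap-fraction alternative maps
leaf area index through ``fvc = 1 - exp(-k * LAI)`` with extinction
coefficient k (default 0.5, a spherical leaf-angle canopy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import ConfigError, DataError
from .rasters import check_aligned
from .trends import pixelwise_trend_map

log = logging.getLogger(__name__)


@dataclass
class EndmemberSet:
    """Per-type (NDVI_soil, NDVI_veg) pairs with their fit diagnostics."""

    table: pd.DataFrame  # index: type; columns ndvi_soil, ndvi_veg, rmse, n_plots

    def __post_init__(self) -> None:
        bad = self.table[self.table["ndvi_veg"] <= self.table["ndvi_soil"]]
        if len(bad):
            raise ConfigError(
                f"NDVI_veg must exceed NDVI_soil; offending types: "
                f"{list(bad.index)}"
            )

    def soil(self, t: int) -> float:
        return float(self.table.loc[t, "ndvi_soil"])

    def veg(self, t: int) -> float:
        return float(self.table.loc[t, "ndvi_veg"])

    @property
    def types(self) -> list[int]:
        return list(self.table.index)

    @classmethod
    def from_dict(cls, pairs: dict[int, tuple[float, float]]) -> "EndmemberSet":
        df = pd.DataFrame(
            {
                "ndvi_soil": {t: p[0] for t, p in pairs.items()},
                "ndvi_veg": {t: p[1] for t, p in pairs.items()},
                "rmse": np.nan,
                "n_plots": 0,
            }
        )
        df.index.name = "type"
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EndmemberSet":
        return cls(pd.read_csv(path, index_col="type"))


def _per_type_lookup(endmembers: EndmemberSet, type_map: np.ndarray):
    types_present = np.unique(type_map[np.isfinite(type_map.astype(float))])
    missing = set(int(t) for t in types_present) - set(endmembers.types)
    if missing:
        raise ConfigError(f"no endmembers for grassland types {sorted(missing)}")
    max_code = int(type_map.max())
    soil = np.full(max_code + 1, np.nan)
    veg = np.full(max_code + 1, np.nan)
    for t in endmembers.types:
        if t <= max_code:
            soil[t] = endmembers.soil(t)
            veg[t] = endmembers.veg(t)
    return soil[type_map], veg[type_map]


def sma_fvc(
    ndvi: float | np.ndarray | xr.DataArray,
    endmembers: EndmemberSet,
    type_map: np.ndarray | xr.DataArray | int | None = None,
) -> float | np.ndarray | xr.DataArray:
    """Unmix NDVI into fractional cover with per-type endmembers.

    ``type_map`` is a 2-D grid of type codes broadcast against cubes, a
    per-sample vector for tabular NDVI, or a single type code.  Output is
    clipped to [0, 1]; NaN propagates.
    """
    if type_map is None:
        if len(endmembers.types) != 1:
            raise ConfigError("type_map required with multiple endmember types")
        type_map = endmembers.types[0]
    if np.isscalar(type_map):
        s, v = endmembers.soil(int(type_map)), endmembers.veg(int(type_map))
    else:
        tm = np.asarray(
            type_map.values if isinstance(type_map, xr.DataArray) else type_map
        ).astype(int)
        s, v = _per_type_lookup(endmembers, tm)

    is_da = isinstance(ndvi, xr.DataArray)
    x = np.asarray(ndvi.values if is_da else ndvi, dtype=float)
    if x.ndim == 3 and np.ndim(s) == 2:
        s, v = s[None], v[None]
    with np.errstate(invalid="ignore"):
        f = np.clip((x - s) / (v - s), 0.0, 1.0)
    if is_da:
        return xr.DataArray(f, dims=ndvi.dims, coords=ndvi.coords, name="fvc")
    if np.ndim(f) == 0:
        return float(f)
    return f


def gap_fraction_fvc(
    lai: float | np.ndarray | xr.DataArray,
    k: float = 0.5,
    lenient: bool = False,
) -> float | np.ndarray | xr.DataArray:
    """Beer-Lambert gap-fraction cover: ``1 - exp(-k * LAI)``.

    Negative LAI raises unless ``lenient=True``, which clips to 0 and logs.
    """
    if k <= 0:
        raise ConfigError("extinction coefficient k must be positive")
    is_da = isinstance(lai, xr.DataArray)
    x = np.asarray(lai.values if is_da else lai, dtype=float)
    neg = np.isfinite(x) & (x < 0)
    if neg.any():
        if not lenient:
            raise DataError(f"{int(neg.sum())} negative LAI values")
        log.info("gap_fraction_fvc: clipped %d negative LAI values", neg.sum())
        x = np.clip(x, 0.0, None)
    f = 1.0 - np.exp(-k * x)
    if is_da:
        return xr.DataArray(f, dims=lai.dims, coords=lai.coords, name="fvc")
    if np.ndim(f) == 0:
        return float(f)
    return f


def invert_gap_fraction(fvc, k: float = 0.5):
    """Inverse of :func:`gap_fraction_fvc`: LAI = -ln(1 - fvc) / k."""
    return -np.log(1.0 - np.asarray(fvc, dtype=float)) / k


@dataclass
class EndmemberModel:
    """Grid-search endmember optimizer (the "model" is the candidate grid).

    For each grassland type the (soil, veg) pair minimizing the RMSE
    between unmixed and surveyed cover over all plots of that type is
    selected from an exhaustive grid — deterministic and exactly
    reproducible.  Ties go to the widest interval (smallest soil, largest
    veg).
    """

    surveys: pd.DataFrame
    soil_bounds: tuple[float, float] = (0.0, 0.3)
    veg_bounds: tuple[float, float] = (0.5, 1.0)
    step: float = 0.01

    def fit(self) -> EndmemberSet:
        need = {"type", "ndvi", "fvc"}
        if not need <= set(self.surveys.columns):
            raise DataError(f"surveys must have columns {sorted(need)}")
        soils = np.round(
            np.arange(
                self.soil_bounds[0], self.soil_bounds[1] + self.step / 2, self.step
            ),
            10,
        )
        vegs = np.round(
            np.arange(
                self.veg_bounds[0], self.veg_bounds[1] + self.step / 2, self.step
            ),
            10,
        )
        rows = {}
        for t, grp in self.surveys.groupby("type"):
            g = grp[np.isfinite(grp["ndvi"]) & np.isfinite(grp["fvc"])]
            if len(g) < 2:
                log.warning("endmember fit: type %s has <2 plots, skipped", t)
                continue
            ndvi = g["ndvi"].to_numpy()[:, None, None]
            fvc = g["fvc"].to_numpy()[:, None, None]
            s = soils[None, :, None]
            v = vegs[None, None, :]
            pred = np.clip((ndvi - s) / (v - s), 0.0, 1.0)
            rmse = np.sqrt(np.mean((pred - fvc) ** 2, axis=0))
            best = rmse.min()
            if not np.isfinite(best):
                raise DataError(f"endmember fit degenerate for type {t}")
            ties = np.argwhere(rmse <= best + 1e-15)
            # widest interval: largest veg - soil; then smallest soil
            width = vegs[ties[:, 1]] - soils[ties[:, 0]]
            order = np.lexsort((soils[ties[:, 0]], -width))
            si, vi = ties[order[0]]
            rows[int(t)] = {
                "ndvi_soil": soils[si],
                "ndvi_veg": vegs[vi],
                "rmse": best,
                "n_plots": len(g),
            }
        if not rows:
            raise DataError("no type had enough plots for endmember fitting")
        table = pd.DataFrame(rows).T.sort_index()
        table.index.name = "type"
        table["n_plots"] = table["n_plots"].astype(int)
        return EndmemberSet(table)


def optimize_endmembers(
    surveys: pd.DataFrame,
    soil_bounds: tuple[float, float] = (0.0, 0.3),
    veg_bounds: tuple[float, float] = (0.5, 1.0),
    step: float = 0.01,
) -> EndmemberSet:
    """Functional wrapper around :class:`EndmemberModel`."""
    return EndmemberModel(surveys, soil_bounds, veg_bounds, step).fit()


@dataclass
class FvcMethodComparison:
    trend_correlation: float
    mean_trend_difference: float
    trend_a: xr.DataArray
    trend_b: xr.DataArray


def compare_fvc_methods(
    fvc_a: xr.DataArray, fvc_b: xr.DataArray
) -> FvcMethodComparison:
    """Pearson correlation and mean difference of two methods' pixel trends."""
    check_aligned(fvc_a, fvc_b)
    ta = pixelwise_trend_map(fvc_a)["slope"]
    tb = pixelwise_trend_map(fvc_b)["slope"]
    a, b = ta.values, tb.values
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise DataError("fewer than 3 valid pixels for comparison")
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        r = 1.0 if np.allclose(a[ok], b[ok]) else np.nan
    else:
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return FvcMethodComparison(
        trend_correlation=r,
        mean_trend_difference=float(np.mean(a[ok] - b[ok])),
        trend_a=ta,
        trend_b=tb,
    )
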