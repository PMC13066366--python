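"""Canopy height from the biomass/cover ratio.

With biomass decoupled into cover (horizontal) and height (vertical), the
ratio AGB/FVC is the biomass packed per unit of covered ground and scales
with community canopy height.  A per-grassland-type linear quantile
regression of surveyed height (cm) on the surveyed ratio turns gridded
ratios into gridded heights; the quantile tau is a first-class parameter
(default 0.5, the median) and robustness across percentiles is checked by
:func:`percentile_robustness`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .exceptions import ConfigError, DataError, NumericalError
from .rasters import check_aligned
from .trends import national_trend, pixelwise_trend_map

log = logging.getLogger(__name__)


def compute_ratio(
    agb: xr.DataArray, fvc: xr.DataArray, fvc_floor: float = 0.05
) -> xr.DataArray:
    """AGB / FVC where cover is at least ``fvc_floor``; below, nodata.

    The floor prevents the ratio from blowing up in sparsely vegetated
    pixels where cover estimates are least reliable.
    """
    check_aligned(agb, fvc)
    a = np.asarray(agb.values, dtype=float)
    f = np.asarray(fvc.values, dtype=float)
    below = np.isfinite(f) & (f < fvc_floor)
    if below.any():
        log.info("compute_ratio: %d pixel-years below FVC floor %.3g",
                 int(below.sum()), fvc_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(f >= fvc_floor, a / f, np.nan)
    return xr.DataArray(r, dims=agb.dims, coords=agb.coords, name="ratio")


def _survey_ratio(surveys: pd.DataFrame, fvc_floor: float) -> pd.Series:
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = surveys["agb_g_m2"] / surveys["fvc"]
    return ratio.where(surveys["fvc"] >= fvc_floor)


def rank_agreement(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Fraction of concordant pairs between observed and predicted values
    (pairs tied in either variable are skipped)."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    conc = tot = 0
    for i, j in combinations(range(len(o)), 2):
        do, dp = o[i] - o[j], p[i] - p[j]
        if do == 0 or dp == 0:
            continue
        tot += 1
        conc += (do > 0) == (dp > 0)
    return conc / tot if tot else np.nan


@dataclass
class HeightScalerModel:
    """Per-type linear quantile regression of height on the AGB/FVC ratio."""

    surveys: pd.DataFrame
    tau: float = 0.5
    fvc_floor: float = 0.05
    use_mean_fit: bool = False  # OLS instead of quantile regression

    def fit(self) -> "HeightScaler":
        if not (0.0 < self.tau < 1.0):
            raise ConfigError("tau must lie in (0, 1)")
        need = {"type", "agb_g_m2", "fvc", "height_cm"}
        if not need <= set(self.surveys.columns):
            raise DataError(f"surveys must have columns {sorted(need)}")
        df = self.surveys.copy()
        df["ratio"] = _survey_ratio(df, self.fvc_floor)
        rows = {}
        for t, grp in df.groupby("type"):
            g = grp[np.isfinite(grp["ratio"]) & np.isfinite(grp["height_cm"])]
            if len(g) < 3:
                raise DataError(f"type {t}: fewer than 3 usable plots")
            x = g["ratio"].to_numpy()
            y = g["height_cm"].to_numpy()
            if np.ptp(x) == 0:
                raise NumericalError(f"type {t}: degenerate (constant) ratios")
            slope, intercept = self._fit_line(x, y)
            pred = slope * x + intercept
            rows[int(t)] = {
                "slope": slope,
                "intercept": intercept,
                "tau": np.nan if self.use_mean_fit else self.tau,
                "n_plots": len(g),
                "mae": float(np.mean(np.abs(pred - y))),
                "rank_agreement": rank_agreement(y, pred)
                if len(g) <= 2000
                else np.nan,
            }
        table = pd.DataFrame(rows).T.sort_index()
        table.index.name = "type"
        table["n_plots"] = table["n_plots"].astype(int)
        return HeightScaler(table, fvc_floor=self.fvc_floor)

    def _fit_line(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        # perfectly collinear data short-circuits the iterative solver and
        # is exact for every tau
        ols = np.polyfit(x, y, 1)
        if np.allclose(y, np.polyval(ols, x), rtol=0, atol=1e-10):
            return float(ols[0]), float(ols[1])
        X = sm.add_constant(x)
        if self.use_mean_fit:
            res = sm.OLS(y, X).fit()
        else:
            res = sm.QuantReg(y, X).fit(q=self.tau)
        return float(res.params[1]), float(res.params[0])


@dataclass
class HeightScaler:
    """Fitted per-type height scalers: height = slope * ratio + intercept."""

    table: pd.DataFrame  # index type; slope, intercept, tau, n_plots, ...
    fvc_floor: float = 0.05

    @property
    def types(self) -> list[int]:
        return list(self.table.index)

    def predict(self, ratio, type_code: int):
        row = self.table.loc[type_code]
        return np.clip(row["slope"] * np.asarray(ratio, float) + row["intercept"], 0.0, None)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "HeightScaler":
        return cls(pd.read_csv(path, index_col="type"))


def fit_height_scaler(
    surveys: pd.DataFrame, tau: float = 0.5, fvc_floor: float = 0.05
) -> HeightScaler:
    """Functional wrapper around :class:`HeightScalerModel`."""
    return HeightScalerModel(surveys, tau=tau, fvc_floor=fvc_floor).fit()


def height_cube(
    ratio: xr.DataArray,
    scaler: HeightScaler,
    type_map: xr.DataArray | np.ndarray,
) -> xr.DataArray:
    """Apply per-type scalers to a ratio cube; negative heights clip to 0."""
    tm = np.asarray(
        type_map.values if isinstance(type_map, xr.DataArray) else type_map
    ).astype(int)
    present = set(int(t) for t in np.unique(tm))
    missing = present - set(scaler.types)
    if missing:
        raise ConfigError(f"no height scaler for types {sorted(missing)}")
    max_code = int(tm.max())
    slope = np.full(max_code + 1, np.nan)
    inter = np.full(max_code + 1, np.nan)
    for t in scaler.types:
        if t <= max_code:
            slope[t] = scaler.table.loc[t, "slope"]
            inter[t] = scaler.table.loc[t, "intercept"]
    s2, i2 = slope[tm], inter[tm]
    r = np.asarray(ratio.values, dtype=float)
    if r.ndim == 3:
        s2, i2 = s2[None], i2[None]
    h = np.clip(s2 * r + i2, 0.0, None)
    return xr.DataArray(h, dims=ratio.dims, coords=ratio.coords, name="height")


@dataclass
class RobustnessReport:
    """Height-trend agreement across quantile variants."""

    variants: list[str]
    national_trends: dict[str, float]
    sign_agreement: pd.DataFrame   # pairwise fraction of pixels agreeing in sign
    national_sign_agreement: float  # fraction of variant pairs with same sign
    flagged: list[str] = field(default_factory=list)


def percentile_robustness(
    surveys: pd.DataFrame,
    ratio: xr.DataArray,
    type_map,
    taus=(0.25, 0.5, 0.75),
    include_mean_fit: bool = True,
    fvc_floor: float = 0.05,
) -> RobustnessReport:
    """Refit the height scaler at several quantiles (and optionally an OLS
    mean fit), rebuild the height cube and compare the resulting trends.

    Variants whose fitted slopes are all ~0 cannot order heights and are
    flagged.
    """
    variants: dict[str, HeightScaler] = {}
    for tau in taus:
        key = f"tau={tau:g}"
        while key in variants:
            key += "'"
        variants[key] = HeightScalerModel(
            surveys, tau=tau, fvc_floor=fvc_floor
        ).fit()
    if include_mean_fit:
        variants["mean-fit"] = HeightScalerModel(
            surveys, fvc_floor=fvc_floor, use_mean_fit=True
        ).fit()
    if len(variants) < 2:
        raise ConfigError("need at least 2 variants")

    names = list(variants)
    trends: dict[str, xr.Dataset] = {}
    national: dict[str, float] = {}
    flagged = []
    for name, sc in variants.items():
        cube = height_cube(ratio, sc, type_map)
        trends[name] = pixelwise_trend_map(cube)
        national[name] = national_trend(cube).slope
        if np.allclose(sc.table["slope"].to_numpy(), 0.0):
            flagged.append(name)

    agree = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pair_signs = []
    for a, b in combinations(names, 2):
        sa = np.sign(trends[a]["slope"].values)
        sb = np.sign(trends[b]["slope"].values)
        ok = np.isfinite(sa) & np.isfinite(sb)
        frac = float(np.mean(sa[ok] == sb[ok])) if ok.any() else np.nan
        agree.loc[a, b] = agree.loc[b, a] = frac
        pair_signs.append(np.sign(national[a]) == np.sign(national[b]))
    return RobustnessReport(
        variants=names,
        national_trends=national,
        sign_agreement=agree,
        national_sign_agreement=float(np.mean(pair_signs)),
        flagged=flagged,
    )
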