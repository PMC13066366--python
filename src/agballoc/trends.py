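"""Linear trend estimation, significance and the printed-statistic identities.

Trends throughout the pipeline are ordinary least squares of a variable on
calendar year.  For a simple regression on ``n`` points the residual
degrees of freedom are ``df = n - 2`` and the familiar closed-form
identities connect the t statistic to everything else that gets reported
next to it:

* two-sided p:     ``p = 2 * (1 - F_t(|t|; df))``
* coefficient of determination: ``R^2 = t^2 / (t^2 + df)``
* Pearson correlation: ``r = t / sqrt(t^2 + df)`` (sign of t)
* slope CI:        ``b +/- t_{(1+level)/2, df} * (b / t)``

Significance is assessed with a two-sided t test and no multiple-testing
adjustment is applied on trend maps by default (a BH-FDR flag exists for
users who want one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import xarray as xr
from scipy import stats

from .exceptions import AlignmentError, DataError, NumericalError
from .rasters import check_aligned, years_of


def t_to_p(t: float | np.ndarray, df: float) -> float | np.ndarray:
    """Two-sided p value of a t statistic."""
    if np.any(np.asarray(df) < 1):
        raise DataError("df must be >= 1")
    return 2.0 * stats.t.sf(np.abs(t), df)


def t_to_r2(t: float | np.ndarray, df: float) -> float | np.ndarray:
    """Simple-regression identity R^2 = t^2 / (t^2 + df)."""
    if np.any(np.asarray(df) < 1):
        raise DataError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    out = t**2 / (t**2 + df)
    return float(out) if out.ndim == 0 else out


def t_to_r(t: float | np.ndarray, df: float) -> float | np.ndarray:
    """Pearson correlation implied by a simple-regression t statistic."""
    if np.any(np.asarray(df) < 1):
        raise DataError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    out = t / np.sqrt(t**2 + df)
    return float(out) if out.ndim == 0 else out


def slope_ci(
    b: float, t: float, df: float, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval of a slope recovered from its printed b and t.

    The standard error is ``b / t``, so ``t`` must be nonzero.
    """
    if df < 1:
        raise DataError("df must be >= 1")
    if t == 0:
        raise NumericalError("t = 0: standard error undefined from (b, t)")
    se = abs(b / t)
    q = stats.t.ppf(0.5 * (1.0 + level), df)
    return (b - q * se, b + q * se)


@dataclass
class TrendFit:
    slope: float
    t: float
    p: float
    r2: float
    n: int
    intercept: float
    se: float

    @property
    def df(self) -> int:
        return self.n - 2

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = stats.t.ppf(0.5 * (1.0 + level), self.df)
        return (self.slope - q * self.se, self.slope + q * self.se)


def fit_trend(values: Sequence[float], years: Sequence[float] | None = None) -> TrendFit:
    """OLS trend of ``values`` on ``years`` with t, two-sided p and R^2.

    A constant series has slope 0, t 0, p 1 and R^2 0 by convention.
    """
    y = np.asarray(values, dtype=float)
    x = (
        np.arange(len(y), dtype=float)
        if years is None
        else np.asarray(years, dtype=float)
    )
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise DataError("trend fit needs >= 3 finite values")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise DataError("zero variance in the year axis")
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = max(syy - slope * sxy, 0.0)
    df = n - 2
    if syy == 0.0:
        return TrendFit(0.0, 0.0, 1.0, 0.0, n, ym, 0.0)
    se = np.sqrt(ss_res / df / sxx) if ss_res > 0 else 0.0
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    p = float(t_to_p(t, df)) if np.isfinite(t) else 0.0
    r2 = 1.0 - ss_res / syy
    return TrendFit(slope, float(t), p, r2, n, intercept, se)


def pixelwise_trend_map(cube: xr.DataArray, fdr: bool = False) -> xr.Dataset:
    """Per-pixel OLS trend on year: slope, t, two-sided p and R^2 maps.

    Pixels with fewer than 3 finite years are nodata.  No multiple-testing
    adjustment by default; ``fdr=True`` adds a Benjamini-Hochberg adjusted
    ``p_fdr`` variable.
    """
    years = years_of(cube).astype(float)
    y = np.asarray(cube.values, dtype=float)
    if y.shape[0] < 3:
        raise DataError("trend map needs >= 3 years")
    valid = np.isfinite(y)
    n = valid.sum(axis=0).astype(float)
    x = years[:, None, None] * np.ones_like(y)
    yz = np.where(valid, y, 0.0)
    xz = np.where(valid, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = xz.sum(0) / n
        ym = yz.sum(0) / n
        sxx = np.where(valid, (x - xm) ** 2, 0.0).sum(0)
        sxy = np.where(valid, (x - xm) * (y - ym), 0.0).sum(0)
        syy = np.where(valid, (y - ym) ** 2, 0.0).sum(0)
        slope = sxy / sxx
        ss_res = np.clip(syy - slope * sxy, 0.0, None)
        df = n - 2
        se = np.sqrt(ss_res / df / sxx)
        t = slope / se
        r2 = 1.0 - ss_res / syy

    const = syy == 0.0
    slope = np.where(const, 0.0, slope)
    t = np.where(const, 0.0, t)
    r2 = np.where(const, 0.0, r2)
    bad = (n < 3) | (sxx == 0)
    for arr in (slope, t, r2):
        arr[bad] = np.nan
    p = np.full_like(slope, np.nan)
    fin = np.isfinite(t)
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df[fin])
    p[np.isinf(t)] = 0.0

    ds = xr.Dataset(
        {
            "slope": (("row", "col"), slope),
            "t": (("row", "col"), t),
            "p": (("row", "col"), p),
            "r2": (("row", "col"), r2),
            "n": (("row", "col"), np.where(bad, np.nan, n)),
        }
    )
    ds.attrs["n_years"] = int(y.shape[0])
    if fdr:
        ds["p_fdr"] = (("row", "col"), _bh_adjust(p))
    return ds


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    flat = p[np.isfinite(p)]
    if flat.size == 0:
        return out
    order = np.argsort(flat)
    m = flat.size
    adj = flat[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.clip(adj, 0, 1)
    out[np.isfinite(p)] = res
    return out


def trend_correlation_map(
    cube_a: xr.DataArray, cube_b: xr.DataArray
) -> tuple[TrendFit, xr.DataArray]:
    """Coupling between two variables' changes.

    Returns the global Pearson correlation (as a :class:`TrendFit`-style
    record via the regression of b-slopes on a-slopes is *not* used —
    the correlation r with its t and df over pixel slope pairs) and the
    per-pixel R^2 between the two interannual series.
    """
    check_aligned(cube_a, cube_b)
    ta = pixelwise_trend_map(cube_a)["slope"].values
    tb = pixelwise_trend_map(cube_b)["slope"].values
    ok = np.isfinite(ta) & np.isfinite(tb)
    if ok.sum() < 3:
        raise DataError("fewer than 3 valid pixel pairs")
    r, _ = stats.pearsonr(ta[ok], tb[ok])
    df = int(ok.sum()) - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    global_fit = TrendFit(
        slope=float(r), t=float(t), p=float(t_to_p(t, df)),
        r2=float(r**2), n=int(ok.sum()), intercept=np.nan, se=np.nan,
    )

    a = np.asarray(cube_a.values, dtype=float)
    b = np.asarray(cube_b.values, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        am = np.nanmean(a, axis=0)
        bm = np.nanmean(b, axis=0)
        cov = np.nanmean((a - am) * (b - bm), axis=0)
        va = np.nanvar(a, axis=0)
        vb = np.nanvar(b, axis=0)
        r2_map = cov**2 / (va * vb)
    r2_map = np.where(np.isfinite(r2_map), r2_map, np.nan)
    return global_fit, xr.DataArray(r2_map, dims=("row", "col"), name="r2")


def area_fraction(
    trendmap: xr.Dataset,
    predicate: Callable[[xr.Dataset], np.ndarray] | str = "slope>0",
    alpha: float | None = None,
) -> float:
    """Fraction of valid pixels satisfying a predicate, equal-area weighted.

    ``predicate`` may be a callable on the trend dataset or one of the
    strings ``"slope>0"`` / ``"slope<0"``; pass ``alpha`` to additionally
    require two-sided significance ``p < alpha``.
    """
    slope = trendmap["slope"].values
    valid = np.isfinite(slope)
    if not valid.any():
        raise DataError("trend map has no valid pixels")
    if callable(predicate):
        mask = np.asarray(predicate(trendmap), dtype=bool)
    elif predicate == "slope>0":
        mask = slope > 0
    elif predicate == "slope<0":
        mask = slope < 0
    else:
        raise DataError(f"unknown predicate {predicate!r}")
    if alpha is not None:
        mask = mask & (trendmap["p"].values < alpha)
    return float(np.sum(mask & valid) / np.sum(valid))


def national_mean_series(cube: xr.DataArray) -> np.ndarray:
    """Spatial mean per year over valid pixels (the regional aggregate)."""
    return np.nanmean(np.asarray(cube.values, dtype=float), axis=(1, 2))


def national_trend(cube: xr.DataArray) -> TrendFit:
    """Trend of the spatial-mean interannual series."""
    return fit_trend(national_mean_series(cube), years_of(cube))
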