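"""Diversity responses of the canopy-height trend and tipping points.

Per-pixel height trends are binned along a diversity axis (plot species
richness in unit-width integer bins, or foliage height diversity in 25
equal-width bins), a line is fitted through the bin means, and the
tipping point is the diversity value where the fitted trend crosses zero
— below it the canopy is declining.  Correlation is reported at the bin
level (matching the small degrees of freedom such binned analyses print);
the pixel-level correlation is available as a secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, NumericalError
from .trends import t_to_p


@dataclass
class BinnedResponse:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_mean: np.ndarray
    bin_se: np.ndarray
    bin_n: np.ndarray
    slope: float
    intercept: float
    r: float
    t: float
    df: int
    p: float
    pixel_r: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.bin_edges)))

    def plot(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.bin_centers, self.bin_mean, yerr=self.bin_se,
                    fmt="o", capsize=2)
        xs = np.linspace(self.bin_centers.min(), self.bin_centers.max(), 50)
        ax.plot(xs, self.slope * xs + self.intercept, "-")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("diversity")
        ax.set_ylabel("height trend (cm y$^{-1}$)")
        return ax


def bin_and_fit(
    height_trend: np.ndarray,
    diversity: np.ndarray,
    n_bins: int = 25,
    integer_bins: bool = False,
) -> BinnedResponse:
    """Bin per-pixel height trends by diversity and fit a line to the
    bin means.

    ``integer_bins=True`` uses unit-width bins centered on integers (for
    species richness counts); otherwise ``n_bins`` equal-width bins span
    the observed diversity range.  Needs at least 3 non-empty bins.
    """
    ht = np.asarray(height_trend, dtype=float).ravel()
    dv = np.asarray(diversity, dtype=float).ravel()
    ok = np.isfinite(ht) & np.isfinite(dv)
    ht, dv = ht[ok], dv[ok]
    if len(ht) < 3:
        raise DataError("fewer than 3 valid pixels")
    if integer_bins:
        lo, hi = int(np.floor(dv.min())), int(np.ceil(dv.max()))
        edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    else:
        edges = np.linspace(dv.min(), dv.max(), n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.digitize(dv, edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)

    centers, means, ses, ns = [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = ht[sel]
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(vals.mean())
        ses.append(vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0)
        ns.append(n)
    if len(centers) < 3:
        raise DataError(f"only {len(centers)} non-empty bins (need >= 3)")
    centers = np.asarray(centers)
    means = np.asarray(means)

    x = centers - centers.mean()
    sxx = float(np.sum(x**2))
    slope = float(np.sum(x * (means - means.mean())) / sxx)
    intercept = float(means.mean() - slope * centers.mean())
    if means.std(ddof=0) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(centers, means)[0, 1])
    df = len(centers) - 2
    denom = max(1.0 - r**2, 1e-300)
    t = r * np.sqrt(df / denom)
    pixel_r = (
        float(np.corrcoef(dv, ht)[0, 1]) if ht.std() > 0 and dv.std() > 0 else np.nan
    )
    return BinnedResponse(
        bin_edges=edges,
        bin_centers=centers,
        bin_mean=means,
        bin_se=np.asarray(ses),
        bin_n=np.asarray(ns, dtype=int),
        slope=slope,
        intercept=intercept,
        r=r,
        t=float(t),
        df=df,
        p=float(t_to_p(t, df)) if df >= 1 else np.nan,
        pixel_r=pixel_r,
    )


def tipping_point(fit: BinnedResponse) -> float | None:
    """Diversity value where the fitted trend line crosses zero.

    Returns ``-intercept / slope`` if it falls inside the observed
    diversity range, else ``None`` (also for a flat fitted line).
    """
    if fit.slope == 0.0:
        return None
    x0 = -fit.intercept / fit.slope
    lo, hi = float(fit.bin_edges[0]), float(fit.bin_edges[-1])
    if lo <= x0 <= hi:
        return float(x0)
    return None
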