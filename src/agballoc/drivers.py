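"""Driver attribution of height and cover changes.

Per-pixel trends of canopy height (CH), cover (FVC) and biomass (AGB) are
regressed on z-scored trends of five drivers — solar radiation (Ra),
precipitation (Pr), air temperature (Ta), CO2 (Ca) and grazing pressure
(Gp) — in two complementary ways:

* a piecewise structural equation model: each endogenous node of a DAG is
  fitted by its own linear regression on its parents, giving standardized
  path coefficients; pixels are stratified by the sign of the height
  trend (increasing vs decreasing canopy);
* linear mixed-effects models with pairwise driver interactions (e.g.
  Ta x Gp) and a random intercept by grassland type.

The default DAG sends all five drivers into both CH and FVC and closes
with AGB <- {CH, FVC}, the decoupling premise; it is configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
import xarray as xr

from .exceptions import ConfigError, DataError, NumericalError
from .scene import DRIVERS

log = logging.getLogger(__name__)

RESPONSES = ("CH", "FVC", "AGB")


def default_dag() -> dict[str, tuple[str, ...]]:
    return {
        "CH": tuple(DRIVERS),
        "FVC": tuple(DRIVERS),
        "AGB": ("CH", "FVC"),
    }


@dataclass
class TrendDesign:
    """One row per valid pixel: response and z-scored explanatory trends."""

    frame: pd.DataFrame           # columns: RESPONSES, DRIVERS, type, stratum
    standardized_responses: bool = True
    n_zero_trend_excluded: int = 0

    def stratum(self, label: str) -> "TrendDesign":
        sub = self.frame[self.frame["stratum"] == label]
        if sub.empty:
            raise DataError(f"stratum {label!r} is empty")
        return TrendDesign(sub.reset_index(drop=True),
                           self.standardized_responses, 0)

    @property
    def strata(self) -> list[str]:
        return sorted(self.frame["stratum"].unique())

    def __len__(self) -> int:
        return len(self.frame)


def _slope_values(obj) -> np.ndarray:
    if isinstance(obj, xr.Dataset):
        return np.asarray(obj["slope"].values, dtype=float)
    if isinstance(obj, xr.DataArray):
        return np.asarray(obj.values, dtype=float)
    return np.asarray(obj, dtype=float)


def build_trend_design(
    response_trends: Mapping[str, object],
    driver_trends: Mapping[str, object],
    type_map=None,
    standardize_responses: bool = True,
) -> TrendDesign:
    """Assemble the pixel-trend regression table.

    ``response_trends`` maps CH/FVC/AGB to trend maps (Datasets from
    :func:`agballoc.trends.pixelwise_trend_map`, slope DataArrays or
    arrays); ``driver_trends`` likewise for Ra/Pr/Ta/Ca/Gp.  Explanatory
    columns (and, by default, responses) are z-scored over the full
    analysis set; pixels are stratified into ``"increasing"`` /
    ``"decreasing"`` by the sign of the raw CH trend, with exact-zero
    trend pixels excluded (count logged and recorded).
    """
    if "CH" not in response_trends:
        raise ConfigError("response_trends must include 'CH'")
    cols: dict[str, np.ndarray] = {}
    shape = None
    for name, obj in list(response_trends.items()) + list(driver_trends.items()):
        arr = _slope_values(obj)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise DataError(f"trend map {name!r} shape {arr.shape} != {shape}")
        cols[name] = arr.ravel()
    valid = np.logical_and.reduce([np.isfinite(v) for v in cols.values()])
    ch_raw = cols["CH"]
    zero = valid & (ch_raw == 0.0)
    n_zero = int(zero.sum())
    if n_zero:
        log.info("build_trend_design: excluded %d zero-CH-trend pixels", n_zero)
    valid = valid & ~zero
    if valid.sum() < 3:
        raise DataError("fewer than 3 valid pixels in the design")

    frame = pd.DataFrame({k: v[valid] for k, v in cols.items()})
    frame["stratum"] = np.where(frame["CH"] > 0, "increasing", "decreasing")
    if type_map is not None:
        tm = np.asarray(
            type_map.values if isinstance(type_map, xr.DataArray) else type_map
        ).ravel()
        frame["type"] = tm[valid].astype(int)
    else:
        frame["type"] = 0

    for d in driver_trends:
        frame[d] = _zscore(frame[d].to_numpy(), d)
    if standardize_responses:
        for r in response_trends:
            frame[r] = _zscore(frame[r].to_numpy(), r)
    return TrendDesign(frame, standardize_responses, n_zero)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise NumericalError(f"column {name!r} has zero variance")
    return (x - x.mean()) / sd


def _check_acyclic(dag: Mapping[str, Sequence[str]]) -> None:
    state: dict[str, int] = {}

    def visit(node):
        if state.get(node) == 1:
            raise ConfigError(f"DAG is cyclic at node {node!r}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for parent in dag.get(node, ()):
            visit(parent)
        state[node] = 2

    for n in dag:
        visit(n)


@dataclass
class PathModelResults:
    """Standardized path coefficients of a fitted piecewise SEM."""

    edges: pd.DataFrame      # response, predictor, beta, se, p
    r2: dict[str, float]
    n: int
    stratum: str = "all"

    def coef(self, response: str, predictor: str) -> float:
        m = self.edges[
            (self.edges["response"] == response)
            & (self.edges["predictor"] == predictor)
        ]
        if m.empty:
            raise KeyError(f"no edge {predictor} -> {response}")
        return float(m["beta"].iloc[0])

    def summary(self) -> pd.DataFrame:
        out = self.edges.copy()
        out["signif"] = np.where(out["p"] < 0.05, "*", "")
        out.attrs["r2"] = self.r2
        out.attrs["n"] = self.n
        return out


class PiecewiseSEM:
    """Piecewise structural equation model on a pixel-trend design.

    Each endogenous variable is modeled by a separate OLS regression on
    its DAG parents; with z-scored variables the coefficients are
    standardized path coefficients.  A saturated DAG with one response
    reduces exactly to that response's multiple regression.
    """

    def __init__(
        self,
        design: TrendDesign,
        dag: Mapping[str, Sequence[str]] | None = None,
    ):
        self.design = design
        self.dag = dict(dag) if dag is not None else default_dag()
        _check_acyclic(self.dag)
        nodes = set(self.dag) | {p for ps in self.dag.values() for p in ps}
        missing = nodes - set(design.frame.columns)
        if missing:
            raise ConfigError(f"DAG nodes absent from design: {sorted(missing)}")

    def fit(self) -> PathModelResults:
        df = self.design.frame
        rows = []
        r2 = {}
        for response, parents in self.dag.items():
            X = df[list(parents)].to_numpy(dtype=float)
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
            if rank < X.shape[1] + 1:
                raise NumericalError(
                    f"rank-deficient design for {response}; collinear "
                    f"columns among {list(parents)}"
                )
            res = sm.OLS(df[response].to_numpy(dtype=float),
                         sm.add_constant(X)).fit()
            r2[response] = float(res.rsquared)
            for j, p_name in enumerate(parents):
                rows.append(
                    {
                        "response": response,
                        "predictor": p_name,
                        "beta": float(res.params[j + 1]),
                        "se": float(res.bse[j + 1]),
                        "p": float(res.pvalues[j + 1]),
                    }
                )
        stratum = (
            df["stratum"].iloc[0] if df["stratum"].nunique() == 1 else "all"
        )
        return PathModelResults(pd.DataFrame(rows), r2, len(df), stratum)


def fit_stratified_sem(
    design: TrendDesign, dag: Mapping[str, Sequence[str]] | None = None
) -> dict[str, PathModelResults]:
    """Fit the piecewise SEM separately in the increasing- and
    decreasing-canopy-height strata."""
    out = {}
    for s in design.strata:
        out[s] = PiecewiseSEM(design.stratum(s), dag).fit()
    return out


def lmm_interactions(
    design: TrendDesign,
    pairs: Sequence[tuple[str, str]] = (("Ta", "Gp"),),
    response: str = "CH",
    group: str = "type",
) -> pd.DataFrame:
    """Mixed model of a response trend on driver trends and interactions.

    Fixed effects: all five driver main terms plus the requested pairwise
    products; random intercept by ``group`` (grassland type).  A single
    group degrades to OLS with a logged notice.  Returns the fixed-effect
    table (coef, se, p).
    """
    df = design.frame.copy()
    terms = list(DRIVERS)
    for a, b in pairs:
        for v in (a, b):
            if v not in df.columns:
                raise ConfigError(f"interaction variable {v!r} not in design")
        name = f"{a}_x_{b}"
        df[name] = df[a] * df[b]
        terms.append(name)
    formula = f"{response} ~ " + " + ".join(terms)
    n_groups = df[group].nunique()
    if n_groups < 2:
        log.info("lmm_interactions: single group, degrading to OLS")
        res = smf.ols(formula, data=df).fit()
        table = pd.DataFrame(
            {"coef": res.params, "se": res.bse, "p": res.pvalues}
        )
        table.attrs["model"] = "ols"
        return table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, data=df, groups=df[group]).fit(reml=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise NumericalError(
                "singular mixed-model fit; drop an interaction or merge groups"
            ) from e
    fe = res.fe_params
    table = pd.DataFrame(
        {
            "coef": fe,
            "se": res.bse_fe.loc[fe.index],
            "p": res.pvalues.loc[fe.index],
        }
    )
    table.attrs["model"] = "mixedlm"
    table.attrs["group_var"] = float(res.cov_re.iloc[0, 0])
    return table
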