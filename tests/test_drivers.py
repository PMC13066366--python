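"""Trend design assembly, piecewise SEM and interaction mixed models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from agballoc.drivers import (
    PiecewiseSEM,
    TrendDesign,
    build_trend_design,
    default_dag,
    fit_stratified_sem,
    lmm_interactions,
)
from agballoc.exceptions import ConfigError, DataError, NumericalError
from agballoc.scene import DRIVERS

BETA = {"Ra": 0.3, "Pr": 0.2, "Ta": -0.4, "Ca": 0.1, "Gp": -0.3}


def _make_design(n=2000, noise=0.0, seed=0, types=1):
    rng = np.random.default_rng(seed)
    X = {d: rng.normal(size=n) for d in DRIVERS}
    ch = sum(BETA[d] * X[d] for d in DRIVERS) + noise * rng.normal(size=n)
    fvc = 0.5 * X["Pr"] + 0.3 * X["Ca"] + noise * rng.normal(size=n)
    agb = 0.6 * ch + 0.7 * fvc + noise * rng.normal(size=n)
    resp = {"CH": ch, "FVC": fvc, "AGB": agb}
    return build_trend_design(
        resp, X, type_map=rng.integers(0, types, n) if types > 1 else None
    )


class TestBuildDesign:
    def test_zscore_contract(self):
        d = _make_design(500, noise=0.3)
        for col in DRIVERS:
            assert abs(d.frame[col].mean()) < 1e-10
            assert abs(d.frame[col].std(ddof=0) - 1) < 1e-10

    def test_strata_partition_by_height_sign(self):
        d = _make_design(500, noise=0.3, seed=1)
        inc = d.frame[d.frame["stratum"] == "increasing"]
        dec = d.frame[d.frame["stratum"] == "decreasing"]
        assert len(inc) + len(dec) == len(d.frame)

    def test_all_positive_leaves_decreasing_empty(self):
        rng = np.random.default_rng(2)
        X = {d: rng.normal(size=100) for d in DRIVERS}
        resp = {"CH": np.abs(rng.normal(size=100)) + 0.1}
        d = build_trend_design(resp, X)
        assert d.strata == ["increasing"]
        with pytest.raises(DataError):
            d.stratum("decreasing")

    def test_zero_trend_pixels_excluded(self):
        rng = np.random.default_rng(3)
        X = {d: rng.normal(size=50) for d in DRIVERS}
        ch = rng.normal(size=50)
        ch[:7] = 0.0
        d = build_trend_design({"CH": ch}, X)
        assert d.n_zero_trend_excluded == 7
        assert len(d) == 43

    def test_known_sign_regions_give_matching_strata_sizes(self):
        """Constructed +/- height-trend regions are partitioned exactly."""
        ch = np.r_[np.full(30, 0.5), np.full(70, -0.5)]
        rng = np.random.default_rng(4)
        X = {d: rng.normal(size=100) for d in DRIVERS}
        d = build_trend_design({"CH": ch}, X)
        assert len(d.stratum("increasing")) == 30
        assert len(d.stratum("decreasing")) == 70

    def test_shape_mismatch_rejected(self):
        X = {d: np.zeros(10) for d in DRIVERS}
        with pytest.raises(DataError):
            build_trend_design({"CH": np.ones(11)}, X)


class TestPiecewiseSEM:
    def test_noise_free_machine_precision_recovery(self):
        d = _make_design(1000, noise=0.0)
        res = PiecewiseSEM(d, dag={"CH": tuple(DRIVERS)}).fit()
        for drv, beta in BETA.items():
            # responses are z-scored, so compare standardized truth
            expect = beta / d.frame.attrs.get("ch_sd", 1.0)
            assert np.sign(res.coef("CH", drv)) == np.sign(expect)
        # refit without response standardization: exact coefficients
        rng = np.random.default_rng(0)
        X = {drv: rng.normal(size=1000) for drv in DRIVERS}
        ch = sum(BETA[drv] * X[drv] for drv in DRIVERS)
        d2 = build_trend_design({"CH": ch}, X, standardize_responses=False)
        res2 = PiecewiseSEM(d2, dag={"CH": tuple(DRIVERS)}).fit()
        for drv, beta in BETA.items():
            # recovered coefficient is beta times the driver's own SD
            sd = X[drv][np.isfinite(ch) & (ch != 0)].std(ddof=0)
            assert res2.coef("CH", drv) == pytest.approx(beta * sd, rel=1e-9)
        assert res2.r2["CH"] == pytest.approx(1.0)

    def test_standardization_invariance_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        X = {d: rng.normal(size=800) for d in DRIVERS}
        ch = sum(BETA[d] * X[d] for d in DRIVERS) + 0.2 * rng.normal(size=800)
        d1 = build_trend_design({"CH": ch}, X)
        X2 = {d: 10.0 * v + 3.0 for d, v in X.items()}
        d2 = build_trend_design({"CH": ch}, X2)
        r1 = PiecewiseSEM(d1, dag={"CH": tuple(DRIVERS)}).fit()
        r2 = PiecewiseSEM(d2, dag={"CH": tuple(DRIVERS)}).fit()
        for drv in DRIVERS:
            assert r1.coef("CH", drv) == pytest.approx(r2.coef("CH", drv),
                                                       rel=1e-9)

    def test_saturated_single_response_equals_multiple_regression(self):
        d = _make_design(600, noise=0.4, seed=6)
        res = PiecewiseSEM(d, dag={"CH": tuple(DRIVERS)}).fit()
        X = sm.add_constant(d.frame[list(DRIVERS)].to_numpy())
        ols = sm.OLS(d.frame["CH"].to_numpy(), X).fit()
        for j, drv in enumerate(DRIVERS):
            assert res.coef("CH", drv) == pytest.approx(ols.params[j + 1],
                                                        rel=1e-10)

    def test_default_dag_closure_edges(self):
        d = _make_design(600, noise=0.4, seed=7)
        res = PiecewiseSEM(d, default_dag()).fit()
        assert res.coef("AGB", "CH") > 0
        assert res.coef("AGB", "FVC") > 0
        assert set(res.r2) == {"CH", "FVC", "AGB"}

    def test_cyclic_dag_rejected(self):
        d = _make_design(100, noise=0.4, seed=8)
        with pytest.raises(ConfigError):
            PiecewiseSEM(d, dag={"CH": ("FVC",), "FVC": ("CH",)})

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(9)
        X = {d: rng.normal(size=200) for d in DRIVERS}
        X["Pr"] = X["Ra"].copy()  # perfectly collinear after z-scoring
        ch = X["Ra"] + 0.1 * rng.normal(size=200)
        d = build_trend_design({"CH": ch}, X)
        with pytest.raises(NumericalError):
            PiecewiseSEM(d, dag={"CH": ("Ra", "Pr")}).fit()

    def test_identically_generated_strata_agree(self):
        """Two strata drawn from one process give equal paths within
        Monte-Carlo error."""
        rng = np.random.default_rng(10)
        n = 4000
        X = {d: rng.normal(size=n) for d in DRIVERS}
        ch = sum(BETA[d] * X[d] for d in DRIVERS) + 0.3 * rng.normal(size=n)
        d = build_trend_design({"CH": ch}, X)
        out = fit_stratified_sem(d, dag={"CH": tuple(DRIVERS)})
        for drv in DRIVERS:
            a = out["increasing"].coef("CH", drv)
            b = out["decreasing"].coef("CH", drv)
            se = max(
                out["increasing"].edges["se"].max(),
                out["decreasing"].edges["se"].max(),
            )
            assert abs(a - b) < 6 * se + 0.05


class TestLMM:
    def _interaction_frame(self, n, gamma, seed, groups=6, noise=0.3):
        rng = np.random.default_rng(seed)
        X = {d: rng.normal(size=n) for d in DRIVERS}
        g = rng.integers(0, groups, n)
        intercepts = rng.normal(scale=0.3, size=groups)
        ch = (
            sum(BETA[d] * X[d] for d in DRIVERS)
            + gamma * X["Ta"] * X["Gp"]
            + intercepts[g]
            + noise * rng.normal(size=n)
        )
        d = build_trend_design({"CH": ch}, X, type_map=g,
                               standardize_responses=False)
        return d

    def test_single_group_degrades_to_ols(self):
        d = _make_design(400, noise=0.3, seed=11)
        table = lmm_interactions(d, pairs=(), response="CH")
        assert table.attrs["model"] == "ols"
        X = sm.add_constant(d.frame[list(DRIVERS)].to_numpy())
        ols = sm.OLS(d.frame["CH"].to_numpy(), X).fit()
        for j, drv in enumerate(DRIVERS):
            assert table.loc[drv, "coef"] == pytest.approx(ols.params[j + 1],
                                                           rel=1e-8)

    def test_interaction_coefficient_recovered(self):
        d = self._interaction_frame(10_000, gamma=-0.2, seed=12)
        table = lmm_interactions(d, pairs=(("Ta", "Gp"),), response="CH")
        assert table.attrs["model"] == "mixedlm"
        assert table.loc["Ta_x_Gp", "coef"] == pytest.approx(-0.2, abs=0.05)

    def test_null_interaction_type_one_control(self):
        hits = 0
        for seed in range(20):
            d = self._interaction_frame(1500, gamma=0.0, seed=100 + seed)
            t = lmm_interactions(d, pairs=(("Ta", "Gp"),), response="CH")
            if abs(t.loc["Ta_x_Gp", "coef"]) < 2 * t.loc["Ta_x_Gp", "se"]:
                hits += 1
        assert hits >= 18

    def test_unknown_interaction_variable_rejected(self):
        d = _make_design(100, noise=0.3, seed=13)
        with pytest.raises(ConfigError):
            lmm_interactions(d, pairs=(("Ta", "Qq"),))
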