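"""Random-forest ensemble training, oversampling, BMA and gridded
prediction."""

import numpy as np
import pandas as pd
import pytest

import agballoc as ab
from agballoc.agb import (
    AGBEnsembleModel,
    ForcingEnsemble,
    ForcingFit,
    bma_weights,
    ensemble_mean_and_sd,
    oversample_minority,
    scene_feature_cubes,
    split_holdout_folds,
)
from agballoc.exceptions import ConfigError, DataError
from agballoc.rasters import make_cube
from agballoc.scene import ScenarioConfig, TypeParams, generate_scene, sample_surveys

ALL_FEATURES = (
    ["ndvi_mean", "ndvi_anom", "lai_mean", "lai_anom"]
    + [f"{d}_{p}" for d in ab.DRIVERS for p in ("mean", "anom")]
    + ["type"]
)


def _feature_table(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f: rng.uniform(0, 1, n) for f in ALL_FEATURES[:-1]})
    df["type"] = rng.integers(1, 4, n).astype(float)
    return df


class TestPartition:
    def test_stated_fraction_arithmetic(self):
        part = split_holdout_folds(100, seed=0)
        assert len(part.holdout) == 10
        assert sorted(len(f) for f in part.folds) == [18] * 5

    def test_same_seed_identical(self):
        a = split_holdout_folds(57, seed=4)
        b = split_holdout_folds(57, seed=4)
        assert np.array_equal(a.holdout, b.holdout)
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa, fb)

    def test_partition_law(self):
        part = split_holdout_folds(83, seed=1)
        everything = np.concatenate([part.holdout] + part.folds)
        assert sorted(everything) == list(range(83))

    def test_too_few_records(self):
        with pytest.raises(DataError):
            split_holdout_folds(5, n_folds=5)


class TestOversampling:
    def _table(self, low, high):
        return pd.DataFrame({"agb_g_m2": np.r_[np.full(low, 10.0),
                                               np.full(high, 100.0)]})

    def test_balancing_contract(self):
        out = oversample_minority(self._table(90, 10), quantile_cut=0.75, seed=0)
        assert len(out) == 180
        assert (out["agb_g_m2"] > 10).sum() == 90

    def test_already_balanced_unchanged(self):
        df = self._table(10, 10)
        out = oversample_minority(df, quantile_cut=0.5, seed=0)
        assert len(out) == len(df)

    def test_constant_target_returned_unchanged(self):
        df = pd.DataFrame({"agb_g_m2": np.full(20, 5.0)})
        out = oversample_minority(df, seed=0)
        assert out is df

    def test_mean_increases_when_high_tail_duplicated(self):
        df = pd.DataFrame({"agb_g_m2": np.arange(20, dtype=float)})
        out = oversample_minority(df, quantile_cut=0.75, seed=3)
        assert out["agb_g_m2"].mean() > df["agb_g_m2"].mean()
        assert len(out) >= len(df)

    def test_originals_all_retained(self, rng):
        df = pd.DataFrame({"agb_g_m2": rng.uniform(0, 100, 50),
                           "id": np.arange(50)})
        out = oversample_minority(df, seed=1)
        assert set(df["id"]) <= set(out["id"])


class TestBMAWeights:
    def test_equal_errors_uniform(self):
        w = bma_weights([2.0] * 5, 40)
        assert np.allclose(w, 0.2)

    def test_zero_error_takes_all_weight(self):
        w = bma_weights([0.0, 1.0, 1.0, 1.0, 1.0], 40)
        assert w[0] == 1.0
        assert np.allclose(w[1:], 0.0)

    def test_matches_hand_computed_bic(self):
        """Independent BIC evaluation: BIC_k = n ln(rmse_k^2)."""
        errs = np.array([1.0, 2.0, 2.0, 2.0, 2.0])
        n = 50
        bic = n * np.log(errs**2)
        expected = np.exp(-0.5 * (bic - bic.min()))
        expected /= expected.sum()
        assert np.allclose(bma_weights(errs, n), expected, rtol=1e-12)

    def test_weights_sum_to_one(self, rng):
        w = bma_weights(rng.uniform(0.5, 3.0, 5), rng.integers(10, 60, 5))
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)

    def test_non_finite_errors_rejected(self):
        with pytest.raises(DataError):
            bma_weights([1.0, np.nan, 1.0], 10)


class TestForcingConfig:
    def test_empty_or_duplicate_features_rejected(self):
        with pytest.raises(ConfigError):
            ForcingEnsemble("x", ())
        with pytest.raises(ConfigError):
            ForcingEnsemble("x", ("a", "a"))

    def test_combined_is_union(self):
        sat, cli, comb = ab.default_forcings()
        assert set(comb.feature_names) == set(sat.feature_names) | set(
            cli.feature_names
        )

    def test_missing_feature_column_named(self):
        df = _feature_table(50)
        df["agb_g_m2"] = 1.0
        with pytest.raises(ConfigError, match="nope"):
            AGBEnsembleModel(df, forcings=[ForcingEnsemble("f", ("nope",))])


class TestTraining:
    def test_deterministic_target_recovered(self):
        """AGB an exact function of combined features -> holdout R2 >= 0.99."""
        df = _feature_table(4000, seed=2)
        df["agb_g_m2"] = 20.0 * df["type"] + 100.0 * df["ndvi_mean"]
        res = AGBEnsembleModel(df, rf_params={"n_estimators": 100}).fit(seed=0)
        assert res.holdout_r2("combined") >= 0.99

    def test_constant_target_degenerate(self):
        df = _feature_table(300, seed=3)
        df["agb_g_m2"] = 42.0
        res = AGBEnsembleModel(df, rf_params={"n_estimators": 20}).fit(seed=0)
        assert np.isnan(res.holdout_r2("combined"))
        assert res.fits["combined"].holdout_rmse == pytest.approx(0.0)

    def test_label_permutation_destroys_holdout_r2(self):
        """Shuffled targets must not score: guards against fold leakage."""
        df = _feature_table(1500, seed=4)
        df["agb_g_m2"] = 20.0 * df["type"] + 100.0 * df["ndvi_mean"]
        df["agb_g_m2"] = np.random.default_rng(0).permutation(
            df["agb_g_m2"].to_numpy()
        )
        res = AGBEnsembleModel(df, rf_params={"n_estimators": 50}).fit(seed=0)
        assert res.holdout_r2("combined") <= 0.1

    def test_nonfinite_records_dropped(self):
        df = _feature_table(100, seed=5)
        df["agb_g_m2"] = 10.0
        df.loc[0, "ndvi_mean"] = np.nan
        m = AGBEnsembleModel(df)
        assert len(m.data) == 99


class TestPrediction:
    def _simple_fit(self, models, weights):
        return ForcingFit(
            label="combined", feature_names=("x",), models=models,
            weights=np.asarray(weights), holdout_r2=1.0, holdout_rmse=0.0,
            cv_rmse=0.0, fold_rmse=np.zeros(len(models)),
        )

    class _Const:
        def __init__(self, c):
            self.c = c

        def predict(self, X):
            return np.full(len(X), self.c)

    def test_identical_fold_models_equal_single(self):
        fit = self._simple_fit([self._Const(7.0)] * 5, [0.2] * 5)
        assert np.allclose(fit.predict(np.zeros((4, 1))), 7.0)

    def test_bma_prediction_within_fold_envelope(self, rng):
        models = [self._Const(c) for c in (3.0, 5.0, 9.0, 4.0, 6.0)]
        w = rng.dirichlet(np.ones(5))
        fit = self._simple_fit(models, w)
        pred = fit.predict(np.zeros((10, 1)))
        assert np.all(pred >= 3.0) and np.all(pred <= 9.0)

    def test_nodata_pixel_propagates(self):
        """A NaN in any feature layer yields NaN in the prediction cube."""
        cfg = ScenarioConfig(
            grid_rows=10, grid_cols=10,
            type_params={1: TypeParams(0.12, 0.82, 10.0, 18.0, 0.45)},
            cover_base_field_sigma=0.1, smooth_sigma=2.0, seed=6,
        )
        scene = generate_scene(cfg)
        surveys = sample_surveys(scene, 200, seed=7)
        res = AGBEnsembleModel.from_scene(
            scene, surveys, rf_params={"n_estimators": 20}
        ).fit(seed=8)
        cubes = dict(scene_feature_cubes(scene))
        dirty = cubes["ndvi_mean"].copy(deep=True)
        dirty.values[3, 4, 4] = np.nan
        cubes["ndvi_mean"] = dirty
        pred = res.predict_cube(cubes, "combined")
        assert np.isnan(pred.values[3, 4, 4])
        assert np.isfinite(pred.values[3, 4, 5])

    def test_missing_feature_cube_named(self):
        df = _feature_table(200, seed=9)
        df["agb_g_m2"] = df["ndvi_mean"]
        res = AGBEnsembleModel(df, rf_params={"n_estimators": 10}).fit(seed=0)
        with pytest.raises(ConfigError, match="lai_mean"):
            res.predict_cube({"ndvi_mean": make_cube(np.zeros((1, 2, 2)), [2001])},
                             "satellite")

    def test_noise_free_scene_per_pixel_accuracy(self):
        """Observable-only spatial variation: predictions within 5%
        relative error of the generator truth for >= 95% of pixels."""
        cfg = ScenarioConfig(
            grid_rows=40, grid_cols=40,
            type_params={1: TypeParams(0.12, 0.82, 10.0, 18.0, 0.45)},
            cover_base_field_sigma=0.12, smooth_sigma=3.0, seed=7,
        )
        scene = generate_scene(cfg)
        surveys = sample_surveys(scene, 1000, seed=8)
        res = AGBEnsembleModel.from_scene(
            scene, surveys, rf_params={"n_estimators": 150}
        ).fit(seed=9)
        pred = res.predict_cube(scene_feature_cubes(scene), "combined")
        rel = np.abs(pred.values - scene.true_agb.values) / scene.true_agb.values
        assert np.mean(rel <= 0.05) >= 0.95


class TestEnsembleSpread:
    def test_identical_maps_zero_sd(self):
        m = make_cube(np.random.default_rng(0).normal(size=(1, 4, 4)), [2001])
        _, sd = ensemble_mean_and_sd([m, m, m])
        assert np.allclose(sd.values, 0.0)

    def test_closed_form(self):
        maps = [make_cube(np.full((1, 1, 1), v), [2001]) for v in (0.0, 1.0, 2.0)]
        mean, sd = ensemble_mean_and_sd(maps)
        assert mean.values[0, 0, 0] == pytest.approx(1.0)
        assert sd.values[0, 0, 0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_matches_loop_oracle(self, rng):
        maps = [make_cube(rng.normal(size=(1, 5, 5)), [2001]) for _ in range(3)]
        mean, sd = ensemble_mean_and_sd(maps)
        for i in range(5):
            for j in range(5):
                vals = [m.values[0, i, j] for m in maps]
                assert mean.values[0, i, j] == pytest.approx(np.mean(vals))
                assert sd.values[0, i, j] == pytest.approx(np.std(vals))

    def test_misaligned_rejected(self):
        a = make_cube(np.zeros((1, 2, 2)), [2001])
        b = make_cube(np.zeros((1, 3, 3)), [2001])
        from agballoc.exceptions import AlignmentError

        with pytest.raises(AlignmentError):
            ensemble_mean_and_sd([a, b])
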