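"""Forest regression, OOB importance, variable selection, CV, isoscape."""

import numpy as np
import pandas as pd
import pytest

from isoprov.grids import CovariateStack, GridSpec, RasterGrid
from isoprov.model import (RandomForestIsoscape, RegressionDataset,
                           RFVariableSelector, cross_validate, fit_forest,
                           select_variables)

FAST = dict(n_trees=150, min_leaf=5)


def make_ds(n=150, p_noise=3, noise_sd=0.0, seed=0, fn=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"signal": rng.uniform(0, 10, n)})
    for j in range(p_noise):
        X[f"noise{j}"] = rng.normal(size=n)
    f = fn or (lambda x: x)
    y = f(X["signal"].to_numpy()) + rng.normal(0, noise_sd, n)
    return RegressionDataset(X=X, y=y)


class TestForestFit:
    def test_constant_response_predicts_constant(self):
        ds = make_ds(60, fn=lambda x: np.full_like(x, 5.5))
        m = fit_forest(ds, seed=0, **FAST)
        np.testing.assert_allclose(m.predict(ds.X), 5.5)

    def test_binary_covariate_group_means(self):
        """A binary split recovers the two group means."""
        X = pd.DataFrame({"g": [0.0, 0.0, 1.0, 1.0] * 13})
        y = np.array([1.0, 3.0, 10.0, 14.0] * 13)
        m = RandomForestIsoscape(n_trees=400, min_leaf=5,
                                 random_state=0).fit(X, y)
        pred = m.predict(pd.DataFrame({"g": [0.0, 1.0]}))
        assert pred[0] == pytest.approx(2.0, abs=0.15)
        assert pred[1] == pytest.approx(12.0, abs=0.3)

    def test_constant_groups_exact(self):
        X = pd.DataFrame({"g": [0.0, 1.0] * 30})
        y = np.where(X["g"] == 0, 2.0, 12.0)
        m = RandomForestIsoscape(n_trees=100, min_leaf=5,
                                 random_state=1).fit(X, y)
        pred = m.predict(pd.DataFrame({"g": [0.0, 1.0]}))
        assert pred[0] == pytest.approx(2.0, abs=1e-9)
        assert pred[1] == pytest.approx(12.0, abs=1e-9)

    def test_linear_ramp_oob_r2(self):
        """Dense linear signal, noise at 10% of range: OOB R^2 > 0.8."""
        ds = make_ds(400, noise_sd=1.0, seed=2)  # range 10, noise sd 1
        m = fit_forest(ds, ["signal"], seed=2, n_trees=300)
        r2 = 1 - m.oob_rmse_ ** 2 / np.var(ds.y)
        assert r2 > 0.8

    def test_range_preservation(self):
        ds = make_ds(200, noise_sd=2.0, seed=3)
        m = fit_forest(ds, seed=3, **FAST)
        probe = ds.X.copy()
        probe["signal"] = np.linspace(-50, 50, len(probe))
        pred = m.predict(probe)
        assert pred.min() >= ds.y.min() - 1e-9
        assert pred.max() <= ds.y.max() + 1e-9

    def test_too_few_rows_raises(self):
        ds = make_ds(3)
        with pytest.raises(ValueError, match="min_leaf"):
            fit_forest(ds, seed=0)

    def test_seed_determinism(self):
        ds = make_ds(120, noise_sd=1.0, seed=4)
        a = fit_forest(ds, seed=42, **FAST)
        b = fit_forest(ds, seed=42, **FAST)
        np.testing.assert_array_equal(a.predict(ds.X), b.predict(ds.X))
        assert a.oob_rmse_ == b.oob_rmse_


class TestOOBMachinery:
    def test_reconstructed_oob_matches_sklearn(self):
        """Bootstrap-index reconstruction reproduces forest.oob_prediction_."""
        ds = make_ds(100, noise_sd=1.0, seed=5)
        m = fit_forest(ds, seed=7, n_trees=80)
        np.testing.assert_allclose(m.oob_prediction_reconstructed(),
                                   m.oob_prediction_, rtol=1e-12)


class TestImportance:
    def test_informative_variable_positive(self):
        ds = make_ds(150, seed=6)
        m = fit_forest(ds, seed=6, **FAST)
        tab = m.permutation_importance_oob().set_index("variable")
        assert tab.loc["signal", "importance"] > 0
        assert tab.index[0] == "signal"

    def test_decoy_importance_near_zero(self):
        ds = make_ds(150, noise_sd=1.0, seed=7)
        m = fit_forest(ds, seed=7, **FAST)
        tab = m.permutation_importance_oob().set_index("variable")
        for j in range(3):
            row = tab.loc[f"noise{j}"]
            assert abs(row["importance"]) < 3 * max(row["se"], 1e-12) + 0.05

    def test_duplicated_covariate_shares_importance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 200)
        y = x + rng.normal(0, 0.5, 200)
        single = RandomForestIsoscape(n_trees=200, random_state=8).fit(
            pd.DataFrame({"x": x, "n": rng.normal(size=200)}), y)
        dup = RandomForestIsoscape(n_trees=200, random_state=8).fit(
            pd.DataFrame({"x": x, "x2": x, "n": rng.normal(size=200)}), y)
        imp_single = single.permutation_importance_oob().set_index("variable")
        imp_dup = dup.permutation_importance_oob().set_index("variable")
        i1 = imp_single.loc["x", "importance"]
        ia, ib = imp_dup.loc["x", "importance"], imp_dup.loc["x2", "importance"]
        # each copy individually reduced; combined comparable to the single
        assert ia < i1 and ib < i1
        assert (ia + ib) > 0.5 * i1

    def test_impurity_importance_available(self):
        ds = make_ds(100, seed=9)
        m = fit_forest(ds, seed=9, **FAST)
        tab = m.impurity_importance()
        assert tab.iloc[0]["variable"] == "signal"


class TestPartialDependence:
    def test_ignored_variable_nearly_flat_curve(self):
        ds = make_ds(150, seed=10)
        m = fit_forest(ds, seed=10, **FAST)
        flat = m.partial_dependence(ds.X, "noise0", np.linspace(-2, 2, 7))
        used = m.partial_dependence(ds.X, "signal", np.linspace(0, 10, 7))
        assert flat["mean_prediction"].std() < \
            0.2 * used["mean_prediction"].std()

    def test_identity_signal_tracks_diagonal(self):
        ds = make_ds(500, seed=11)
        m = fit_forest(ds, ["signal"], seed=11, n_trees=200)
        grid = np.linspace(1.0, 9.0, 9)  # interior probe points
        curve = m.partial_dependence(ds.X[["signal"]], "signal", grid)
        np.testing.assert_allclose(curve["mean_prediction"], grid, atol=0.35)

    def test_unknown_variable_raises(self):
        ds = make_ds(60, seed=12)
        m = fit_forest(ds, seed=12, **FAST)
        with pytest.raises(ValueError, match="unknown"):
            m.partial_dependence(ds.X, "nope", [0.0])


class TestSelection:
    def test_recovers_exact_covariate_across_seeds(self):
        """y equals one covariate exactly, 9 decoys: it is selected, decoys
        are not, across 5 seeds."""
        for seed in range(5):
            ds = make_ds(120, p_noise=9, noise_sd=0.0, seed=seed)
            sel = select_variables(ds, n_rank_forests=4, seed=seed,
                                   model_params=dict(n_trees=120))
            assert sel.selected_variables_ == ["signal"], seed

    def test_pure_noise_selects_nothing_or_errors(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(80, 5)),
                         columns=[f"n{j}" for j in range(5)])
        ds = RegressionDataset(X=X, y=rng.normal(size=80))
        try:
            sel = select_variables(ds, n_rank_forests=4, seed=13,
                                   model_params=dict(n_trees=120))
            assert sel.selected_variables_ == []
        except ValueError as exc:
            assert "eliminated" in str(exc)

    def test_oob_path_non_increasing(self):
        ds = make_ds(150, p_noise=4, noise_sd=1.0, seed=14)
        sel = select_variables(ds, n_rank_forests=4, seed=14,
                               model_params=dict(n_trees=120))
        rmses = [r for _, r in sel.oob_path_]
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))
        assert set(sel.selected_variables_) <= \
            {n for n, _ in sel.ranked_variables_}

    def test_preconditions(self):
        ds = make_ds(10, p_noise=1)
        with pytest.raises(ValueError, match="20 rows"):
            select_variables(ds, seed=0)
        one_var = RegressionDataset(X=ds.X[["signal"]], y=ds.y)
        with pytest.raises(ValueError, match="2 candidate"):
            select_variables(one_var, seed=0)

    def test_selector_transform_keeps_selected_columns(self):
        ds = make_ds(120, p_noise=3, seed=15)
        sel = RFVariableSelector(n_rank_forests=3, n_trees=100,
                                 random_state=15).fit(ds.X, ds.y)
        out = sel.transform(ds.X)
        assert out.shape == (120, len(sel.selected_variables_))


class TestCrossValidation:
    def test_noiseless_signal_near_perfect(self):
        ds = make_ds(200, noise_sd=0.0, seed=16)
        cv = cross_validate(ds, ["signal"], folds=5, repeats=2, seed=16,
                            model_params=dict(n_trees=150))
        assert cv.r2 > 0.95
        assert cv.rmse < 0.15 * ds.y.std()

    def test_pure_noise_r2_near_zero_rmse_near_sigma(self):
        sigma = 2.0
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"a": rng.normal(size=200),
                          "b": rng.normal(size=200)})
        ds = RegressionDataset(X=X, y=rng.normal(0, sigma, 200))
        cv = cross_validate(ds, folds=10, repeats=2, seed=17,
                            model_params=dict(n_trees=100))
        assert cv.r2 < 0.1
        assert cv.rmse == pytest.approx(sigma, rel=0.2)

    def test_shuffled_response_destroys_skill(self, dataset_small):
        rng = np.random.default_rng(18)
        shuffled = RegressionDataset(X=dataset_small.X,
                                     y=rng.permutation(dataset_small.y))
        cv = cross_validate(shuffled, folds=10, repeats=1, seed=18,
                            model_params=dict(n_trees=100))
        assert cv.r2 <= 0.1

    def test_too_many_folds_raises(self):
        ds = make_ds(8, p_noise=1)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ds, folds=10, seed=0)

    def test_classic_kfold_available(self):
        ds = make_ds(60, noise_sd=1.0, seed=19)
        cv = cross_validate(ds, folds=5, repeats=1, train_fraction=None,
                            seed=19, model_params=dict(n_trees=60))
        assert cv.scheme["train_fraction"] is None
        assert len(cv.observed) == 60  # every row held out exactly once

    def test_determinism(self):
        ds = make_ds(80, noise_sd=1.0, seed=20)
        a = cross_validate(ds, folds=5, repeats=1, seed=3,
                           model_params=dict(n_trees=60))
        b = cross_validate(ds, folds=5, repeats=1, seed=3,
                           model_params=dict(n_trees=60))
        assert a.rmse == b.rmse and a.r2 == b.r2
        np.testing.assert_array_equal(a.predicted, b.predicted)


class TestPredictIsoscape:
    def _stack(self, vals_by_name, cell=1.0):
        shape = next(iter(vals_by_name.values())).shape
        spec = GridSpec(crs="local", cell_size=cell, xmin=0.0,
                        ymax=shape[0] * cell, nrows=shape[0], ncols=shape[1])
        stack = CovariateStack(spec)
        for name, vals in vals_by_name.items():
            stack.add(RasterGrid(spec, vals, name=name))
        return stack

    def test_constant_world_constant_grid(self):
        ds = make_ds(60, p_noise=0, noise_sd=0.5, seed=21)
        m = fit_forest(ds, seed=21, **FAST)
        stack = self._stack({"signal": np.full((4, 4), 5.0)})
        iso = m.predict_isoscape(stack, constant_rmse=1.0)
        assert np.allclose(iso.mean.values, iso.mean.values[0, 0])
        assert iso.sd == 1.0

    def test_training_cell_consistency(self):
        ds = make_ds(60, p_noise=0, noise_sd=0.5, seed=22)
        m = fit_forest(ds, seed=22, **FAST)
        v = float(ds.X["signal"].iloc[0])
        stack = self._stack({"signal": np.full((2, 2), v)})
        iso = m.predict_isoscape(stack, constant_rmse=1.0)
        direct = m.predict(pd.DataFrame({"signal": [v]}))[0]
        assert iso.mean.values[0, 0] == pytest.approx(direct)

    def test_missing_layer_named(self):
        ds = make_ds(60, p_noise=1, seed=23)
        m = fit_forest(ds, seed=23, **FAST)
        stack = self._stack({"signal": np.full((2, 2), 5.0)})
        with pytest.raises(ValueError, match="noise0"):
            m.predict_isoscape(stack, constant_rmse=1.0)

    def test_nodata_propagates(self):
        ds = make_ds(60, p_noise=0, seed=24)
        m = fit_forest(ds, seed=24, **FAST)
        vals = np.full((2, 2), 5.0)
        vals[0, 0] = np.nan
        stack = self._stack({"signal": vals})
        iso = m.predict_isoscape(stack, constant_rmse=1.0)
        assert iso.mean.nodata_mask[0, 0]
        assert not iso.mean.nodata_mask[1, 1]
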