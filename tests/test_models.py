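"""Base learners, stacking protocol, Ensemble-Mean, re-balancing."""

from dataclasses import dataclass

import numpy as np
import pytest

import solstack as ss
from solstack.models import RESAMPLING_TECHNIQUES


def _regression_toy(n=200, d=4, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = 2.0 * X[:, 0] - X[:, 1] + noise * rng.normal(size=n)
    return X, y


class TestFitBase:
    def test_constant_target(self):
        X, _ = _regression_toy()
        est = ss.fit_base("lgbm", X, np.full(len(X), 3.0))
        assert np.allclose(est.predict(X), 3.0, atol=1e-6)

    def test_rf_learns_linear_signal(self):
        X, y = _regression_toy(n=500, seed=1)
        est = ss.fit_base("rf", X, y, hyperparameters={"n_estimators": 100})
        pred = est.predict(X)
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9

    def test_same_seed_identical(self):
        X, y = _regression_toy(noise=0.5)
        p1 = ss.fit_base("xgb", X, y, seed=5).predict(X)
        p2 = ss.fit_base("xgb", X, y, seed=5).predict(X)
        assert np.array_equal(p1, p2)

    def test_nonfinite_features_rejected(self):
        X, y = _regression_toy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ss.fit_base("rf", X, y)


class TestTuneHyperparameters:
    def test_singleton_grid_returned(self):
        X, y = _regression_toy(n=60)
        best = ss.tune_hyperparameters("lgbm", X, y, {"n_estimators": [17]})
        assert best == {"n_estimators": 17}

    def test_generating_complexity_selected_on_noiseless_data(self):
        X, y = _regression_toy(n=300, seed=2)
        best = ss.tune_hyperparameters(
            "lgbm", X, y, {"n_estimators": [5, 150]}, n_folds=3)
        assert best["n_estimators"] == 150

    def test_deterministic_given_seed(self):
        X, y = _regression_toy(n=120, noise=1.0, seed=3)
        grid = {"n_estimators": [20, 40], "learning_rate": [0.05, 0.2]}
        assert (ss.tune_hyperparameters("lgbm", X, y, grid, seed=9)
                == ss.tune_hyperparameters("lgbm", X, y, grid, seed=9))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ss.tune_hyperparameters("rf", *_regression_toy(), {})


class TestStacking:
    def test_identical_perfect_bases_reproduced_by_mlr_meta(self):
        X, y = _regression_toy(n=300, seed=4)
        specs = [ss.BaseSpec("lgbm", {"n_estimators": 200}),
                 ss.BaseSpec("lgbm", {"n_estimators": 200})]
        model = ss.fit_stacking(specs, ss.MetaSpec("mlr"), X, y, n_folds=5, seed=0)
        base_pred = model.base_models_[0].predict(X)
        assert np.allclose(model.predict(X), base_pred, atol=0.05)
        assert np.sum(model.meta_model_.coef_) == pytest.approx(1.0, abs=0.05)

    def test_saturating_lasso_penalty_predicts_mean(self):
        X, y = _regression_toy(n=200, seed=5, noise=0.3)
        model = ss.fit_stacking(
            [ss.BaseSpec("rf", {"n_estimators": 30}), ss.BaseSpec("svm")],
            ss.MetaSpec("lasso", {"alpha": 1e6}), X, y, n_folds=3, seed=0)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_out_of_fold_protocol_no_leakage(self):
        # pure-noise target: OOF predictions must not correlate with y even
        # though deep trees memorize it in-fold
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 5))
        y = rng.normal(size=400)
        model = ss.fit_stacking(
            [ss.BaseSpec("rf", {"n_estimators": 50}),
             ss.BaseSpec("lgbm", {"n_estimators": 50})],
            ss.MetaSpec("mlr"), X, y, n_folds=5, seed=0)
        folds = model.fold_assignment_
        assert sorted(np.unique(folds)) == list(range(5))
        oof_rf = model.oof_design_[:, 0]
        in_fold_rf = model.base_models_[0].predict(X)
        assert abs(np.corrcoef(oof_rf, y)[0, 1]) < 0.2
        assert np.corrcoef(in_fold_rf, y)[0, 1] > 0.5

    def test_too_few_bases_or_folds_rejected(self):
        X, y = _regression_toy(n=50)
        with pytest.raises(ValueError):
            ss.fit_stacking([ss.BaseSpec("rf")], ss.MetaSpec("mlr"), X, y)
        with pytest.raises(ValueError):
            ss.fit_stacking([ss.BaseSpec("rf"), ss.BaseSpec("svm")],
                            ss.MetaSpec("mlr"), X, y, n_folds=1)

    def test_unfitted_model_rejected(self):
        model = ss.StackedModel("regression", [], ss.MetaSpec("mlr"), 5, 0)
        with pytest.raises(RuntimeError):
            model.predict(np.zeros((2, 3)))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(300, 4))
    y = np.digitize(X[:, 0] + 0.3 * rng.normal(size=300), [-0.8, 0.8])
    return X, y


@pytest.fixture(scope="module")
def clf(toy):
    X, y = toy
    return ss.fit_stacking(
        [ss.BaseSpec("rf", {"n_estimators": 50}),
         ss.BaseSpec("lgbm", {"n_estimators": 50})],
        ss.MetaSpec("logistic"), X, y, task="classification",
        n_folds=3, seed=0)


class TestClassificationStacking:
    def test_probabilities_normalized_and_deterministic(self, toy, clf):
        X, _ = toy
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(proba, clf.predict_proba(X))

    def test_meta_design_width_is_bases_times_classes(self, toy, clf):
        assert clf.oof_design_.shape[1] == 2 * 3

    def test_missing_class_in_fold_raises(self, toy):
        X, y = toy
        y_rare = y.copy()
        y_rare[:] = 0
        y_rare[:3] = 1  # 3 samples of class 1 cannot stratify into 5 folds
        with pytest.raises(ValueError, match="class"):
            ss.fit_stacking([ss.BaseSpec("rf"), ss.BaseSpec("lgbm")],
                            ss.MetaSpec("logistic"), X, y_rare,
                            task="classification", n_folds=5, seed=0)


class TestEnsembleMean:
    @dataclass
    class _Stub:
        value: float
        n_features_: int = 3

        def predict(self, X):
            return np.full(len(X), self.value)

    def test_mean_and_member_sd(self):
        members = [self._Stub(-1.0), self._Stub(-2.0), self._Stub(-3.0)]
        mean, sd = ss.ensemble_mean_predict(members, np.zeros((4, 3)))
        assert np.allclose(mean, -2.0)
        assert np.allclose(sd, 1.0)  # sample SD of {-1,-2,-3}

    def test_identical_members_zero_sd(self):
        members = [self._Stub(-1.5)] * 3
        _, sd = ss.ensemble_mean_predict(members, np.zeros((2, 3)))
        assert np.allclose(sd, 0.0)

    def test_member_order_irrelevant(self):
        m = [self._Stub(-1.0), self._Stub(-2.0), self._Stub(-3.0)]
        a = ss.ensemble_mean_predict(m, np.zeros((2, 3)))
        b = ss.ensemble_mean_predict(m[::-1], np.zeros((2, 3)))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_exactly_three_members_required(self):
        with pytest.raises(ValueError):
            ss.EnsembleMean([self._Stub(0.0)] * 2)


class TestResampling:
    @pytest.fixture
    def imbalanced(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, size=(90, 2)),
                       rng.normal(4, 1, size=(10, 2))])
        y = np.array([0] * 90 + [1] * 10)
        return X, y

    def test_balanced_input_unchanged_by_undersampling(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        Xr, yr = ss.resample_training(X, y, "RandomUnder", seed=0)
        assert len(yr) == 40 and np.bincount(yr).tolist() == [20, 20]

    def test_random_over_equalizes_to_majority(self, imbalanced):
        X, y = imbalanced
        _, yr = ss.resample_training(X, y, "RandomOver", seed=0)
        assert np.bincount(yr).tolist() == [90, 90]

    def test_smote_points_interpolate_minority_segments(self, imbalanced):
        X, y = imbalanced
        Xr, yr = ss.resample_training(X, y, "SMOTE", seed=0)
        new = Xr[len(y):]
        assert (yr[len(y):] == 1).all()
        minority = X[y == 1]
        for p in new:
            on_some_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    t = np.dot(p - a, b - a) / np.dot(b - a, b - a)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(p - (a + t * (b - a))) < 1e-9:
                        on_some_segment = True
                        break
                if on_some_segment:
                    break
            assert on_some_segment

    @pytest.mark.parametrize("technique", RESAMPLING_TECHNIQUES)
    def test_inputs_never_mutated(self, imbalanced, technique):
        X, y = imbalanced
        X0, y0 = X.copy(), y.copy()
        ss.resample_training(X, y, technique, seed=1)
        assert np.array_equal(X, X0) and np.array_equal(y, y0)

    @pytest.mark.parametrize("technique", ["SMOTE", "Borderline1", "Borderline2"])
    def test_oversamplers_balance_counts(self, imbalanced, technique):
        X, y = imbalanced
        _, yr = ss.resample_training(X, y, technique, seed=2)
        counts = np.bincount(yr)
        assert counts[1] == counts[0]

    def test_smoteenn_cleans_after_oversampling(self, imbalanced):
        X, y = imbalanced
        Xr, yr = ss.resample_training(X, y, "SMOTEENN", seed=3)
        assert len(np.unique(yr)) == 2
        assert len(yr) <= 180  # ENN can only remove points

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.resample_training(np.zeros((5, 2)), np.zeros(5), "SMOTE")


class TestStackingBenchmark:
    def test_stacking_at_least_matches_best_base(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 6))
        y = X[:, 0] - 0.5 * X[:, 1] + np.sin(2 * X[:, 2]) + 0.3 * rng.normal(size=300)
        light = [ss.BaseSpec("rf", {"n_estimators": 60}),
                 ss.BaseSpec("lgbm", {"n_estimators": 80}),
                 ss.BaseSpec("svm")]
        res = ss.stacking_benchmark(X, y, light, seed=0)
        assert res["stacking_rmse"] <= min(res["base_rmse"].values()) + 0.02
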