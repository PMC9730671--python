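"""Model fitting, cross-validation, feature elimination and ensembling."""

import numpy as np
import pandas as pd
import pytest

from ntcp_albi.model import (
    EnsembleModel,
    ModelSpec,
    NTCPModel,
    crossval_5fold,
    default_monotone_constraints,
    ensemble_crossval,
    fit_model,
    recursive_feature_elimination,
)
from conftest import FAST_GRIDS


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (x > 0).astype(int)
    X = pd.DataFrame({"mld": x, "age": rng.normal(size=n)})
    return X, y


class TestModelSpec:
    def test_constraints_only_for_gbt_and_known_features(self):
        with pytest.raises(ValueError):
            ModelSpec("plr", ("mld",), monotone_constraints={"mld": 1})
        with pytest.raises(ValueError):
            ModelSpec("gbt", ("age",), monotone_constraints={"mld": 1})
        with pytest.raises(ValueError):
            ModelSpec("gbt", ("mld",), monotone_constraints={"mld": -1})
        with pytest.raises(ValueError):
            ModelSpec("svm", ("mld",))

    def test_default_constraints_pick_dosimetric_features(self):
        mono = default_monotone_constraints(("age", "mld", "total_dose", "geud_a2", "ast"))
        assert mono == {"mld": 1, "total_dose": 1, "geud_a2": 1}


class TestFitModel:
    @pytest.mark.parametrize("family", ["plr", "rf", "gbt"])
    def test_separable_data_fits_perfectly(self, family):
        X, y = separable_data()
        spec = ModelSpec.with_default_constraints(family, ("mld", "age"),
                                                  param_grid=FAST_GRIDS[family])
        m = fit_model(spec, X, y)
        from ntcp_albi import auroc

        assert auroc(m.predict(X), y) == 1.0

    def test_single_class_outcome_rejected(self):
        X, _ = separable_data()
        spec = ModelSpec("plr", ("mld", "age"))
        with pytest.raises(ValueError):
            fit_model(spec, X, np.zeros(len(X), dtype=int))

    def test_missing_values_rejected(self):
        X, y = separable_data()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_model(ModelSpec("plr", ("mld", "age")), X, y)

    def test_plr_on_pure_noise_has_near_zero_coefficients(self):
        rng = np.random.default_rng(2)
        n = 5000
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["age", "ast", "inr", "alp"])
        y = rng.integers(0, 2, n)
        m = fit_model(ModelSpec("plr", tuple(X.columns), seed=2), X, y)
        assert (m.params.abs() < 0.1).all()

    def test_gbt_monotone_sweep_never_decreases(self, small_features):
        X, y = small_features
        feats = ("mld", "total_dose", "ast", "albi_score_until_next_grade")
        spec = ModelSpec.with_default_constraints("gbt", feats, param_grid=FAST_GRIDS["gbt"])
        m = fit_model(spec, X[list(feats)], y)
        rng = np.random.default_rng(0)
        rows = rng.choice(len(X), 50, replace=False)
        for feat in ("mld", "total_dose"):
            grid = np.linspace(X[feat].min(), X[feat].max(), 40)
            for i in rows:
                xi = X[list(feats)].iloc[[i]].copy()
                preds = []
                for v in grid:
                    xi[feat] = v
                    preds.append(m.predict(xi)[0])
                assert np.all(np.diff(preds) >= -1e-12)

    def test_prediction_rejects_column_mismatch(self):
        X, y = separable_data()
        m = fit_model(ModelSpec("plr", ("mld", "age"), param_grid=FAST_GRIDS["plr"]), X, y)
        with pytest.raises(ValueError, match="missing"):
            m.predict(X[["mld"]])

    def test_importances_defined_for_every_feature(self, small_features):
        X, y = small_features
        feats = ("mld", "ast", "total_bilirubin")
        for family in ("plr", "rf", "gbt"):
            spec = ModelSpec.with_default_constraints(family, feats, param_grid=FAST_GRIDS[family])
            m = fit_model(spec, X[list(feats)], y)
            assert set(m.importances.index) == set(feats)
            if family != "plr":
                assert (m.importances >= 0).all()
                assert m.importances.sum() == pytest.approx(1.0)


class TestEnsemble:
    class _Stub:
        def __init__(self, p):
            self.p = p

        def predict_proba(self, X):
            return np.full(len(X), self.p)

    def test_mean_of_members(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        ens = EnsembleModel([self._Stub(0.2), self._Stub(0.6)])
        assert ens.predict(X) == pytest.approx([0.4, 0.4])

    def test_identical_members_equal_single_member(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        ens = EnsembleModel([self._Stub(0.3), self._Stub(0.3)])
        assert ens.predict(X) == pytest.approx([0.3, 0.3, 0.3])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([])

    def test_zero_coefficient_logistic_predicts_half(self):
        X, y = separable_data()
        m = fit_model(ModelSpec("plr", ("mld", "age"), param_grid=FAST_GRIDS["plr"]), X, y)
        m.estimator.coef_[:] = 0.0
        m.estimator.intercept_[:] = 0.0
        assert m.predict(X) == pytest.approx(np.full(len(X), 0.5))


class TestCrossValidation:
    def test_fold_sizes_balanced_at_table_size(self, rng):
        n = 201
        X = pd.DataFrame({"mld": rng.normal(size=n), "age": rng.normal(size=n)})
        y = (rng.random(n) < 0.43).astype(int)
        cv = crossval_5fold(ModelSpec("plr", ("mld", "age"), param_grid=FAST_GRIDS["plr"]), X, y, seed=0)
        sizes = sorted(np.bincount(cv.fold_assignments).tolist())
        assert sizes == [40, 40, 40, 40, 41]

    def test_held_out_predictions_cover_every_patient_once(self, small_features):
        X, y = small_features
        cv = crossval_5fold(ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"]), X, y, seed=1)
        assert len(cv.oof_predictions) == len(y)
        assert set(np.unique(cv.fold_assignments)) == set(range(5))
        assert np.isfinite(cv.oof_predictions).all()

    def test_uninformative_features_score_near_chance(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["age", "ast", "inr"])
        y = (rng.random(n) < 0.4).astype(int)
        cv = crossval_5fold(ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"]), X, y, seed=8)
        assert 0.45 <= cv.mean_auroc <= 0.55

    def test_separable_data_scores_one_with_zero_spread(self):
        X, y = separable_data(n=100, seed=3)
        cv = crossval_5fold(ModelSpec("plr", ("mld", "age"), param_grid=FAST_GRIDS["plr"]), X, y, seed=3)
        assert cv.mean_auroc == 1.0
        assert cv.sd_auroc == 0.0

    def test_rare_class_rejected(self):
        X = pd.DataFrame({"mld": np.arange(20.0), "age": np.arange(20.0)})
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError, match="stratify"):
            crossval_5fold(ModelSpec("plr", ("mld", "age")), X, y, seed=0)

    def test_same_seed_reproduces_cv(self, small_features):
        X, y = small_features
        spec = ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"])
        cv1 = crossval_5fold(spec, X, y, seed=5)
        cv2 = crossval_5fold(spec, X, y, seed=5)
        assert np.array_equal(cv1.oof_predictions, cv2.oof_predictions)
        assert cv1.fold_auroc.tolist() == cv2.fold_auroc.tolist()

    def test_model_results_idiom(self, small_features):
        X, y = small_features
        model = NTCPModel(y, X, family="plr", features=("mld", "ast"),
                          param_grid=FAST_GRIDS["plr"], seed=0)
        res = model.fit()
        assert "plr" in res.summary()
        cv = model.fit_cv()
        assert "AUROC" in cv.summary()
        df = pd.DataFrame(X)
        df["albi1plus"] = y
        m2 = NTCPModel.from_dataframe(df, family="plr", features=("mld", "ast"),
                                      param_grid=FAST_GRIDS["plr"])
        assert m2.spec.features == ("mld", "ast")


class TestRecursiveFeatureElimination:
    def _data(self, n, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["mld", "age", "inr", "alp"]
        )
        logit = 2.0 * X["mld"].to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return X, y

    def test_informative_feature_survives_noise_eliminated(self):
        kept_informative, eliminated_noise = 0, 0
        for seed in range(5):
            X, y = self._data(1200, seed)
            spec = ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"], seed=seed)
            res = recursive_feature_elimination(spec, X, y, seed=seed)
            kept_informative += "mld" in res.best_features
            eliminated_noise += 3 - len(set(res.best_features) & {"age", "inr", "alp"})
        assert kept_informative == 5
        assert eliminated_noise >= 2 * 5  # >= 2 of 3 noise features dropped on average

    def test_single_candidate_returned_unchanged(self, small_features):
        X, y = small_features
        spec = ModelSpec("plr", ("mld",), param_grid=FAST_GRIDS["plr"])
        res = recursive_feature_elimination(spec, X[["mld"]], y)
        assert res.best_features == ("mld",)

    def test_trace_is_deterministic(self):
        X, y = self._data(400, 1)
        spec = ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"], seed=1)
        r1 = recursive_feature_elimination(spec, X, y, seed=1)
        r2 = recursive_feature_elimination(spec, X, y, seed=1)
        assert r1.trace == r2.trace
        assert r1.best_features == r2.best_features

    def test_single_dosimetric_variants_reported(self):
        rng = np.random.default_rng(4)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["mld", "total_dose", "ast"])
        logit = 1.5 * X["mld"] + 1.5 * X["total_dose"] + X["ast"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        spec = ModelSpec("plr", tuple(X.columns), param_grid=FAST_GRIDS["plr"], seed=4)
        res = recursive_feature_elimination(spec, X, y, seed=4)
        if sum(f in ("mld", "total_dose") for f in res.best_features) > 1:
            assert len(res.single_dosimetric_variants) == 2
            for feats, auc in res.single_dosimetric_variants:
                assert sum(f in ("mld", "total_dose") for f in feats) == 1


class TestEnsembleCV:
    def test_ensemble_tracks_best_member(self, small_features):
        X, y = small_features
        plr = ModelSpec("plr", ("mld", "ast", "albi_score_until_next_grade"),
                        param_grid=FAST_GRIDS["plr"])
        gbt = ModelSpec.with_default_constraints(
            "gbt", ("mld", "ast", "albi_score_until_next_grade"), param_grid=FAST_GRIDS["gbt"]
        )
        cv_plr = crossval_5fold(plr, X[list(plr.features)], y, seed=2)
        cv_gbt = crossval_5fold(gbt, X[list(gbt.features)], y, seed=2)
        cv_ens = ensemble_crossval([plr, gbt], X, y, seed=2)
        assert cv_ens.mean_auroc >= max(cv_plr.mean_auroc, cv_gbt.mean_auroc) - 0.02
        assert len(cv_ens.oof_predictions) == len(y)
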