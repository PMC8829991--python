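import json

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import osteoscreen as osc
from osteoscreen.model import (
    BASE_CLASSIFIER_NAMES,
    CLASSIFIER_NAMES,
    ScreeningClassifier,
    evaluate,
    feature_importance,
    route_subject,
    stratified_splits,
)


def separable_data(rng, n=40):
    y = np.array([0, 1] * (n // 2))
    X = np.column_stack([
        rng.normal(0, 0.3, n) + 10.0 * y,
        rng.normal(0, 1, n),
    ])
    return X, y


class TestRouting:
    def _record(self, small_cohort, **changes):
        import dataclasses
        rec = small_cohort.records[0]
        return dataclasses.replace(rec, **changes)

    def test_full_record_routes_to_three(self, small_cohort):
        assert route_subject(small_cohort.records[0]) == 3

    def test_missing_images_routes_to_two(self, small_cohort):
        rec = self._record(small_cohort, vertebrae=[])
        assert route_subject(rec) == 2

    def test_missing_labs_routes_to_one(self, small_cohort):
        rec = self._record(small_cohort, vertebrae=[])
        rec.clinical = {k: v for k, v in rec.clinical.items()
                        if k in ("age", "bmi", "systolic_bp", "diastolic_bp",
                                 "pulse_pressure", "mps")}
        assert route_subject(rec) == 1

    def test_missing_demographics_is_an_error(self, small_cohort):
        rec = self._record(small_cohort)
        rec.clinical = dict(rec.clinical)
        del rec.clinical["age"]
        with pytest.raises(ValueError, match="age"):
            route_subject(rec)


class TestScreeningClassifier:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separable_data_perfect_train_auc(self, rng, name):
        X, y = separable_data(rng, n=100)
        sc = ScreeningClassifier(name=name, grids="compact",
                                 scaled=("LR", "SVM", "ANN"), random_state=0)
        sc.fit(X, y)
        assert sc.score(X, y) == 1.0

    def test_same_seed_identical_fit(self, rng):
        X, y = separable_data(rng, n=60)
        a = ScreeningClassifier(name="XGB", grids="compact", random_state=5).fit(X, y)
        b = ScreeningClassifier(name="XGB", grids="compact", random_state=5).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert np.array_equal(a.decision_scores(X), b.decision_scores(X))

    def test_label_permuted_cv_auc_near_chance(self):
        aucs = []
        for s in range(20):
            local = np.random.default_rng(300 + s)
            X = local.normal(size=(60, 4))
            y = local.permutation([0, 1] * 30)
            sc = ScreeningClassifier(name="LR", grids="compact",
                                     random_state=s).fit(X, y)
            aucs.append(sc.cv_auc_)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_minority_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 15 + [1] * 5)
        with pytest.raises(ValueError, match="folds"):
            ScreeningClassifier(name="LR", cv=10).fit(X, y)

    def test_auc_symmetry_of_scores(self, rng):
        X, y = separable_data(rng, n=60)
        sc = ScreeningClassifier(name="RF", grids="compact",
                                 random_state=1).fit(X, y)
        s = sc.decision_scores(X)
        assert roc_auc_score(y, s) + roc_auc_score(y, -s) == pytest.approx(1.0)


class TestStacking:
    def test_meta_learner_sees_exactly_five_columns(self, rng):
        X, y = separable_data(rng, n=60)
        sc = ScreeningClassifier(name="Stacking", grids="compact",
                                 random_state=0).fit(X, y)
        meta = sc.estimator_.final_estimator_
        assert meta.coef_.shape == (1, 5)
        assert [n for n, _ in sc.estimator_.estimators] == list(BASE_CLASSIFIER_NAMES)

    def test_stacking_tracks_informative_base(self):
        rng = np.random.default_rng(17)
        n = 120
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack(
            [rng.normal(0, 1, n) + 1.8 * y] + [rng.normal(size=n) for _ in range(4)])
        tr = slice(0, 90)
        te = slice(90, None)
        best_base_auc = 0.0
        for name in BASE_CLASSIFIER_NAMES:
            sc = ScreeningClassifier(name=name, grids="compact",
                                     scaled=("LR", "SVM", "ANN"),
                                     random_state=0).fit(X[tr], y[tr])
            best_base_auc = max(best_base_auc, sc.score(X[te], y[te]))
        stack = ScreeningClassifier(name="Stacking", grids="compact",
                                    scaled=("LR", "SVM", "ANN"),
                                    random_state=0).fit(X[tr], y[tr])
        assert stack.score(X[te], y[te]) >= best_base_auc - 0.05


class TestEvaluate:
    @pytest.fixture(scope="class")
    def result(self, small_matrix):
        return evaluate(small_matrix, layers=(1, 2), classifiers=("LR", "RF"),
                        n_repeats=2, seed=0, grids="compact", cv=5)

    def test_result_table_shape(self, result):
        assert len(result.results) == 2 * 2 * 2
        assert set(result.results["classifier"]) == {"LR", "RF"}
        assert ((result.results["train_auc"] >= 0)
                & (result.results["train_auc"] <= 1)).all()

    def test_stratification_within_one_subject(self, small_matrix):
        splits = stratified_splits(small_matrix.y, 3, 0.2, seed=0)
        prev = small_matrix.y.mean()
        for tr, te in splits:
            n_pos = small_matrix.y.loc[te].sum()
            assert abs(n_pos - prev * len(te)) <= 1

    def test_summary_aggregates_repeats(self, result):
        s = result.summary()
        assert set(s.index.get_level_values("layer")) == {1, 2}
        row = result.results.query("layer == 1 and classifier == 'LR'")
        assert s.loc[(1, "LR"), "test_auc"] == pytest.approx(row["test_auc"].mean())

    def test_importance_covers_layer_features(self, result):
        imp = result.importances
        lr1 = imp.query("layer == 1 and classifier == 'LR'")
        # layer 1 = 5 numeric demographics + 3 one-hot MPS levels
        assert len(lr1) == 8
        assert lr1["rank"].tolist() == list(range(1, 9))

    def test_missing_class_rejected(self, small_matrix):
        bad = small_matrix.subset(small_matrix.feature_names)
        bad.y[:] = 1
        with pytest.raises(ValueError):
            evaluate(bad, layers=(1,), classifiers=("LR",), n_repeats=1)


class TestImportance:
    def _planted(self, rng, n=200, n_noise=10):
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack(
            [rng.normal(0, 1, n) + 3.0 * y]
            + [rng.normal(size=n) for _ in range(n_noise)])
        names = ["signal"] + [f"noise_{i}" for i in range(n_noise)]
        return X, y, names

    @pytest.mark.parametrize("name", ["LR", "RF", "XGB"])
    def test_planted_feature_ranks_first(self, rng, name):
        X, y, names = self._planted(rng)
        sc = ScreeningClassifier(name=name, grids="compact",
                                 random_state=0).fit(X, y, feature_names=names)
        imp = feature_importance(sc)
        assert imp.iloc[0]["feature"] == "signal"

    def test_rf_noise_importance_roughly_uniform(self, rng):
        n_feat = 50
        X = rng.normal(size=(200, n_feat))
        y = np.array([0, 1] * 100)
        sc = ScreeningClassifier(name="RF", grids="compact",
                                 random_state=0).fit(X, y)
        imp = feature_importance(sc)
        assert imp["score"].max() < 3.0 / n_feat

    @pytest.mark.parametrize("name", ["SVM", "ANN", "Stacking"])
    def test_unsupported_classifiers_raise(self, rng, name):
        X, y = separable_data(rng)
        sc = ScreeningClassifier(name=name, grids="compact", random_state=0)
        sc.fit(X, y)
        with pytest.raises(ValueError, match="importance"):
            feature_importance(sc)


class TestLeakage:
    def test_scrambled_test_labels_change_no_fitted_parameter(self, small_matrix):
        splits = stratified_splits(small_matrix.y, 1, 0.2, seed=3)
        tr, te = splits[0]
        scrambled = small_matrix.subset(small_matrix.feature_names)
        rng = np.random.default_rng(0)
        scrambled.y.loc[te] = rng.permutation(1 - scrambled.y.loc[te].to_numpy())
        res_a = evaluate(small_matrix, layers=(1,), classifiers=("LR",),
                         n_repeats=1, seed=3, grids="compact", cv=5,
                         splits=splits)
        res_b = evaluate(scrambled, layers=(1,), classifiers=("LR",),
                         n_repeats=1, seed=3, grids="compact", cv=5,
                         splits=splits)
        a, b = res_a.results.iloc[0], res_b.results.iloc[0]
        assert a["best_params"] == b["best_params"]
        assert a["train_auc"] == b["train_auc"]

    def test_end_to_end_determinism(self, small_matrix):
        kw = dict(layers=(1, 2), classifiers=("LR", "XGB"), n_repeats=2,
                  seed=11, grids="compact", cv=5)
        a = evaluate(small_matrix, **kw).to_json()
        b = evaluate(small_matrix, **kw).to_json()
        assert a == b

    def test_json_roundtrip(self, small_matrix, tmp_path):
        res = evaluate(small_matrix, layers=(1,), classifiers=("LR",),
                       n_repeats=1, seed=0, grids="compact", cv=5)
        res.to_json(tmp_path / "eval.json")
        payload = json.loads((tmp_path / "eval.json").read_text())
        assert payload["seed"] == 0
        assert "layer1/LR" in payload["summary"]
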