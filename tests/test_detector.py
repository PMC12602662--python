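import numpy as np
import pytest

from irpclean.core_io import ValidationError
from irpclean.detector import (
    CaseData,
    CompatibilityError,
    TrainConfig,
    TrainedDetector,
    oversample_minority,
    predict_proba,
    split_cases,
    train_final,
    tune_hyperparameters,
)
from irpclean.features import FeatureMatrix, FeatureSchema

TINY_SPACE = {"n_estimators": (30, 30), "max_depth": (4, 4),
              "learning_rate": (0.2, 0.2), "subsample": (1.0, 1.0),
              "colsample": (1.0, 1.0)}


def tiny_config(**kw):
    defaults = dict(search_space=dict(TINY_SPACE), search_trials=1,
                    cv_folds=3, tuning_row_cap=None)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSplitCases:
    def test_eighty_twenty_case_split(self):
        ids = [f"c{i}" for i in range(20)]
        train, holdout = split_cases(ids, 0.8, seed=1)
        assert len(train) == 16 and len(holdout) == 4
        assert set(train) | set(holdout) == set(ids)
        assert set(train) & set(holdout) == set()

    def test_same_seed_same_partition(self):
        ids = [f"c{i}" for i in range(13)]
        assert split_cases(ids, 0.7, 5) == split_cases(ids, 0.7, 5)

    def test_two_cases_always_one_per_side(self):
        train, holdout = split_cases(["a", "b"], 0.8, seed=0)
        assert len(train) == 1 and len(holdout) == 1

    def test_single_case_rejected(self):
        with pytest.raises(ValidationError):
            split_cases(["a"], 0.8, seed=0)


class TestOversampling:
    def _data(self, rng, n_neg, n_pos, pos_pressure=10.0):
        X = np.vstack([rng.normal(0, 1, (n_neg, 5)), rng.normal(3, 1, (n_pos, 5))])
        y = np.concatenate([np.zeros(n_neg, np.int8), np.ones(n_pos, np.int8)])
        p = np.concatenate([np.full(n_neg, 10.0), np.full(n_pos, pos_pressure)])
        return X, y, p

    def test_smote_balances_classes(self, rng):
        X, y, p = self._data(rng, 900, 100)
        cfg = TrainConfig(hp_oversample_factor=1)
        X2, y2 = oversample_minority(X, y, p, cfg, seed=0)
        assert (y2 == 1).sum() == 900 and (y2 == 0).sum() == 900

    def test_balanced_input_unchanged_counts(self, rng):
        X, y, p = self._data(rng, 80, 80)
        cfg = TrainConfig(hp_oversample_factor=1)
        X2, y2 = oversample_minority(X, y, p, cfg, seed=0)
        assert X2.shape == X.shape and (y2 == 1).sum() == 80

    def test_high_pressure_duplication_arithmetic(self, rng):
        # balanced input isolates stage 2: 10 high-pressure positives at
        # factor 3 gain exactly 20 additional copies
        X, y, p = self._data(rng, 50, 50)
        p[50:60] = 45.0  # 10 artifact rows above the 30 mmHg threshold
        cfg = TrainConfig(hp_oversample_factor=3)
        X2, y2 = oversample_minority(X, y, p, cfg, seed=0)
        assert len(y2) == 120
        assert (y2 == 1).sum() == 70 and (y2 == 0).sum() == 50

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 5))
        with pytest.raises(ValidationError):
            oversample_minority(X, np.zeros(50), np.full(50, 10.0), TrainConfig(), 0)

    def test_tiny_minority_falls_back_to_duplication(self, rng):
        X, y, p = self._data(rng, 100, 3)  # minority < k+1 = 6
        with pytest.warns(UserWarning, match="duplication"):
            X2, y2 = oversample_minority(X, y, p, TrainConfig(hp_oversample_factor=1), 0)
        assert (y2 == 1).sum() == 100

    def test_synthetic_rows_interpolate_minority_neighbors(self, rng):
        X, y, p = self._data(rng, 400, 50)
        cfg = TrainConfig(hp_oversample_factor=1)
        X2, y2 = oversample_minority(X, y, p, cfg, seed=0)
        pos = X2[y2 == 1]
        lo, hi = X[y == 1].min(axis=0), X[y == 1].max(axis=0)
        assert np.all(pos >= lo - 1e-9) and np.all(pos <= hi + 1e-9)


class TestTuning:
    def test_collapsed_space_returns_that_point(self, toy_cases):
        result = tune_hyperparameters(toy_cases, tiny_config())
        assert result.best_params["n_estimators"] == 30
        assert result.best_params["max_depth"] == 4
        assert len(result.best_fold_scores) == 3

    def test_separable_spikes_reach_high_f1(self, toy_cases):
        result = tune_hyperparameters(toy_cases, tiny_config())
        assert result.best_mean_f1 >= 0.99

    def test_search_is_deterministic(self, toy_cases):
        cfg = tiny_config(search_trials=4, search_space={
            "n_estimators": (20, 60), "max_depth": (3, 6),
            "learning_rate": (0.05, 0.3), "subsample": (0.7, 1.0),
            "colsample": (0.7, 1.0)})
        a = tune_hyperparameters(toy_cases, cfg)
        b = tune_hyperparameters(toy_cases, cfg)
        assert a.best_params == b.best_params
        assert a.best_mean_f1 == b.best_mean_f1

    def test_holdout_cases_never_accessed(self, toy_cases):
        accessed = []

        class Logged(dict):
            def __getitem__(self, key):
                accessed.append(key)
                return dict.__getitem__(self, key)

        cases = Logged(toy_cases)
        train_ids = sorted(cases)[:4]
        holdout_ids = sorted(cases)[4:]
        tune_hyperparameters(cases, tiny_config(), case_ids=train_ids)
        assert set(accessed) == set(train_ids)
        assert not set(accessed) & set(holdout_ids)

    def test_oversampling_confined_to_training_folds(self, toy_cases, monkeypatch):
        import irpclean.detector as det

        sizes = []
        orig = det.oversample_minority

        def spy(X, y, p, cfg, seed):
            sizes.append(len(y))
            return orig(X, y, p, cfg, seed)

        monkeypatch.setattr(det, "oversample_minority", spy)
        cfg = tiny_config()
        tune_hyperparameters(toy_cases, cfg)
        n_total = sum(len(c.y) for c in toy_cases.values())
        assert len(sizes) == cfg.cv_folds
        # each call sees only the training part of one fold
        for s in sizes:
            assert s < n_total


@pytest.fixture(scope="module")
def fitted(toy_cases):
    cfg = tiny_config()
    result = tune_hyperparameters(toy_cases, cfg)
    return train_final(toy_cases, result.best_params, cfg), cfg


@pytest.mark.parametrize("kind", ["random_forest", "xgboost", "lightgbm"])
def test_each_model_kind_discriminates_on_synthetic_cohort(small_cohort, kind):
    """All three tree ensembles reach high sample-level AUC on held-out
    cases of a (scaled) calibrated synthetic cohort."""
    from irpclean.evaluate import rank_auc

    data = {c.trace.case_id: CaseData.from_trace(c.trace, c.truth) for c in small_cohort}
    train_ids, test_ids = split_cases(sorted(data), 0.8, seed=0)
    cfg = TrainConfig(model_kind=kind, tuning_row_cap=None)
    det = train_final(data, {"n_estimators": 60, "max_depth": 6}, cfg, case_ids=train_ids)
    truth = np.concatenate([data[c].y for c in test_ids])
    prob = np.concatenate([
        predict_proba(det, FeatureMatrix(c, data[c].X, data[c].schema)) for c in test_ids
    ])
    assert rank_auc(truth, prob) >= 0.90


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["random_forest", "xgboost", "lightgbm"])
    def test_all_three_model_kinds_train(self, toy_cases, kind):
        cfg = tiny_config(model_kind=kind)
        det = train_final(toy_cases, {"n_estimators": 25, "max_depth": 4}, cfg)
        cid = sorted(toy_cases)[0]
        fm = FeatureMatrix(cid, toy_cases[cid].X, toy_cases[cid].schema)
        prob = predict_proba(det, fm)
        assert prob.shape == (toy_cases[cid].X.shape[0],)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_probabilities_separate_spikes(self, fitted, toy_cases):
        det, _ = fitted
        cid = sorted(toy_cases)[0]
        case = toy_cases[cid]
        prob = predict_proba(det, FeatureMatrix(cid, case.X, case.schema))
        spikes = case.y == 1
        assert prob[spikes].min() >= 0.9
        assert np.median(prob[~spikes]) <= 0.1

    def test_retrain_reproduces_probabilities(self, toy_cases):
        cfg = tiny_config()
        params = {"n_estimators": 25, "max_depth": 4}
        cid = sorted(toy_cases)[0]
        fm = FeatureMatrix(cid, toy_cases[cid].X, toy_cases[cid].schema)
        p1 = predict_proba(train_final(toy_cases, params, cfg), fm)
        p2 = predict_proba(train_final(toy_cases, params, cfg), fm)
        np.testing.assert_array_equal(p1, p2)

    def test_bundle_round_trip_preserves_predictions(self, fitted, toy_cases, tmp_path):
        det, _ = fitted
        cid = sorted(toy_cases)[0]
        fm = FeatureMatrix(cid, toy_cases[cid].X, toy_cases[cid].schema)
        before = predict_proba(det, fm)
        det.save(tmp_path / "model.bundle")
        loaded = TrainedDetector.load(tmp_path / "model.bundle")
        np.testing.assert_array_equal(predict_proba(loaded, fm), before)
        assert loaded.params == det.params

    def test_empty_feature_matrix_gives_empty_output(self, fitted):
        det, _ = fitted
        fm = FeatureMatrix("empty", np.empty((0, 32)), FeatureSchema())
        assert predict_proba(det, fm).size == 0

    def test_schema_mismatch_rejected(self, fitted, toy_cases):
        det, _ = fitted
        cid = sorted(toy_cases)[0]
        old = FeatureSchema(version="0.0")
        fm = FeatureMatrix(cid, toy_cases[cid].X, old)
        with pytest.raises(CompatibilityError):
            predict_proba(det, fm)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(model_kind="svm")
        with pytest.raises(ValidationError):
            TrainConfig(train_fraction_cases=1.0)
        with pytest.raises(ValidationError):
            TrainConfig(cv_folds=1)
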