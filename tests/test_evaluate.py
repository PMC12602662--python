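import numpy as np
import pytest

from irpclean.core_io import AnnotationTrack, PressureTrace
from irpclean.detector import train_final
from irpclean.evaluate import (
    evaluate,
    feature_attribution_summary,
    fn_duration_by_bin,
    fn_seconds_above,
    rank_auc,
    timing_report,
)
from irpclean.features import FEATURE_NAMES, FeatureSchema

from oracles import pairwise_auc


def tracks(case_id, truth, pred, pressure):
    return (
        {case_id: AnnotationTrack(case_id, pred, source="predicted")},
        {case_id: AnnotationTrack(case_id, truth, source="simulated")},
        {case_id: PressureTrace(case_id, pressure)},
    )


class TestMetrics:
    def test_perfect_predictions(self):
        truth = np.array([1, 1, 0, 0, 1, 0], dtype=np.int8)
        pred, tru, trc = tracks("c", truth, truth, np.full(6, 50.0))
        report = evaluate(pred, {"c": truth.astype(float)}, tru, trc, bootstrap_reps=0)
        assert report.overall["agreement_pct"]["value"] == 100.0
        assert report.overall["recall"]["value"] == 1.0
        assert report.overall["specificity"]["value"] == 1.0
        assert report.overall["auc"]["value"] == 1.0

    def test_confusion_table_arithmetic(self):
        truth = np.array([1, 1, 0, 0], dtype=np.int8)
        predicted = np.array([1, 0, 0, 0], dtype=np.int8)
        pred, tru, trc = tracks("c", truth, predicted, np.full(4, 10.0))
        report = evaluate(pred, {"c": predicted.astype(float)}, tru, trc, bootstrap_reps=0)
        assert report.overall["agreement_pct"]["value"] == 75.0
        assert report.overall["recall"]["value"] == 0.5
        assert report.overall["specificity"]["value"] == 1.0

    def test_auc_ranks_all_positives_above_negatives(self):
        truth = np.array([1, 1, 0, 0], dtype=np.int8)
        prob = np.array([0.9, 0.4, 0.2, 0.1])
        assert rank_auc(truth, prob) == 1.0

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 2, 40).astype(np.int8)
            if truth.min() == truth.max():
                continue
            scores = np.round(rng.uniform(0, 1, 40), 2)  # induces ties
            assert abs(rank_auc(truth, scores) - pairwise_auc(truth, scores)) < 1e-12

    def test_auc_invariant_under_monotone_transform(self, rng):
        truth = rng.integers(0, 2, 200).astype(np.int8)
        prob = rng.uniform(0, 1, 200)
        a = rank_auc(truth, prob)
        assert abs(rank_auc(truth, prob**3) - a) < 1e-12
        assert abs(rank_auc(truth, np.sqrt(prob)) - a) < 1e-12

    def test_single_class_truth_reports_undefined_auc(self):
        truth = np.zeros(10, dtype=np.int8)
        pred, tru, trc = tracks("c", truth, truth, np.full(10, 10.0))
        report = evaluate(pred, {"c": np.zeros(10)}, tru, trc, bootstrap_reps=0)
        assert report.overall["auc"]["value"] is None

    def test_high_pressure_stratum_separated(self):
        truth = np.array([1, 1, 0, 0], dtype=np.int8)
        predicted = np.array([0, 1, 0, 0], dtype=np.int8)
        pressure = np.array([10.0, 50.0, 50.0, 10.0])  # only middle two are HP
        pred, tru, trc = tracks("c", truth, predicted, pressure)
        report = evaluate(pred, {"c": predicted.astype(float)}, tru, trc, bootstrap_reps=0)
        assert report.high_pressure["agreement_pct"]["value"] == 100.0
        assert report.overall["agreement_pct"]["value"] == 75.0

    def test_pooled_equals_sum_of_per_case_confusions(self, rng):
        preds, trus, trcs, probs = {}, {}, {}, {}
        per_case = np.zeros(4, dtype=int)
        for i in range(4):
            n = int(rng.integers(30, 80))
            truth = rng.integers(0, 2, n).astype(np.int8)
            predicted = rng.integers(0, 2, n).astype(np.int8)
            cid = f"c{i}"
            preds[cid] = AnnotationTrack(cid, predicted, source="predicted")
            trus[cid] = AnnotationTrack(cid, truth, source="simulated")
            trcs[cid] = PressureTrace(cid, rng.uniform(0, 100, n))
            probs[cid] = predicted.astype(float)
            per_case += np.array([
                ((truth == 1) & (predicted == 1)).sum(),
                ((truth == 0) & (predicted == 1)).sum(),
                ((truth == 0) & (predicted == 0)).sum(),
                ((truth == 1) & (predicted == 0)).sum(),
            ])
        report = evaluate(preds, probs, trus, trcs, bootstrap_reps=0)
        conf = report.overall["confusion"]
        assert [conf["tp"], conf["fp"], conf["tn"], conf["fn"]] == per_case.tolist()


class TestBootstrap:
    def test_ci_contains_point_and_shrinks_with_n(self, rng):
        widths = []
        for n in (200, 3200):
            truth = rng.integers(0, 2, n).astype(np.int8)
            predicted = np.where(rng.uniform(size=n) < 0.8, truth, 1 - truth).astype(np.int8)
            prob = np.clip(predicted + rng.normal(0, 0.3, n), 0, 1)
            pred, tru, trc = tracks("c", truth, predicted, np.full(n, 10.0))
            report = evaluate(pred, {"c": prob}, tru, trc, bootstrap_reps=300, seed=1)
            m = report.overall["agreement_pct"]
            lo, hi = m["ci95"]
            assert lo <= m["value"] <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestFalseNegativeDurations:
    def test_perfect_predictions_give_all_zero(self):
        truth = np.array([1, 1, 0, 0], dtype=np.int8)
        pred, tru, trc = tracks("c", truth, truth, np.full(4, 50.0))
        out = fn_duration_by_bin(pred, tru, trc)
        assert all(v == 0.0 for v in out["per_case"]["c"].values())

    def test_missed_artifact_lands_in_its_pressure_bin(self):
        n = 40
        truth = np.zeros(n, dtype=np.int8)
        truth[10:18] = 1  # 8 samples = 2.0 s
        predicted = np.zeros(n, dtype=np.int8)
        pressure = np.full(n, 10.0)
        pressure[10:18] = 65.0
        pred, tru, trc = tracks("c", truth, predicted, pressure)
        out = fn_duration_by_bin(pred, tru, trc)
        assert out["per_case"]["c"]["60-79"] == 2.0
        assert out["per_case"]["c"]["30-39"] == 0.0
        assert out["fraction_missed_below_30"] == 0.0
        assert fn_seconds_above(pred["c"], tru["c"], trc["c"], 60.0) == 2.0

    def test_low_pressure_miss_fraction(self):
        truth = np.array([1, 1, 1, 1], dtype=np.int8)
        predicted = np.array([0, 0, 0, 1], dtype=np.int8)
        pressure = np.array([10.0, 10.0, 50.0, 50.0])
        pred, tru, trc = tracks("c", truth, predicted, pressure)
        out = fn_duration_by_bin(pred, tru, trc)
        assert out["fraction_missed_below_30"] == pytest.approx(2 / 3)


class TestAttribution:
    def _informative_cases(self, rng, kind):
        # label depends only on pressure_abs (column 0); all other features
        # are noise, one is constant
        from irpclean.detector import CaseData, TrainConfig

        cases = {}
        for i in range(3):
            n = 400
            X = rng.normal(0, 1, (n, 32)).astype(np.float32)
            X[:, 5] = 0.0  # constant feature
            y = (rng.uniform(size=n) < 0.3).astype(np.int8)
            X[:, 0] = np.where(y == 1, 200.0, 10.0) + rng.normal(0, 1, n)
            cases[f"c{i}"] = CaseData(f"c{i}", X, y, X[:, 0].astype(float))
        cfg = TrainConfig(model_kind=kind, hp_oversample_factor=1)
        det = train_final(cases, {"n_estimators": 30, "max_depth": 4}, cfg)
        Xs = np.vstack([c.X for c in cases.values()])
        return det, Xs

    @pytest.mark.parametrize("kind", ["lightgbm", "xgboost", "random_forest"])
    def test_single_informative_feature_dominates(self, rng, kind):
        det, Xs = self._informative_cases(rng, kind)
        out = feature_attribution_summary(det, Xs[:500])
        assert out["shares"]["pressure_abs"] > 0.9
        assert abs(sum(out["shares"].values()) - 1.0) <= 1e-6
        assert out["shares"][FEATURE_NAMES[5]] < 0.01  # constant feature
        assert out["ranked"][0][0] == "pressure_abs"


class TestTiming:
    def test_one_row_per_case_and_stable_count(self, toy_cases, rng):
        from irpclean.detector import TrainConfig

        cfg = TrainConfig(model_kind="lightgbm")
        det = train_final(toy_cases, {"n_estimators": 10, "max_depth": 3}, cfg)
        traces = [PressureTrace(f"t{i}", np.abs(rng.normal(15, 5, 300))) for i in range(3)]
        r1 = timing_report(det, traces, manual_minutes_per_case=56.6)
        r2 = timing_report(det, traces)
        assert len(r1["per_case"]) == 3
        assert len(r2["per_case"]) == len(r1["per_case"])
        assert r1["manual_minutes_per_case"] == 56.6
        assert all(row["seconds"] >= 0 for row in r1["per_case"])
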