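"""End-to-end orchestration: simulate, train, post-process, evaluate.

The benchmark protocol mirrors the clinical study design on synthetic
data: a cohort is split case-wise into training and held-out test cases;
the training cases are further split 80/20 into model-training and
internal-validation cases; hyperparameters are tuned by cross-validation
on the model-training cases; the final model is refit there; the
post-processing pipeline is optimized on the internal-validation cases;
and all reported metrics come from the untouched test cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AnnotationTrack, PressureTrace
from .detector import (
    CaseData,
    TrainConfig,
    TrainedDetector,
    predict_proba,
    split_cases,
    train_final,
    tune_hyperparameters,
)
from .evaluate import EvalReport, evaluate, fn_seconds_above
from .features import FeatureMatrix
from .postprocess import optimize_postprocess, postprocess
from .simulate import SimCase, SimConfig, simulate_cohort


@dataclass
class BenchmarkResult:
    detector: TrainedDetector
    report: EvalReport
    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    predicted: dict[str, AnnotationTrack]
    probabilities: dict[str, np.ndarray]
    metrics: dict = field(default_factory=dict)


def prepare_cases(cases: list[SimCase]) -> dict[str, CaseData]:
    return {
        c.trace.case_id: CaseData.from_trace(c.trace, c.truth) for c in cases
    }


def run_benchmark(
    sim_config: SimConfig = SimConfig(),
    train_config: TrainConfig = TrainConfig(),
    test_fraction: float = 7.0 / 27.0,
    postprocess_budget: int = 60,
    bootstrap_reps: int = 1000,
) -> BenchmarkResult:
    """Run the full synthetic benchmark and return detector + evaluation."""
    cohort = simulate_cohort(sim_config)
    by_id = {c.trace.case_id: c for c in cohort}
    data = prepare_cases(cohort)
    ids = sorted(data)

    train_all, test_ids = split_cases(ids, 1.0 - test_fraction, seed=sim_config.seed)
    train_ids, val_ids = split_cases(
        train_all, train_config.train_fraction_cases, seed=train_config.cv_seed
    )

    tune = tune_hyperparameters(data, train_config, case_ids=train_ids)
    detector = train_final(
        data, tune.best_params, train_config,
        case_ids=train_ids, fold_scores=tune.best_fold_scores,
    )

    # optimize post-processing on the internal-validation cases
    val_probs, val_truth, val_pres = [], [], []
    for cid in val_ids:
        fm = FeatureMatrix(cid, data[cid].X, data[cid].schema)
        val_probs.append(predict_proba(detector, fm))
        val_truth.append(data[cid].y)
        val_pres.append(data[cid].pressure)
    detector.postprocess_params = optimize_postprocess(
        val_probs, val_truth, val_pres,
        budget=postprocess_budget, seed=train_config.cv_seed,
    )

    # predict the held-out test cases
    probabilities: dict[str, np.ndarray] = {}
    predicted: dict[str, AnnotationTrack] = {}
    truth: dict[str, AnnotationTrack] = {}
    traces: dict[str, PressureTrace] = {}
    for cid in test_ids:
        fm = FeatureMatrix(cid, data[cid].X, data[cid].schema)
        prob = predict_proba(detector, fm)
        probabilities[cid] = prob
        predicted[cid] = postprocess(
            prob, data[cid].pressure, detector.postprocess_params, cid
        )
        truth[cid] = by_id[cid].truth
        traces[cid] = by_id[cid].trace

    report = evaluate(
        predicted, probabilities, truth, traces,
        bootstrap_reps=bootstrap_reps, seed=train_config.cv_seed,
    )

    fn60 = [
        fn_seconds_above(predicted[cid], truth[cid], traces[cid], 60.0)
        for cid in test_ids
    ]
    metrics = {
        "auc_overall": report.overall["auc"]["value"],
        "auc_high_pressure": report.high_pressure["auc"]["value"],
        "median_fn_seconds_above_60": float(np.median(fn60)),
        "agreement_pct": report.overall["agreement_pct"]["value"],
        "best_params": tune.best_params,
        "best_mean_f1": tune.best_mean_f1,
    }
    return BenchmarkResult(
        detector=detector,
        report=report,
        train_ids=train_ids,
        validation_ids=val_ids,
        test_ids=test_ids,
        predicted=predicted,
        probabilities=probabilities,
        metrics=metrics,
    )
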