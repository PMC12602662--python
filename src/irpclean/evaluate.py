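"""Evaluation of artifact detectors against ground-truth labels.

Binary metrics (agreement = sample-level accuracy in percent, recall,
specificity, F1) are computed on the *post-processed* labels pooled over
all test samples; AUC is computed rank-based from the *pre*-post-processing
probabilities, because post-processing is binary and would degenerate the
ROC.  The artifact class is positive throughout: recall is artifact
sensitivity, specificity is true-signal retention.

95% confidence intervals come from a seeded percentile bootstrap over
samples (1,000 replicates by default).  For the binary metrics the
bootstrap is drawn over the four confusion categories directly — a
multinomial over (TP, FP, TN, FN) is distributionally identical to
resampling samples, since the metrics depend only on the category counts.
AUC replicates resample sample indices.

All metrics are reported both overall and restricted to the high-pressure
stratum (samples whose *raw* pressure is >= 30 mmHg), where a missed
artifact matters most clinically.  Error analysis additionally reports the
cumulative per-case duration of missed (false-negative) artifact samples
within each clinical pressure bin.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .core_io import AnnotationTrack, PressureTrace, ValidationError
from .correct_summarize import PRESSURE_BINS
from .detector import TrainedDetector, predict_proba
from .features import extract_features
from .postprocess import postprocess

HIGH_PRESSURE_MMHG = 30.0


@dataclass(frozen=True)
class EvalReport:
    overall: dict
    high_pressure: dict
    fn_duration_by_bin: dict
    n_samples: int
    n_cases: int


def _confusion(truth: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.count_nonzero((truth == 1) & (pred == 1)))
    fp = int(np.count_nonzero((truth == 0) & (pred == 1)))
    tn = int(np.count_nonzero((truth == 0) & (pred == 0)))
    fn = int(np.count_nonzero((truth == 1) & (pred == 0)))
    return tp, fp, tn, fn


def _binary_metrics(tp: float, fp: float, tn: float, fn: float) -> dict[str, float]:
    n = tp + fp + tn + fn
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    prec = tp / (tp + fp) if tp + fp > 0 else np.nan
    f1 = (
        2 * prec * recall / (prec + recall)
        if np.isfinite(prec) and np.isfinite(recall) and (prec + recall) > 0
        else np.nan
    )
    return {
        "agreement_pct": 100.0 * (tp + tn) / n if n > 0 else np.nan,
        "recall": recall,
        "specificity": spec,
        "f1": f1,
    }


def _percentile_ci(samples: np.ndarray) -> tuple[float, float]:
    ok = samples[np.isfinite(samples)]
    if ok.size == 0:
        return (np.nan, np.nan)
    return (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))


def rank_auc(truth: np.ndarray, scores: np.ndarray) -> float | None:
    """Mann–Whitney rank AUC; None when truth has a single class."""
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        return None
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def _stratum_metrics(
    truth: np.ndarray,
    pred: np.ndarray,
    prob: np.ndarray,
    bootstrap_reps: int,
    rng: np.random.Generator,
) -> dict:
    tp, fp, tn, fn = _confusion(truth, pred)
    point = _binary_metrics(tp, fp, tn, fn)
    n = truth.size
    out: dict = {}

    if bootstrap_reps > 0 and n > 0:
        counts = rng.multinomial(n, np.array([tp, fp, tn, fn]) / n, size=bootstrap_reps)
        reps = {k: np.empty(bootstrap_reps) for k in point}
        for r in range(bootstrap_reps):
            m = _binary_metrics(*counts[r])
            for k, v in m.items():
                reps[k][r] = v
        for k in point:
            out[k] = {"value": point[k], "ci95": _percentile_ci(reps[k])}
    else:
        for k in point:
            out[k] = {"value": point[k], "ci95": (np.nan, np.nan)}

    auc = rank_auc(truth, prob)
    if auc is None:
        out["auc"] = {"value": None, "note": "undefined (single-class truth)"}
    else:
        if bootstrap_reps > 0:
            auc_reps = np.empty(bootstrap_reps)
            for r in range(bootstrap_reps):
                idx = rng.integers(0, n, size=n)
                a = rank_auc(truth[idx], prob[idx])
                auc_reps[r] = np.nan if a is None else a
            out["auc"] = {"value": auc, "ci95": _percentile_ci(auc_reps)}
        else:
            out["auc"] = {"value": auc, "ci95": (np.nan, np.nan)}
    out["confusion"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return out


def fn_duration_by_bin(
    predicted: Mapping[str, AnnotationTrack],
    truth: Mapping[str, AnnotationTrack],
    traces: Mapping[str, PressureTrace],
) -> dict:
    """Per-case cumulative seconds of missed artifact, per raw-pressure bin."""
    per_case: dict[str, dict[str, float]] = {}
    missed_below_30 = 0
    missed_total = 0
    for cid in sorted(truth):
        tr = traces[cid]
        t = truth[cid].mask
        pr = predicted[cid].mask
        if t.size != pr.size or t.size != tr.n:
            raise ValidationError(f"case {cid}: unaligned inputs")
        dt = 1.0 / tr.sampling_rate_hz
        miss = (t == 1) & (pr == 0)
        p = tr.pressure_mmHg
        row = {"<20": float(np.count_nonzero(miss & (p < 20.0)) * dt)}
        for label, lo, hi in PRESSURE_BINS:
            row[label] = float(np.count_nonzero(miss & (p >= lo) & (p < hi)) * dt)
        per_case[cid] = row
        missed_below_30 += int(np.count_nonzero(miss & (p < 30.0)))
        missed_total += int(np.count_nonzero(miss))
    labels = ["<20"] + [label for label, _, _ in PRESSURE_BINS]
    cohort = {}
    for label in labels:
        v = np.array([per_case[c][label] for c in per_case])
        cohort[label] = {
            "median": float(np.median(v)),
            "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
        }
    return {
        "per_case": per_case,
        "cohort": cohort,
        "fraction_missed_below_30": (
            missed_below_30 / missed_total if missed_total else np.nan
        ),
    }


def fn_seconds_above(
    predicted: AnnotationTrack,
    truth: AnnotationTrack,
    trace: PressureTrace,
    cut_mmHg: float,
) -> float:
    """Seconds of truth-artifact samples missed at raw pressure > cut."""
    miss = (truth.mask == 1) & (predicted.mask == 0) & (trace.pressure_mmHg > cut_mmHg)
    return float(np.count_nonzero(miss) / trace.sampling_rate_hz)


def evaluate(
    predicted: Mapping[str, AnnotationTrack],
    probabilities: Mapping[str, np.ndarray],
    truth: Mapping[str, AnnotationTrack],
    traces: Mapping[str, PressureTrace],
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Pooled sample-level evaluation over a set of cases."""
    ids = sorted(truth)
    for cid in ids:
        if cid not in predicted or cid not in probabilities or cid not in traces:
            raise ValidationError(f"case {cid}: missing predictions or trace")
    t = np.concatenate([truth[c].mask for c in ids])
    y = np.concatenate([predicted[c].mask for c in ids])
    prob = np.concatenate([np.asarray(probabilities[c], dtype=float) for c in ids])
    pres = np.concatenate([traces[c].pressure_mmHg for c in ids])
    if not (t.size == y.size == prob.size == pres.size):
        raise ValidationError("unaligned pooled arrays")

    rng = np.random.default_rng(seed)
    overall = _stratum_metrics(t, y, prob, bootstrap_reps, rng)
    hp = pres >= HIGH_PRESSURE_MMHG
    high = _stratum_metrics(t[hp], y[hp], prob[hp], bootstrap_reps, rng)
    fn_bins = fn_duration_by_bin(predicted, truth, traces)
    return EvalReport(
        overall=overall,
        high_pressure=high,
        fn_duration_by_bin=fn_bins,
        n_samples=int(t.size),
        n_cases=len(ids),
    )


# ---------------------------------------------------------------------------
# feature attribution
# ---------------------------------------------------------------------------

def _rf_path_attributions(model, X: np.ndarray) -> np.ndarray:
    """Saabas-style path attributions for a random forest.

    Each split's change in the artifact-class probability along a sample's
    decision path is credited to the split feature, averaged over trees.
    """
    n, d = X.shape
    contrib = np.zeros((n, d))
    cls1 = list(model.classes_).index(1)
    for est in model.estimators_:
        tree = est.tree_
        value = tree.value[:, 0, :]
        prob = value / value.sum(axis=1, keepdims=True)
        paths = est.decision_path(X)  # csr (n, nodes)
        indptr, indices = paths.indptr, paths.indices
        for i in range(n):
            nodes = indices[indptr[i] : indptr[i + 1]]
            for parent, child in zip(nodes[:-1], nodes[1:]):
                contrib[i, tree.feature[parent]] += prob[child, cls1] - prob[parent, cls1]
    return contrib / len(model.estimators_)


def feature_attribution_summary(detector: TrainedDetector, X: np.ndarray) -> dict:
    """Per-feature attribution shares (mean |attribution|, normalized to 1).

    LightGBM and XGBoost use their built-in exact tree-path Shapley values
    (``pred_contrib``); random forests use Saabas path attributions, which
    share the additive decomposition but credit splits locally.
    """
    X = np.asarray(X, dtype=np.float32)
    names = list(detector.schema.names)
    if detector.model_kind == "lightgbm":
        contrib = detector.model.booster_.predict(X, pred_contrib=True)[:, :-1]
    elif detector.model_kind == "xgboost":
        import xgboost as xgb

        booster = detector.model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)[:, :-1]
    elif detector.model_kind == "random_forest":
        contrib = _rf_path_attributions(detector.model, X)
    else:
        raise TypeError(f"unsupported model state: {detector.model_kind!r}")
    mean_abs = np.abs(np.asarray(contrib, dtype=float)).mean(axis=0)
    total = mean_abs.sum()
    if total <= 0:
        raise ValidationError("model produced no attributions (no splits?)")
    shares = mean_abs / total
    order = np.argsort(shares)[::-1]
    ranked = [(names[i], float(shares[i])) for i in order]
    return {
        "shares": {name: float(s) for name, s in zip(names, shares)},
        "ranked": ranked,
        "top7_cumulative": float(sum(s for _, s in ranked[:7])),
    }


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def timing_report(
    detector: TrainedDetector,
    traces: Sequence[PressureTrace],
    manual_minutes_per_case: float | None = None,
) -> dict:
    """Wall-clock seconds per case for extraction + prediction + post-processing.

    Model loading/initialization is excluded (the detector is already in
    memory).  Informational only — timings are hardware-dependent.
    """
    rows = []
    for tr in traces:
        t0 = time.perf_counter()
        fm = extract_features(tr)
        prob = predict_proba(detector, fm)
        postprocess(prob, tr.pressure_mmHg, detector.postprocess_params, tr.case_id)
        rows.append({"case_id": tr.case_id, "seconds": time.perf_counter() - t0})
    secs = np.array([r["seconds"] for r in rows])
    return {
        "per_case": rows,
        "median_seconds": float(np.median(secs)) if secs.size else np.nan,
        "manual_minutes_per_case": manual_minutes_per_case,
    }
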