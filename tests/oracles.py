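"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle restates a pipeline definition in the most literal possible
form (explicit loops, exhaustive enumeration) so the vectorized library
code is checked against an implementation that shares none of its
machinery.
"""

from __future__ import annotations

import itertools

import numpy as np


def runs_of_ones(mask) -> list[tuple[int, int]]:
    """Run-length scan for maximal runs of 1s, as half-open intervals."""
    out = []
    start = None
    for i, v in enumerate(list(mask) + [0]):
        if v == 1 and start is None:
            start = i
        elif v != 1 and start is not None:
            out.append((start, i))
            start = None
    return out


def staged_postprocess(prob, pres, params) -> np.ndarray:
    """Literal restatement of the five post-processing stages."""
    prob = list(map(float, prob))
    pres = list(map(float, pres))
    n = len(prob)
    half = params.smooth_window // 2
    sm = [
        float(np.median(prob[max(0, i - half) : min(n, i + half + 1)]))
        for i in range(n)
    ]
    binary = [1 if s >= params.threshold else 0 for s in sm]
    guard = [0] * n
    for i in range(n):
        if pres[i] >= params.hp_pressure_mmHg and max(prob[i], sm[i]) >= params.hp_threshold:
            binary[i] = 1
            guard[i] = 1
    segs = runs_of_ones(binary)
    merged: list[list[int]] = []
    for a, b in segs:
        if merged and a - merged[-1][1] <= params.merge_gap_max:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = np.zeros(n, dtype=np.int8)
    for a, b in merged:
        if b - a >= params.min_segment_len or any(guard[a:b]):
            out[a:b] = 1
    return out


def wilcoxon_exact_two_sided(diffs) -> tuple[float, float]:
    """Exhaustive signed-rank test over all 2^n sign assignments.

    Zero differences must already be removed and absolute values untied.
    Returns (W = min(W+, W-), two-sided p as 2*min-tail capped at 1).
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(len(d))
    ranks[order] = np.arange(1, len(d) + 1)
    w_plus = float(ranks[d > 0].sum())
    total = ranks.sum()

    dist = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    p_le = np.mean(dist <= w_plus)
    p_ge = np.mean(dist >= w_plus)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(min(w_plus, total - w_plus)), float(p)


def pairwise_auc(truth, scores) -> float:
    """Mann–Whitney AUC by explicit pair counting with half-credit ties."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def make_separable_case(case_id: str, n: int, rng: np.random.Generator,
                        spike_mmHg: float = 300.0):
    """Toy case: flat 10 mmHg signal with unmistakable labeled spikes."""
    from irpclean.core_io import AnnotationTrack, PressureTrace

    p = 10.0 + rng.normal(0.0, 0.5, n)
    mask = np.zeros(n, dtype=np.int8)
    for _ in range(max(2, n // 120)):
        start = int(rng.integers(5, n - 8))
        length = int(rng.integers(2, 6))
        p[start : start + length] += spike_mmHg
        mask[start : start + length] = 1
    return PressureTrace(case_id, np.maximum(p, 0.0)), AnnotationTrack(case_id, mask)
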