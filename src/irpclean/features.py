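"""Causal per-sample waveform features for artifact detection.

Thirty-two features describe each 4 Hz pressure sample through its recent
history only: every window is *trailing*, so a feature value at index ``i``
depends on samples ``<= i``.  Short histories are handled by left-padding
the series with its first value, which keeps the matrix full-length and
finite and leaves label alignment trivial.

Seven features carry the names used in the clinical artifact-detection
literature for this task (FFT dominant frequency, peak count over the last
120 points, absolute pressure, edge position of the 10-point maximum,
duration above the 30 mmHg safety threshold, maximum absolute curvature
over 10 points, and 10-point peak area).  The remaining 25 instantiate the
four standard categories — derivatives, peak shape, short-term energy, and
frequency-domain metrics — and the schema is versioned so alternative sets
can be swapped in.

Window lengths: 10 samples (2.5 s) for spike morphology, 40 samples (10 s)
for local context, 64 samples (16 s; shortest power of two resolving the
0.25 Hz respiratory band at 4 Hz) for spectra, and 120 samples (30 s) for
peak statistics and the running baseline.

:func:`feature_oracle` recomputes any single feature by a direct,
unvectorized evaluation of its definition and exists solely as an
independent check of the vectorized implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core_io import PressureTrace, ValidationError

SCHEMA_VERSION = "1.0"

EPS = 1e-6
FFT_WINDOW = 64
PEAK_PROMINENCE_MMHG = 2.0
PRESSURE_THRESHOLD_MMHG = 30.0

FEATURE_NAMES: tuple[str, ...] = (
    # features named in the clinical literature
    "pressure_abs",
    "fft_dominant_freq",
    "peak_count_120",
    "edge_max_pos_10",
    "dur_above_30",
    "abs_curv_max_10",
    "peak_area_10",
    # derivative family
    "d1",
    "d1_max_10",
    "d1_min_10",
    "d1_mean_10",
    "d1_sd_10",
    "d1_max_40",
    "d1_min_40",
    "d2",
    # peak-shape family
    "rise_from_min_10",
    "fall_from_max_10",
    "range_10",
    "range_40",
    "prominence_cur",
    "time_since_local_max_120",
    # short-term energy family
    "energy_10",
    "energy_40",
    "sd_40",
    "zscore_40",
    "mad_40",
    # frequency family
    "spectral_entropy_64",
    "hf_power_ratio_64",
    "dominant_power_ratio_64",
    "lowband_power_64",
    # context family
    "above_30_flag",
    "global_z",
)

WINDOW_LENGTHS: dict[str, int] = {
    "pressure_abs": 1, "fft_dominant_freq": 64, "peak_count_120": 120,
    "edge_max_pos_10": 10, "dur_above_30": 1, "abs_curv_max_10": 10,
    "peak_area_10": 120, "d1": 2, "d1_max_10": 10, "d1_min_10": 10,
    "d1_mean_10": 10, "d1_sd_10": 10, "d1_max_40": 40, "d1_min_40": 40,
    "d2": 3, "rise_from_min_10": 10, "fall_from_max_10": 10, "range_10": 10,
    "range_40": 40, "prominence_cur": 40, "time_since_local_max_120": 120,
    "energy_10": 10, "energy_40": 40, "sd_40": 40, "zscore_40": 40,
    "mad_40": 40, "spectral_entropy_64": 64, "hf_power_ratio_64": 64,
    "dominant_power_ratio_64": 64, "lowband_power_64": 64,
    "above_30_flag": 1, "global_z": 1,
}


@dataclass(frozen=True)
class FeatureSchema:
    names: tuple[str, ...] = FEATURE_NAMES
    window_lengths: tuple[tuple[str, int], ...] = tuple(WINDOW_LENGTHS.items())
    version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(self.names) != 32 or len(set(self.names)) != 32:
            raise ValidationError("schema must have exactly 32 unique feature names")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None


@dataclass(frozen=True)
class FeatureMatrix:
    case_id: str
    values: np.ndarray  # n x 32
    schema: FeatureSchema

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.schema.names):
            raise ValidationError("feature matrix shape must be n x 32")
        if not np.all(np.isfinite(v)):
            raise ValidationError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.schema.index(name)]

    def to_frame(self, sampling_rate_hz: float = 4.0) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.names))
        df.insert(0, "time_s", np.arange(self.n) / sampling_rate_hz)
        return df


# ---------------------------------------------------------------------------
# vectorized implementation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _peak_counts(pad: np.ndarray, n: int, window: int, prom_thr: float) -> np.ndarray:
    """Per-sample count of strict local maxima with prominence >= prom_thr
    inside the trailing window ``pad[i : i + window]`` (pad is left-padded)."""
    out = np.zeros(n)
    for i in range(n):
        base = i
        cnt = 0
        for j in range(1, window - 1):
            v = pad[base + j]
            if pad[base + j - 1] < v and v > pad[base + j + 1]:
                lmin = v
                k = j - 1
                while k >= 0 and pad[base + k] <= v:
                    if pad[base + k] < lmin:
                        lmin = pad[base + k]
                    k -= 1
                rmin = v
                k = j + 1
                while k <= window - 1 and pad[base + k] <= v:
                    if pad[base + k] < rmin:
                        rmin = pad[base + k]
                    k += 1
                if v - max(lmin, rmin) >= prom_thr:
                    cnt += 1
        out[i] = cnt
    return out


def _pad_left(x: np.ndarray, k: int, value: float) -> np.ndarray:
    return np.concatenate([np.full(k, value), x])


def _trailing_windows(x: np.ndarray, window: int, pad_value: float) -> np.ndarray:
    """(n, window) view; row i is x padded-trailing window ending at i."""
    return np.lib.stride_tricks.sliding_window_view(
        _pad_left(x, window - 1, pad_value), window
    )


def _spectral_block(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    w = _trailing_windows(p, FFT_WINDOW, p[0]).astype(float)
    w = w - w.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(w, axis=1)) ** 2  # bins 0..32
    nondc = power[:, 1:]
    tot = nondc.sum(axis=1)
    ok = tot > 1e-12
    safe_tot = np.where(ok, tot, 1.0)

    # dominant bin with a tolerant tie-break (lowest bin within 1e-9 relative
    # of the max) — near-delta windows have an almost-flat spectrum and a
    # strict argmax would be decided by roundoff
    maxv = nondc.max(axis=1)
    kmax = np.argmax(nondc >= maxv[:, None] * (1.0 - 1e-9), axis=1) + 1
    freq = np.where(ok, kmax * (4.0 / FFT_WINDOW), 0.0)

    q = nondc / safe_tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1) / np.log(nondc.shape[1])
    ent = np.where(ok, ent, 0.0)

    # bin k maps to frequency k * 4/64 Hz; "> 0.5 Hz" starts at bin 9
    hf = np.where(ok, nondc[:, 8:].sum(axis=1) / safe_tot, 0.0)
    dom = np.where(ok, nondc.max(axis=1) / safe_tot, 0.0)
    low = np.where(ok, nondc[:, :8].sum(axis=1) / FFT_WINDOW, 0.0)
    return freq, ent, hf, dom, low


def extract_features(trace: PressureTrace) -> FeatureMatrix:
    """Compute the full n x 32 feature matrix for one trace."""
    p = np.asarray(trace.pressure_mmHg, dtype=float)
    n = p.size
    if n < 1:
        raise ValidationError("trace must have n >= 1")
    schema = FeatureSchema()
    out = np.empty((n, 32))
    col = {name: i for i, name in enumerate(schema.names)}

    p0 = p[0]
    w10 = _trailing_windows(p, 10, p0)
    w40 = _trailing_windows(p, 40, p0)
    w120 = _trailing_windows(p, 120, p0)

    out[:, col["pressure_abs"]] = p
    out[:, col["above_30_flag"]] = (p > PRESSURE_THRESHOLD_MMHG).astype(float)

    # duration (samples) of the current contiguous run with p > 30
    above = p > PRESSURE_THRESHOLD_MMHG
    idx = np.arange(n)
    last_below = np.maximum.accumulate(np.where(~above, idx, -1))
    out[:, col["dur_above_30"]] = np.where(above, idx - last_below, 0.0)

    # first and second differences of the left-padded series
    d1 = np.diff(p, prepend=p0)
    d2 = np.diff(d1, prepend=0.0)
    out[:, col["d1"]] = d1
    out[:, col["d2"]] = d2
    dw10 = _trailing_windows(d1, 10, 0.0)
    dw40 = _trailing_windows(d1, 40, 0.0)
    out[:, col["d1_max_10"]] = dw10.max(axis=1)
    out[:, col["d1_min_10"]] = dw10.min(axis=1)
    out[:, col["d1_mean_10"]] = dw10.mean(axis=1)
    out[:, col["d1_sd_10"]] = dw10.std(axis=1)
    out[:, col["d1_max_40"]] = dw40.max(axis=1)
    out[:, col["d1_min_40"]] = dw40.min(axis=1)

    cw10 = _trailing_windows(np.abs(d2), 10, 0.0)
    out[:, col["abs_curv_max_10"]] = cw10.max(axis=1)

    mx10 = w10.max(axis=1)
    mn10 = w10.min(axis=1)
    out[:, col["edge_max_pos_10"]] = np.argmax(w10, axis=1).astype(float)
    out[:, col["rise_from_min_10"]] = p - mn10
    out[:, col["fall_from_max_10"]] = mx10 - p
    out[:, col["range_10"]] = mx10 - mn10
    out[:, col["range_40"]] = w40.max(axis=1) - w40.min(axis=1)

    med40 = np.median(w40, axis=1)
    out[:, col["prominence_cur"]] = p - med40
    out[:, col["mad_40"]] = np.median(np.abs(w40 - med40[:, None]), axis=1)

    mean10 = w10.mean(axis=1)
    out[:, col["energy_10"]] = ((w10 - mean10[:, None]) ** 2).mean(axis=1)
    mean40 = w40.mean(axis=1)
    energy40 = ((w40 - mean40[:, None]) ** 2).mean(axis=1)
    sd40 = np.sqrt(energy40)
    out[:, col["energy_40"]] = energy40
    out[:, col["sd_40"]] = sd40
    out[:, col["zscore_40"]] = (p - mean40) / (sd40 + EPS)

    # strict local maxima usable at index i are those at j <= i - 1
    lm = np.zeros(n, dtype=bool)
    if n >= 2:
        pprev = np.concatenate(([p0], p[:-1]))
        pnext = np.concatenate((p[1:], [np.nan]))
        lm[:-1] = (pprev[:-1] < p[:-1]) & (p[:-1] > pnext[:-1])
    lm_idx = np.where(lm, idx, -(10**9))
    run_max = np.maximum.accumulate(lm_idx)
    prev_peak = np.concatenate(([-(10**9)], run_max[:-1]))
    out[:, col["time_since_local_max_120"]] = np.minimum(idx - prev_peak, 120.0)

    out[:, col["peak_count_120"]] = _peak_counts(
        _pad_left(p, 119, p0), n, 120, PEAK_PROMINENCE_MMHG
    )

    # peak area above the trailing-120-sample running-median baseline
    baseline = np.median(w120, axis=1)
    excess = np.maximum(p - baseline, 0.0)
    ew10 = _trailing_windows(excess, 10, 0.0)
    out[:, col["peak_area_10"]] = ew10.sum(axis=1)

    freq, ent, hf, dom, low = _spectral_block(p)
    out[:, col["fft_dominant_freq"]] = freq
    out[:, col["spectral_entropy_64"]] = ent
    out[:, col["hf_power_ratio_64"]] = hf
    out[:, col["dominant_power_ratio_64"]] = dom
    out[:, col["lowband_power_64"]] = low

    # causal robust z against the expanding median / expanding MAD
    s = pd.Series(p)
    m = s.expanding().median().to_numpy()
    mad = pd.Series(np.abs(p - m)).expanding().median().to_numpy()
    out[:, col["global_z"]] = (p - m) / (mad + EPS)

    return FeatureMatrix(trace.case_id, out, schema)


# ---------------------------------------------------------------------------
# unvectorized oracle
# ---------------------------------------------------------------------------

def _owin(p: np.ndarray, i: int, k: int) -> np.ndarray:
    """Trailing window of length k ending at i, left-padded with p[0]."""
    lo = i - k + 1
    if lo >= 0:
        return p[lo : i + 1].astype(float)
    return np.concatenate([np.full(-lo, p[0]), p[: i + 1]]).astype(float)


def _opad(p: np.ndarray, j: int) -> float:
    return float(p[j]) if j >= 0 else float(p[0])


def _od1(p: np.ndarray, j: int) -> float:
    return _opad(p, j) - _opad(p, j - 1)


def _od2(p: np.ndarray, j: int) -> float:
    return _opad(p, j) - 2.0 * _opad(p, j - 1) + _opad(p, j - 2)


def _ospectrum(p: np.ndarray, i: int):
    w = _owin(p, i, FFT_WINDOW)
    w = w - w.mean()
    power = np.abs(np.fft.rfft(w)) ** 2
    nondc = power[1:]
    tot = float(nondc.sum())
    return nondc, tot


def feature_oracle(trace: PressureTrace, i: int, name: str) -> float:
    """One feature value computed directly from its definition (slow path)."""
    p = np.asarray(trace.pressure_mmHg, dtype=float)
    n = p.size
    if not 0 <= i < n:
        raise IndexError(f"index {i} out of range for n={n}")
    if name not in FEATURE_NAMES:
        raise KeyError(f"unknown feature {name!r}")

    if name == "pressure_abs":
        return float(p[i])
    if name == "above_30_flag":
        return float(p[i] > PRESSURE_THRESHOLD_MMHG)
    if name == "dur_above_30":
        if p[i] <= PRESSURE_THRESHOLD_MMHG:
            return 0.0
        run = 0
        j = i
        while j >= 0 and p[j] > PRESSURE_THRESHOLD_MMHG:
            run += 1
            j -= 1
        return float(run)
    if name == "d1":
        return _od1(p, i)
    if name == "d2":
        return _od2(p, i)
    if name in ("d1_max_10", "d1_min_10", "d1_mean_10", "d1_sd_10", "d1_max_40", "d1_min_40"):
        k = 10 if name.endswith("_10") else 40
        vals = np.array([_od1(p, j) for j in range(i - k + 1, i + 1)])
        if name.startswith("d1_max"):
            return float(vals.max())
        if name.startswith("d1_min"):
            return float(vals.min())
        if name == "d1_mean_10":
            return float(vals.mean())
        return float(vals.std())
    if name == "abs_curv_max_10":
        return float(max(abs(_od2(p, j)) for j in range(i - 9, i + 1)))
    if name == "edge_max_pos_10":
        w = _owin(p, i, 10)
        best = 0
        for j in range(1, 10):
            if w[j] > w[best]:
                best = j
        return float(best)
    if name in ("rise_from_min_10", "fall_from_max_10", "range_10", "range_40"):
        k = 40 if name == "range_40" else 10
        w = _owin(p, i, k)
        if name == "rise_from_min_10":
            return float(p[i] - w.min())
        if name == "fall_from_max_10":
            return float(w.max() - p[i])
        return float(w.max() - w.min())
    if name == "prominence_cur":
        return float(p[i] - np.median(_owin(p, i, 40)))
    if name == "mad_40":
        w = _owin(p, i, 40)
        return float(np.median(np.abs(w - np.median(w))))
    if name in ("energy_10", "energy_40", "sd_40", "zscore_40"):
        k = 10 if name == "energy_10" else 40
        w = _owin(p, i, k)
        var = float(((w - w.mean()) ** 2).mean())
        if name.startswith("energy"):
            return var
        if name == "sd_40":
            return float(np.sqrt(var))
        return float((p[i] - w.mean()) / (np.sqrt(var) + EPS))
    if name == "time_since_local_max_120":
        for j in range(i - 1, 0, -1):
            if i - j > 120:
                break
            if _opad(p, j - 1) < p[j] > p[j + 1]:
                return float(min(i - j, 120))
        return 120.0
    if name == "peak_count_120":
        w = _owin(p, i, 120)
        cnt = 0
        for j in range(1, 119):
            v = w[j]
            if not (w[j - 1] < v and v > w[j + 1]):
                continue
            left = [w[k] for k in range(j - 1, -1, -1)]
            lvals = []
            for x in left:
                if x > v:
                    break
                lvals.append(x)
            right = []
            for k in range(j + 1, 120):
                if w[k] > v:
                    break
                right.append(w[k])
            lmin = min(lvals) if lvals else v
            rmin = min(right) if right else v
            if v - max(lmin, rmin) >= PEAK_PROMINENCE_MMHG:
                cnt += 1
        return float(cnt)
    if name == "peak_area_10":
        total = 0.0
        for j in range(i - 9, i + 1):
            if j < 0:
                continue  # padded region: excess over its own baseline is 0
            b = float(np.median(_owin(p, j, 120)))
            total += max(float(p[j]) - b, 0.0)
        return total
    if name == "fft_dominant_freq":
        nondc, tot = _ospectrum(p, i)
        if tot <= 1e-12:
            return 0.0
        thr = nondc.max() * (1.0 - 1e-9)
        k = next(j for j, v in enumerate(nondc) if v >= thr) + 1
        return float(k * (4.0 / FFT_WINDOW))
    if name == "spectral_entropy_64":
        nondc, tot = _ospectrum(p, i)
        if tot <= 1e-12:
            return 0.0
        q = nondc / tot
        return float(-sum(x * np.log(x) for x in q if x > 0) / np.log(len(nondc)))
    if name == "hf_power_ratio_64":
        nondc, tot = _ospectrum(p, i)
        return float(nondc[8:].sum() / tot) if tot > 1e-12 else 0.0
    if name == "dominant_power_ratio_64":
        nondc, tot = _ospectrum(p, i)
        return float(nondc.max() / tot) if tot > 1e-12 else 0.0
    if name == "lowband_power_64":
        nondc, tot = _ospectrum(p, i)
        return float(nondc[:8].sum() / FFT_WINDOW) if tot > 1e-12 else 0.0
    if name == "global_z":
        m = float(np.median(p[: i + 1]))
        devs = [abs(float(p[j]) - float(np.median(p[: j + 1]))) for j in range(i + 1)]
        mad = float(np.median(devs))
        return float((p[i] - m) / (mad + EPS))
    raise KeyError(f"unknown feature {name!r}")  # pragma: no cover
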