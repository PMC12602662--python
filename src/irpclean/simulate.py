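"""Seeded generator of labeled synthetic IRP cases.

Clinical recordings from pressure-sensing ureteroscopes are not publicly
available, so this module provides a calibrated stand-in: a cohort of
synthetic 4 Hz intrarenal-pressure traces with ground-truth contact-spike
artifact labels.  The generator is calibrated so that cohort *summary
statistics* (per-case sample count, artifact count and total artifact
seconds, artifact-free and raw maximum IRP) match the medians and
interquartile ranges reported for a 27-case clinical cohort.  It does not
attempt physiological fidelity beyond those aggregates.

The clean (artifact-free) signal is the sum, clipped at zero, of

* a per-case baseline pressure ``~ Normal(10, 3)`` mmHg,
* a slow Ornstein--Uhlenbeck drift (relaxation 300 s, stationary sd 2),
* a respiratory sinusoid near 0.25 Hz,
* irrigation episodes: Poisson arrivals, Gamma-distributed amplitude with a
  per-case scale factor, exponential rise/decay around a flat plateau of
  Uniform[5, 60] s, and
* white Gaussian sensor noise (sd 0.5 mmHg).

Contact-spike artifacts are superimposed *additively* on the clean signal
(a wall-contact spike rides on the true pressure): each has a 1--2-sample
rise, a noisy plateau whose jitter sd is drawn per artifact, a 1--2-sample
fall, and a lognormal peak amplitude.  A configurable fraction of artifacts
is placed inside irrigation episodes, concentrating them at high pressure
as observed clinically.  The truth mask marks exactly the samples where the
superimposed contribution is non-zero, so ``trace != clean  <=>  mask == 1``
holds sample-for-sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .core_io import (
    DEFAULT_RATE_HZ,
    AnnotationTrack,
    PressureTrace,
    ValidationError,
    write_annotation,
    write_trace,
)

_RATE = DEFAULT_RATE_HZ


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the published cohort aggregates (27 cases, median
    16,173 samples/case, median 94 artifacts totalling 258 s, artifact-free
    max IRP median 73 mmHg, raw max median 257 mmHg).
    """

    n_cases: int = 27
    seed: int = 42

    # case duration (samples): lognormal, median 16173, IQR ~ [10494, 28983]
    duration_log_median_samples: float = math.log(16173.0)
    duration_log_sigma: float = 0.753

    # clean-signal components
    baseline_mean_mmHg: float = 10.0
    baseline_sd: float = 3.0
    ou_tau_s: float = 300.0
    ou_sd_mmHg: float = 2.0
    resp_freq_hz: float = 0.25
    resp_amp_range: tuple[float, float] = (0.5, 2.0)
    noise_sd_mmHg: float = 0.5

    # irrigation episodes
    episode_rate_per_hour: float = 12.0
    episode_amp_shape: float = 2.0
    episode_amp_scale: float = 12.5
    episode_case_scale_sigma: float = 0.40
    episode_rise_tau_s: float = 3.0
    episode_decay_tau_s: float = 5.0
    episode_plateau_range_s: tuple[float, float] = (5.0, 60.0)

    # artifacts; the count mean applies to a median-duration case and grows
    # sub-linearly with case duration (contact events accrue with operative
    # time, damped so cohort medians stay stable); it exceeds the
    # observed-spike target because overlapping spikes merge into single
    # labeled runs
    artifact_count_mean: float = 135.0
    artifact_count_size: float = 3.5  # negative-binomial dispersion (size r)
    artifact_count_duration_exponent: float = 0.7
    artifact_dur_log_median_s: float = math.log(1.8)
    artifact_dur_log_sigma: float = 0.7
    artifact_amp_log_median_mmHg: float = math.log(28.0)
    artifact_amp_log_sigma: float = 0.75
    artifact_jitter_sd_range_mmHg: tuple[float, float] = (10.0, 30.0)
    artifact_high_pressure_affinity: float = 0.55

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        for name in (
            "duration_log_sigma", "baseline_sd", "ou_tau_s", "ou_sd_mmHg",
            "resp_freq_hz", "noise_sd_mmHg", "episode_rate_per_hour",
            "episode_amp_shape", "episode_amp_scale", "episode_rise_tau_s",
            "episode_decay_tau_s", "artifact_count_mean", "artifact_count_size",
            "artifact_dur_log_sigma", "artifact_amp_log_sigma",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 <= self.artifact_high_pressure_affinity <= 1.0:
            raise ValidationError("artifact_high_pressure_affinity must be in [0, 1]")


@dataclass(frozen=True)
class SimCase:
    """One synthetic case: raw trace, truth labels, and the clean signal."""

    trace: PressureTrace
    truth: AnnotationTrack
    clean: PressureTrace


def _clean_signal(rng: np.random.Generator, n: int, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Artifact-free signal and the episode component (for placement)."""
    dt = 1.0 / _RATE
    t = np.arange(n) * dt

    baseline = rng.normal(cfg.baseline_mean_mmHg, cfg.baseline_sd)

    # OU drift: exact discretization of the stationary process
    a = math.exp(-dt / cfg.ou_tau_s)
    innov_sd = cfg.ou_sd_mmHg * math.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, cfg.ou_sd_mmHg)
    # x[i] = a * x[i-1] + eps[i], started from a stationary draw
    ou = lfilter([1.0], [1.0, -a], eps)

    resp_amp = rng.uniform(*cfg.resp_amp_range)
    resp_phase = rng.uniform(0.0, 2.0 * math.pi)
    resp = resp_amp * np.sin(2.0 * math.pi * cfg.resp_freq_hz * t + resp_phase)

    episodes = np.zeros(n)
    duration_h = n * dt / 3600.0
    k = rng.poisson(cfg.episode_rate_per_hour * duration_h)
    case_scale = rng.lognormal(0.0, cfg.episode_case_scale_sigma)
    starts = np.sort(rng.uniform(0.0, n * dt, size=k))
    for t0 in starts:
        amp = case_scale * rng.gamma(cfg.episode_amp_shape, cfg.episode_amp_scale)
        plateau = rng.uniform(*cfg.episode_plateau_range_s)
        i0 = int(t0 * _RATE)
        # render until decayed to ~1% of amplitude
        span_s = plateau + cfg.episode_decay_tau_s * 5.0
        i1 = min(n, i0 + int(span_s * _RATE) + 1)
        if i0 >= n:
            continue
        rel = t[i0:i1] - t0
        shape = np.where(
            rel <= plateau,
            1.0 - np.exp(-rel / cfg.episode_rise_tau_s),
            (1.0 - math.exp(-plateau / cfg.episode_rise_tau_s))
            * np.exp(-(rel - plateau) / cfg.episode_decay_tau_s),
        )
        episodes[i0:i1] += amp * shape

    noise = rng.normal(0.0, cfg.noise_sd_mmHg, size=n)
    clean = np.maximum(0.0, baseline + ou + resp + episodes + noise)
    return clean, episodes


def _artifact_shape(rng: np.random.Generator, n_samples: int, amp: float, jitter_sd: float) -> np.ndarray:
    """Additive contribution of one contact spike: rise / noisy plateau / fall."""
    n_rise = int(rng.integers(1, 3))
    n_fall = int(rng.integers(1, 3))
    if n_samples <= n_rise + n_fall:
        # too short for transitions: all-plateau spike
        vals = amp + rng.normal(0.0, jitter_sd, size=n_samples)
    else:
        plateau = amp + rng.normal(0.0, jitter_sd, size=n_samples - n_rise - n_fall)
        rise = amp * (np.arange(1, n_rise + 1) / (n_rise + 1))
        fall = amp * (np.arange(n_fall, 0, -1) / (n_fall + 1))
        vals = np.concatenate([rise, plateau, fall])
    # keep every marked sample strictly above the clean signal
    return np.maximum(vals, 0.5)


def simulate_case(config: SimConfig, case_seed: int, case_id: str | None = None) -> SimCase:
    """Generate one labeled case; deterministic for a given (config, seed)."""
    rng = np.random.default_rng(case_seed)
    cid = case_id or f"sim_{case_seed:05d}"

    n = 0
    for _ in range(100):
        n = int(round(rng.lognormal(config.duration_log_median_samples, config.duration_log_sigma)))
        if n >= 1:
            break
    else:
        raise ValidationError("could not draw a positive case duration in 100 attempts")

    clean, episodes = _clean_signal(rng, n, config)

    count_mean = config.artifact_count_mean * (
        n / math.exp(config.duration_log_median_samples)
    ) ** config.artifact_count_duration_exponent
    n_art = rng.negative_binomial(
        config.artifact_count_size,
        config.artifact_count_size / (config.artifact_count_size + count_mean),
    )

    add = np.zeros(n)
    in_episode = np.flatnonzero(episodes > 5.0)
    for _ in range(int(n_art)):
        dur_s = rng.lognormal(config.artifact_dur_log_median_s, config.artifact_dur_log_sigma)
        length = max(1, int(round(dur_s * _RATE)))
        length = min(length, n)
        if in_episode.size and rng.uniform() < config.artifact_high_pressure_affinity:
            start = int(in_episode[rng.integers(in_episode.size)])
            start = min(start, n - length)
        else:
            start = int(rng.integers(0, n - length + 1))
        amp = rng.lognormal(config.artifact_amp_log_median_mmHg, config.artifact_amp_log_sigma)
        jitter_sd = rng.uniform(*config.artifact_jitter_sd_range_mmHg)
        seg = _artifact_shape(rng, length, amp, jitter_sd)
        # overlapping artifacts union: keep the larger excursion per sample
        sl = slice(start, start + length)
        add[sl] = np.maximum(add[sl], seg)

    raw = clean + add
    mask = (add > 0.0).astype(np.int8)
    return SimCase(
        trace=PressureTrace(cid, raw),
        truth=AnnotationTrack(cid, mask, source="simulated"),
        clean=PressureTrace(cid, clean),
    )


def simulate_cohort(config: SimConfig) -> list[SimCase]:
    """Generate ``config.n_cases`` cases with per-case seeds ``seed + index``."""
    return [
        simulate_case(config, config.seed + i, case_id=f"case_{i:03d}")
        for i in range(config.n_cases)
    ]


def cohort_stats(cases: list[SimCase]) -> dict[str, float]:
    """Cohort medians of the calibration quantities (per-case aggregates)."""
    counts = [len(c.truth.intervals()) for c in cases]
    seconds = [c.truth.mask.sum() / _RATE for c in cases]
    raw_max = [float(c.trace.pressure_mmHg.max()) for c in cases]
    clean_max = [float(c.clean.pressure_mmHg.max()) for c in cases]
    density = [c.truth.mask.mean() for c in cases]
    n_samples = [c.trace.n for c in cases]
    return {
        "median_n_samples": float(np.median(n_samples)),
        "median_artifact_count": float(np.median(counts)),
        "median_artifact_seconds": float(np.median(seconds)),
        "median_raw_max_mmHg": float(np.median(raw_max)),
        "median_clean_max_mmHg": float(np.median(clean_max)),
        "median_mask_density": float(np.median(density)),
    }


def write_cohort(cases: list[SimCase], out_dir: str | Path, config: SimConfig | None = None) -> None:
    """Write per-case trace + truth CSVs and a cohort manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": [], "stats": cohort_stats(cases)}
    if config is not None:
        manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
    for case in cases:
        cid = case.trace.case_id
        write_trace(case.trace, out / f"{cid}_trace.csv")
        write_trace(case.clean, out / f"{cid}_clean.csv")
        write_annotation(case.truth, out / f"{cid}_truth.csv", form="samples")
        manifest["cases"].append({"case_id": cid, "n_samples": case.trace.n})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def scaled_config(config: SimConfig, duration_scale: float) -> SimConfig:
    """A shorter-case variant for quick tests; artifact density is preserved
    because per-case artifact counts scale with case duration."""
    return replace(
        config,
        duration_log_median_samples=config.duration_log_median_samples + math.log(duration_scale),
    )
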