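"""Core data model and I/O for intrarenal pressure (IRP) recordings.

A recording is a single case's pressure series sampled at 4 Hz by the
ureteroscope tip sensor.  Artifact labels travel either as a per-sample
binary mask (the canonical representation) or as an equivalent list of
half-open sample-index intervals.  Indices are 0-based and intervals are
half-open ``[start, end)`` throughout the package, so a segment's duration
in seconds is ``(end - start) / 4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

DEFAULT_RATE_HZ = 4.0
#: Tolerated relative deviation of the inferred sampling interval from 4 Hz.
RATE_TOLERANCE = 0.01

AnnotationSource = Literal["manual", "predicted", "simulated"]


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """Input values violate a contract (non-finite, non-binary, empty...)."""


class SamplingRateError(ValidationError):
    """Timestamps are irregular or imply a rate other than 4 Hz."""


@dataclass(frozen=True)
class PressureTrace:
    """One case's IRP series in mmHg, uniformly sampled (4 Hz by default)."""

    case_id: str
    pressure_mmHg: np.ndarray
    sampling_rate_hz: float = DEFAULT_RATE_HZ
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure_mmHg, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValidationError("pressure series must be 1-D with n >= 1")
        if not np.all(np.isfinite(p)):
            raise ValidationError("pressure series contains non-finite values")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling rate must be positive")
        object.__setattr__(self, "pressure_mmHg", p)

    @property
    def n(self) -> int:
        return int(self.pressure_mmHg.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n) / self.sampling_rate_hz


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-sample artifact labels for one case (1 = artifact sample)."""

    case_id: str
    mask: np.ndarray
    source: AnnotationSource = "manual"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 1:
            raise ValidationError("mask must be 1-D")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("mask values must be 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.mask.size)

    def intervals(self) -> "SegmentList":
        return mask_to_intervals(self.mask)


@dataclass(frozen=True)
class SegmentList:
    """Sorted, disjoint, non-adjacent half-open ``[start, end)`` intervals."""

    intervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        prev_end = None
        for a, b in ivs:
            if not 0 <= a < b:
                raise ValidationError(f"invalid interval [{a}, {b})")
            if prev_end is not None and a <= prev_end:
                raise ValidationError("intervals must be sorted and non-adjacent")
            prev_end = b
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_samples(self) -> int:
        return sum(b - a for a, b in self.intervals)


def mask_to_intervals(mask: Sequence[int] | np.ndarray) -> SegmentList:
    """Maximal runs of 1s in ``mask`` as half-open index intervals."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("mask values must be 0 or 1")
    m = m.astype(np.int8)
    if m.size == 0:
        return SegmentList()
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return SegmentList(tuple(zip(starts.tolist(), ends.tolist())))


def intervals_to_mask(segments: SegmentList | Iterable[tuple[int, int]], n: int) -> np.ndarray:
    """Inverse of :func:`mask_to_intervals` for a series of length ``n``."""
    mask = np.zeros(int(n), dtype=np.int8)
    for a, b in segments:
        if not (0 <= a < b <= n):
            raise IndexError(f"interval [{a}, {b}) out of range for n={n}")
        mask[a:b] = 1
    return mask


def merge_adjacent(intervals: Iterable[tuple[int, int]]) -> SegmentList:
    """Normalize arbitrary intervals: sort, union overlaps, merge adjacency."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return SegmentList(tuple((a, b) for a, b in merged))


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_trace(path: str | Path, case_id: str | None = None) -> PressureTrace:
    """Read a trace CSV with columns ``time_s,pressure_mmHg``.

    The sampling rate is inferred from the median time step and must agree
    with 4 Hz within 1%; other rates are rejected rather than resampled
    because every detector window is defined in samples at 4 Hz.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_mmHg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty data section")
    p = df["pressure_mmHg"].to_numpy(dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"{path}: non-finite pressure values")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise SamplingRateError(f"{path}: timestamps not strictly increasing")
        dt = float(np.median(steps))
        if abs(dt - 1.0 / DEFAULT_RATE_HZ) > RATE_TOLERANCE / DEFAULT_RATE_HZ:
            raise SamplingRateError(
                f"{path}: inferred rate {1.0 / dt:.3g} Hz differs from 4 Hz by > 1%"
            )
        if np.any(np.abs(steps - dt) > RATE_TOLERANCE * dt):
            raise SamplingRateError(f"{path}: irregular time step (> 1%)")
    return PressureTrace(
        case_id=case_id or path.stem,
        pressure_mmHg=p,
        start_time_s=float(t[0]) if len(t) else 0.0,
    )


def write_trace(trace: PressureTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.time_s, "pressure_mmHg": trace.pressure_mmHg}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_annotation(
    path: str | Path,
    n: int,
    sampling_rate_hz: float = DEFAULT_RATE_HZ,
    case_id: str | None = None,
) -> AnnotationTrack:
    """Read artifact labels from CSV, in either supported layout.

    Per-sample form has columns ``time_s,artifact``; interval form has
    ``case_id,start_s,end_s,source``.  ``n`` is the paired trace length.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if {"time_s", "artifact"} <= set(df.columns):
        mask = df["artifact"].to_numpy()
        if len(mask) != n:
            raise ValidationError(
                f"{path}: annotation length {len(mask)} != trace length {n}"
            )
        return AnnotationTrack(case_id or path.stem, mask)
    if {"start_s", "end_s"} <= set(df.columns):
        ivs = [
            (int(round(r.start_s * sampling_rate_hz)), int(round(r.end_s * sampling_rate_hz)))
            for r in df.itertuples()
        ]
        source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "manual"
        cid = case_id or (str(df["case_id"].iloc[0]) if "case_id" in df.columns and len(df) else path.stem)
        mask = intervals_to_mask(merge_adjacent(ivs), n)
        return AnnotationTrack(cid, mask, source)  # type: ignore[arg-type]
    raise FormatError(f"{path}: expected columns time_s,artifact or case_id,start_s,end_s,source")


def write_annotation(
    track: AnnotationTrack,
    path: str | Path,
    form: Literal["samples", "intervals"] = "intervals",
    sampling_rate_hz: float = DEFAULT_RATE_HZ,
) -> None:
    path = Path(path)
    if form == "samples":
        t = np.arange(track.n) / sampling_rate_hz
        pd.DataFrame({"time_s": t, "artifact": track.mask}).to_csv(
            path, index=False, float_format="%.10g"
        )
        return
    rows = [
        {
            "case_id": track.case_id,
            "start_s": a / sampling_rate_hz,
            "end_s": b / sampling_rate_hz,
            "source": track.source,
        }
        for a, b in track.intervals()
    ]
    pd.DataFrame(rows, columns=["case_id", "start_s", "end_s", "source"]).to_csv(
        path, index=False, float_format="%.10g"
    )
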