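"""Locomotion bout and resting-period segmentation of speed traces.

A locomotion bout is a maximal run of samples whose speed exceeds the
session threshold, mean + 1 SD of the whole-session speed.  Candidate
bouts that never reach 20% of the session's maximum speed are discarded
as pseudo-bouts (an artifact of low-activity sessions dragging the
threshold down).  Surviving bouts are extended by ~2.5 s to absorb
residual locomotion-driven Ca2+ activity, and a resting period is any
sub-threshold stretch outside the extended bouts lasting at least 30 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeedTrace",
    "LocomotionBout",
    "RestingPeriod",
    "BehaviorParams",
    "detect_bouts",
    "detect_resting",
    "unclassified_intervals",
]


@dataclass
class SpeedTrace:
    """Locomotion speed samples (mm/s) on a near-uniform time base."""

    time_s: np.ndarray
    speed_mm_s: np.ndarray
    x_mm: np.ndarray | None = None
    y_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed_mm_s = np.asarray(self.speed_mm_s, dtype=float)
        if self.time_s.shape != self.speed_mm_s.shape:
            raise ValueError("time and speed must have equal length")
        if self.time_s.size < 2:
            raise ValueError("speed trace needs at least 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if dt.max() > 1.1 * dt.min():
            warnings.warn("speed sampling jitter exceeds 10%", stacklevel=2)
        if np.any(self.speed_mm_s < 0):
            raise ValueError("speeds must be non-negative")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0] + self.dt)


@dataclass
class LocomotionBout:
    start_s: float
    end_raw_s: float  # last super-threshold sample
    end_extended_s: float
    peak_speed_mm_s: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.end_raw_s <= self.end_extended_s + 1e-12):
            raise ValueError("bout must satisfy start < end_raw <= end_extended")


@dataclass
class RestingPeriod:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BehaviorParams:
    extension_s: float = 2.5
    rest_min_s: float = 30.0
    min_peak_frac: float = 0.2


def detect_bouts(
    speed: SpeedTrace, params: BehaviorParams | None = None
) -> list[LocomotionBout]:
    """Segment locomotion bouts with the mean+1SD / 20%-of-max rules.

    The threshold uses the whole session, bout samples included.  A
    candidate is kept only if its peak speed strictly exceeds
    ``min_peak_frac`` of the session maximum.  Extensions are clipped at
    the next bout's raw start and at the session end; extended bouts
    that overlap are merged.
    """
    params = params or BehaviorParams()
    if speed.duration_s < 60:
        raise ValueError("bout detection needs at least 60 s of data")
    v = speed.speed_mm_s
    t = speed.time_s
    dt = speed.dt

    sd = v.std()
    if sd < 1e-12:
        warnings.warn("constant speed trace; no bouts detectable", stacklevel=2)
        return []
    threshold = v.mean() + sd
    vmax = v.max()

    above = v > threshold
    bouts: list[LocomotionBout] = []
    raw_runs: list[tuple[int, int]] = []
    if above.any():
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        for i0, i1 in zip(starts, ends):
            peak = v[i0 : i1 + 1].max()
            if peak <= params.min_peak_frac * vmax:
                continue  # pseudo-bout
            if i1 == i0:
                continue  # single-sample blip, no extent
            raw_runs.append((i0, i1))

    session_end = t[-1] + dt
    for j, (i0, i1) in enumerate(raw_runs):
        end_ext = t[i1] + params.extension_s
        if j + 1 < len(raw_runs):
            end_ext = min(end_ext, t[raw_runs[j + 1][0]])
        end_ext = min(end_ext, session_end)
        bouts.append(
            LocomotionBout(
                start_s=float(t[i0]),
                end_raw_s=float(t[i1]),
                end_extended_s=float(end_ext),
                peak_speed_mm_s=float(v[i0 : i1 + 1].max()),
            )
        )

    return _merge_overlapping(bouts)


def _merge_overlapping(bouts: list[LocomotionBout]) -> list[LocomotionBout]:
    merged: list[LocomotionBout] = []
    for b in sorted(bouts, key=lambda b: b.start_s):
        if merged and b.start_s <= merged[-1].end_extended_s:
            prev = merged[-1]
            merged[-1] = LocomotionBout(
                start_s=prev.start_s,
                end_raw_s=max(prev.end_raw_s, b.end_raw_s),
                end_extended_s=max(prev.end_extended_s, b.end_extended_s),
                peak_speed_mm_s=max(prev.peak_speed_mm_s, b.peak_speed_mm_s),
            )
        else:
            merged.append(b)
    return merged


def detect_resting(
    speed: SpeedTrace,
    bouts: list[LocomotionBout],
    params: BehaviorParams | None = None,
) -> list[RestingPeriod]:
    """Sub-threshold stretches outside extended bouts, >= 30 s long.

    Each sample is taken to cover [t, t + dt).  A half-sample slack
    (dt) is allowed on the duration so that a gap constructed to last
    exactly ``rest_min_s`` is not lost to boundary rounding.
    """
    params = params or BehaviorParams()
    v = speed.speed_mm_s
    t = speed.time_s
    dt = speed.dt
    sd = v.std()
    threshold = v.mean() + sd if sd > 1e-12 else np.inf

    quiet = v <= threshold
    for b in bouts:
        quiet &= ~((t >= b.start_s) & (t < b.end_extended_s))

    periods: list[RestingPeriod] = []
    if not quiet.any():
        return periods
    idx = np.flatnonzero(quiet)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    for i0, i1 in zip(starts, ends):
        start, end = float(t[i0]), float(t[i1] + dt)
        if end - start >= params.rest_min_s - dt:
            periods.append(RestingPeriod(start_s=start, end_s=end))
    return periods


def unclassified_intervals(
    speed: SpeedTrace,
    bouts: list[LocomotionBout],
    resting: list[RestingPeriod],
) -> list[tuple[float, float]]:
    """Session time covered by neither extended bouts nor resting periods."""
    session = (float(speed.time_s[0]), float(speed.time_s[-1] + speed.dt))
    covered = sorted(
        [(b.start_s, b.end_extended_s) for b in bouts]
        + [(r.start_s, r.end_s) for r in resting]
    )
    gaps: list[tuple[float, float]] = []
    cursor = session[0]
    for lo, hi in covered:
        if lo > cursor + 1e-9:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < session[1] - 1e-9:
        gaps.append((cursor, session[1]))
    return gaps
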