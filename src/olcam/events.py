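"""Ca2+ event detection on z-scored microdomain traces.

The core detector implements the rule set used for 5 Hz recordings:
local maxima above an amplitude threshold (strictly more than 5 z by
default) are bracketed by a 1 z-score bound rule -- the onset bracket is
the last frame before the peak with z below 1, the offset bracket is the
first frame after the peak where z stays at or below 1 for two
consecutive frames, or where the trace falls back within 10% of the
onset value (amplitude-relative form, see :func:`event_bounds`).  The
event proper is the contiguous super-bound run containing the peak, and
must last at least 4 frames.

The 15 Hz variant adds a 7+ z prefilter for inactive/noisy microdomains,
runs detection in parallel on the raw trace and on a zero-phase 1 Hz
low-passed copy, unions the two binary detections, and fuses runs closer
than 0.2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .preprocess import ZTrace

__all__ = [
    "DetectionParams",
    "CaEvent",
    "event_bounds",
    "detect_events",
    "detect_events_fast",
    "merge_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the event detector.

    amp_thresh_z
        Peak amplitude cut; events must exceed it strictly (default 5 z).
    min_dur_frames
        Minimum event length in frames (default 4), measured on the
        super-``bound_z`` core of the event.
    bound_z
        The onset/offset bracketing level (default 1 z).
    offset_frac
        Fraction of the peak-to-onset excursion used in the alternative
        offset rule (default 0.10).
    offset_mode
        ``"relative"`` (default) triggers the offset when
        z(t) <= z(onset) + offset_frac * (z(peak) - z(onset));
        ``"literal"`` uses z(t) <= offset_frac * |z(onset)| + z(onset)
        i.e. within 10% of the starting point's raw value, which is
        degenerate for onsets near zero.
    prefilter_z, lowpass_hz, merge_gap_s
        Fast-imaging (15 Hz) parameters: minimum peak z a trace must ever
        reach to be analysed at all, the cutoff of the zero-phase
        low-pass, and the gap below which detections are fused.
    """

    amp_thresh_z: float = 5.0
    min_dur_frames: int = 4
    bound_z: float = 1.0
    offset_frac: float = 0.10
    offset_mode: Literal["relative", "literal"] = "relative"
    prefilter_z: float = 7.0
    lowpass_hz: float = 1.0
    merge_gap_s: float = 0.2

    def __post_init__(self) -> None:
        if self.amp_thresh_z <= 0 or self.bound_z <= 0 or self.prefilter_z <= 0:
            raise ValueError("all z thresholds must be positive")
        if self.min_dur_frames < 1:
            raise ValueError("min_dur_frames must be >= 1")
        if not (0 < self.merge_gap_s < 1):
            raise ValueError("merge_gap_s must lie in (0, 1) s")
        if self.lowpass_hz <= 0:
            raise ValueError("lowpass_hz must be positive")


@dataclass
class CaEvent:
    """One detected Ca2+ transient.

    ``onset_frame``/``offset_frame`` delimit the contiguous run of frames
    at or above the bound level that contains the peak, so
    ``duration_s`` is the time the microdomain spends elevated.
    """

    roi_id: int
    onset_frame: int
    peak_frame: int
    offset_frame: int
    amplitude_z: float
    frame_rate_hz: float
    phase: str = "unclassified"

    @property
    def duration_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1

    @property
    def duration_s(self) -> float:
        return self.duration_frames / self.frame_rate_hz

    @property
    def onset_s(self) -> float:
        return self.onset_frame / self.frame_rate_hz

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.peak_frame <= self.offset_frame):
            raise ValueError("event frames must satisfy onset <= peak <= offset")


def event_bounds(
    z: np.ndarray,
    peak_frame: int,
    bound_z: float = 1.0,
    offset_frac: float = 0.10,
    offset_mode: str = "relative",
) -> tuple[int, int]:
    """Bracket a peak with the 1 z onset/offset rule.

    Returns the *bracket* frames: the onset is the last frame preceding
    the peak whose value is below ``bound_z`` (frame 0 if none), the
    offset is the first frame after the peak where ``z <= bound_z`` holds
    for two consecutive frames, or where the trace falls back within
    ``offset_frac`` of the onset value (amplitude-relative by default),
    whichever comes first; the last frame if neither occurs.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if not 0 <= peak_frame < n:
        raise IndexError("peak_frame outside trace")

    onset = 0
    for t in range(peak_frame - 1, -1, -1):
        if z[t] < bound_z:
            onset = t
            break

    if offset_mode == "relative":
        fall_level = z[onset] + offset_frac * (z[peak_frame] - z[onset])
    elif offset_mode == "literal":
        fall_level = z[onset] + offset_frac * abs(z[onset])
    else:  # pragma: no cover - guarded by DetectionParams
        raise ValueError(f"unknown offset_mode {offset_mode!r}")

    offset = n - 1
    for t in range(peak_frame + 1, n):
        if z[t] <= bound_z and t + 1 < n and z[t + 1] <= bound_z:
            offset = t
            break
        if z[t] <= fall_level:
            offset = t
            break
    return onset, offset


def _core_run(z: np.ndarray, peak: int, onset: int, offset: int, bound_z: float) -> tuple[int, int]:
    """Trim the bracket to the contiguous >= bound run containing the peak."""
    lo = peak
    while lo - 1 >= onset and z[lo - 1] >= bound_z:
        lo -= 1
    hi = peak
    while hi + 1 <= offset and z[hi + 1] >= bound_z:
        hi += 1
    return lo, hi


def _candidate_peaks(z: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Strict local maxima above threshold; plateaus take their first frame.

    The trace is padded with -inf so peaks at the edges are found too.
    """
    padded = np.concatenate(([-np.inf], z, [-np.inf]))
    peaks, props = signal.find_peaks(
        padded,
        height=np.nextafter(params.amp_thresh_z, np.inf),
        distance=params.min_dur_frames,
        plateau_size=(1, None),
    )
    # first frame of each plateau, shifted back for the padding
    return props["left_edges"] - 1


def detect_events(
    trace: ZTrace,
    params: DetectionParams | None = None,
    roi_id: int | None = None,
) -> list[CaEvent]:
    """Detect Ca2+ events on a z-scored trace (core 5 Hz rule set).

    Candidate peaks above ``amp_thresh_z`` are bracketed with
    :func:`event_bounds`; an event is kept if its super-bound core spans
    at least ``min_dur_frames`` frames.  Overlapping candidates are
    resolved by keeping the higher peak.
    """
    params = params or DetectionParams()
    z = np.asarray(trace.values, dtype=float)
    rid = trace.roi_id if roi_id is None else roi_id

    events: list[CaEvent] = []
    for peak in _candidate_peaks(z, params):
        onset_b, offset_b = event_bounds(
            z, peak, params.bound_z, params.offset_frac, params.offset_mode
        )
        lo, hi = _core_run(z, peak, onset_b, offset_b, params.bound_z)
        if hi - lo + 1 < params.min_dur_frames:
            continue
        events.append(
            CaEvent(
                roi_id=rid,
                onset_frame=lo,
                peak_frame=int(peak),
                offset_frame=hi,
                amplitude_z=float(z[peak]),
                frame_rate_hz=trace.frame_rate_hz,
            )
        )

    return _resolve_overlaps(events)


def _resolve_overlaps(events: list[CaEvent]) -> list[CaEvent]:
    """Keep the higher peak among overlapping candidates; sort by onset."""
    kept: list[CaEvent] = []
    for ev in sorted(events, key=lambda e: -e.amplitude_z):
        if all(
            ev.offset_frame < k.onset_frame or ev.onset_frame > k.offset_frame
            for k in kept
        ):
            kept.append(ev)
    return sorted(kept, key=lambda e: e.onset_frame)


def merge_events(events: Sequence[CaEvent], merge_gap_s: float = 0.2) -> list[CaEvent]:
    """Fuse consecutive events separated by less than ``merge_gap_s``.

    The gap between two events is (next.onset - prev.offset) / frame_rate;
    fusion is transitive (applied until fixpoint).  The fused event takes
    the onset of the first, the offset of the last and the maximal peak.
    """
    if not events:
        return []
    evs = sorted(events, key=lambda e: e.onset_frame)
    out: list[CaEvent] = [evs[0]]
    for ev in evs[1:]:
        prev = out[-1]
        gap_s = (ev.onset_frame - prev.offset_frame) / ev.frame_rate_hz
        if gap_s < merge_gap_s:
            if ev.amplitude_z > prev.amplitude_z:
                peak, amp = ev.peak_frame, ev.amplitude_z
            else:
                peak, amp = prev.peak_frame, prev.amplitude_z
            out[-1] = replace(
                prev,
                offset_frame=max(prev.offset_frame, ev.offset_frame),
                peak_frame=peak,
                amplitude_z=amp,
            )
        else:
            out.append(ev)
    return out


def detect_events_fast(
    trace: ZTrace,
    params: DetectionParams | None = None,
    roi_id: int | None = None,
) -> list[CaEvent]:
    """Dual-band detector for 15 Hz recordings.

    Traces that never reach ``prefilter_z`` are treated as inactive or
    too noisy and return no events.  Otherwise binary detections are
    computed independently on the raw trace (without the duration
    filter, so noise-fragmented slow events are not lost before
    merging) and on a zero-phase 4th-order Butterworth low-passed copy.
    The two are combined: raw detections provide the event timing and
    are fused when closer than ``merge_gap_s`` (hyper-segmentation
    repair); low-passed detections with no raw counterpart contribute
    slow events at the filtered bounds.  The amplitude/duration filters
    are re-applied on the raw trace at the end.
    """
    params = params or DetectionParams()
    fs = trace.frame_rate_hz
    if fs < 2 * params.lowpass_hz:
        raise ValueError(
            f"frame rate {fs} Hz cannot support a {params.lowpass_hz} Hz low-pass"
        )
    z = np.asarray(trace.values, dtype=float)
    rid = trace.roi_id if roi_id is None else roi_id

    if z.max(initial=-np.inf) < params.prefilter_z:
        return []

    sos = signal.butter(4, params.lowpass_hz, btype="low", fs=fs, output="sos")
    z_lp = signal.sosfiltfilt(sos, z)

    relaxed = replace(params, min_dur_frames=1)
    raw_events = detect_events(
        ZTrace(values=z, frame_rate_hz=fs, roi_id=rid), relaxed
    )
    lp_events = detect_events(
        ZTrace(values=z_lp, frame_rate_hz=fs, roi_id=rid), params
    )
    merged = merge_events(raw_events, params.merge_gap_s)

    # slow events visible only after low-passing (raw trace too noisy)
    for lp_ev in lp_events:
        overlaps = any(
            not (lp_ev.offset_frame < m.onset_frame or lp_ev.onset_frame > m.offset_frame)
            for m in merged
        )
        if not overlaps:
            lo, hi = lp_ev.onset_frame, lp_ev.offset_frame
            merged.append(
                replace(
                    lp_ev,
                    peak_frame=lo + int(np.argmax(z[lo : hi + 1])),
                    amplitude_z=float(z[lo : hi + 1].max()),
                )
            )
    merged = merge_events(sorted(merged, key=lambda e: e.onset_frame), params.merge_gap_s)
    return [
        ev
        for ev in merged
        if ev.amplitude_z > params.amp_thresh_z
        and ev.duration_frames >= params.min_dur_frames
    ]


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(first, last) index pairs of the True runs of a boolean mask."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))
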