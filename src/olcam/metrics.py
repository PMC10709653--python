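"""Event-behavior alignment and per-cell summary statistics.

Events are sorted into resting/active by the behavioral state at their
*onset*: inside an extended locomotion bout they are active, inside a
resting period they are resting, otherwise unclassified.  Per phase the
module computes active CaMs/min, events/min, events/min/CaM, amplitude
and duration statistics and pooled inter-spike intervals; the A/R ratio
(active over resting events/min) classifies a cell as locomotion
responsive (LR, A/R strictly above 1.5) or non-responsive (LNR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .behavior import LocomotionBout, RestingPeriod
from .events import CaEvent

__all__ = [
    "PhaseSummary",
    "SessionSummary",
    "assign_phase",
    "phase_durations",
    "summarize_session",
    "classify_responsiveness",
    "latency_to_max",
    "bout_triggered_response",
    "neuron_responsive",
]

AR_RESPONSIVE_THRESHOLD = 1.5


@dataclass
class PhaseSummary:
    """Per-phase activity metrics of one cell."""

    phase: str
    minutes: float
    n_events: int
    active_cams: int
    events_per_min: float
    active_cams_per_min: float
    events_per_min_per_cam: float
    mean_amplitude_z: float
    durations_s: np.ndarray
    isis_s: np.ndarray


@dataclass
class SessionSummary:
    """Resting/active metrics, A/R ratio and responder class of a cell."""

    cell_id: int
    n_cams: int
    resting: PhaseSummary | None
    active: PhaseSummary | None
    ar_ratio: float | None = None
    responder_class: str = "undefined"


def assign_phase(
    events: list[CaEvent],
    bouts: list[LocomotionBout],
    resting: list[RestingPeriod],
) -> list[CaEvent]:
    """Label each event by the behavioral state at its onset (in place)."""
    for ev in events:
        t = ev.onset_s
        if any(b.start_s <= t <= b.end_extended_s for b in bouts):
            ev.phase = "active"
        elif any(r.start_s <= t <= r.end_s for r in resting):
            ev.phase = "resting"
        else:
            ev.phase = "unclassified"
    return events


def phase_durations(
    bouts: list[LocomotionBout], resting: list[RestingPeriod]
) -> dict[str, float]:
    """Total seconds spent in the active and resting states."""
    return {
        "active": float(sum(b.end_extended_s - b.start_s for b in bouts)),
        "resting": float(sum(r.duration_s for r in resting)),
    }


def _summarize_phase(
    phase: str, events: list[CaEvent], seconds: float
) -> PhaseSummary | None:
    if seconds <= 0:
        return None
    minutes = seconds / 60.0
    evs = sorted(
        (e for e in events if e.phase == phase), key=lambda e: e.onset_s
    )
    onsets = np.array([e.onset_s for e in evs])
    cams = {e.roi_id for e in evs}
    n = len(evs)
    return PhaseSummary(
        phase=phase,
        minutes=minutes,
        n_events=n,
        active_cams=len(cams),
        events_per_min=n / minutes,
        active_cams_per_min=len(cams) / minutes,
        events_per_min_per_cam=(n / minutes / len(cams)) if cams else 0.0,
        mean_amplitude_z=float(np.mean([e.amplitude_z for e in evs])) if evs else 0.0,
        durations_s=np.array([e.duration_s for e in evs]),
        # ISIs pooled across the cell's CaMs, within the phase
        isis_s=np.diff(onsets) if n > 1 else np.empty(0),
    )


def summarize_session(
    events: list[CaEvent],
    bouts: list[LocomotionBout],
    resting: list[RestingPeriod],
    n_cams: int,
    cell_id: int = 0,
) -> SessionSummary:
    """Per-phase metrics and responsiveness class for one cell.

    ``events`` must already be phase-labelled (:func:`assign_phase`).
    With zero resting minutes (or a silent resting phase) the A/R ratio
    and responder class are undefined.
    """
    durs = phase_durations(bouts, resting)
    summary = SessionSummary(
        cell_id=cell_id,
        n_cams=n_cams,
        resting=_summarize_phase("resting", events, durs["resting"]),
        active=_summarize_phase("active", events, durs["active"]),
    )
    if (
        summary.resting is not None
        and summary.active is not None
        and summary.resting.events_per_min > 0
    ):
        summary.ar_ratio = summary.active.events_per_min / summary.resting.events_per_min
        summary.responder_class = classify_responsiveness(summary.ar_ratio)
    return summary


def classify_responsiveness(ar_ratio: float | None) -> str:
    """LR iff the A/R ratio strictly exceeds 1.5; LNR otherwise.

    A cell is locomotion responsive when its event frequency increases
    to more than 150% of the resting frequency during locomotion.
    """
    if ar_ratio is None:
        return "undefined"
    return "LR" if ar_ratio > AR_RESPONSIVE_THRESHOLD else "LNR"


def _active_cam_count(events: list[CaEvent], n_frames: int) -> np.ndarray:
    """Number of distinct CaMs elevated at each frame."""
    count = np.zeros(n_frames)
    per_cam: dict[int, np.ndarray] = {}
    for ev in events:
        mask = per_cam.setdefault(ev.roi_id, np.zeros(n_frames, dtype=bool))
        mask[ev.onset_frame : ev.offset_frame + 1] = True
    for mask in per_cam.values():
        count += mask
    return count


def _onset_count(events: list[CaEvent], n_frames: int) -> np.ndarray:
    """Number of event onsets at each frame (rate kernel, not extent)."""
    count = np.zeros(n_frames)
    for ev in events:
        count[ev.onset_frame] += 1
    return count


def bout_triggered_response(
    events: list[CaEvent],
    bouts: list[LocomotionBout],
    n_frames: int,
    frame_rate_hz: float,
    window_s: float = 10.0,
    pre_s: float = 2.0,
    smooth_s: float = 0.5,
    mode: str = "onsets",
) -> tuple[np.ndarray, np.ndarray]:
    """Event response averaged across bouts, aligned to bout starts.

    ``mode="onsets"`` uses the event-onset rate (unbiased timing);
    ``mode="active_cams"`` uses the per-frame active-CaM count (the
    display quantity, whose rise lags by about half an event duration).
    Returns (lag axis in s from ``-pre_s`` to ``window_s``, mean
    smoothed response).  Bouts whose window is truncated by the session
    edges are skipped with a warning.
    """
    fs = frame_rate_hz
    kernel = _onset_count if mode == "onsets" else _active_cam_count
    count = ndimage.gaussian_filter1d(
        kernel(events, n_frames), sigma=max(smooth_s * fs, 1e-6)
    )
    npre = int(round(pre_s * fs))
    npost = int(round(window_s * fs))
    segments = []
    for b in bouts:
        i0 = int(round(b.start_s * fs))
        if i0 - npre < 0 or i0 + npost >= n_frames:
            warnings.warn("bout window truncated by session edge; skipped", stacklevel=2)
            continue
        segments.append(count[i0 - npre : i0 + npost + 1])
    if not segments:
        raise ValueError("no bout window fits inside the session")
    lags = (np.arange(-npre, npost + 1)) / fs
    return lags, np.mean(segments, axis=0)


def _half_rise_lag(lags: np.ndarray, resp: np.ndarray) -> float:
    """First post-onset time where the response crosses half its rise.

    The plateau level is estimated robustly (60th percentile of the
    post-onset window) because the window maximum rides on noise and
    would bias the crossing late; the baseline excludes the 0.5 s just
    before onset, into which temporal smoothing leaks the rise.
    """
    pre = resp[lags < -0.5]
    baseline = pre.mean() if pre.size else resp[0]
    post = resp[lags >= 0]
    post_lags = lags[lags >= 0]
    plateau = np.percentile(post, 60)
    level = baseline + 0.5 * (plateau - baseline)
    above = np.flatnonzero(post >= level)
    return float(post_lags[above[0]]) if above.size else float(post_lags[-1])


def latency_to_max(
    events: list[CaEvent],
    bouts: list[LocomotionBout],
    n_frames: int,
    frame_rate_hz: float,
    window_s: float = 10.0,
    smooth_s: float = 0.5,
) -> tuple[list[float], np.ndarray]:
    """Per-bout response latencies (s) and their histogram counts.

    The response is the smoothed event-onset rate; the latency of a
    bout is the first post-onset time at which the response reaches
    half of its rise toward the window maximum (half-rise crossing).
    With symmetric smoothing this recovers the underlying onset lag
    without the plateau bias a plain argmax would have on sustained
    responses.  Bouts truncated by the session end are skipped with a
    warning.
    """
    if not bouts:
        raise ValueError("latency_to_max needs at least one bout")
    fs = frame_rate_hz
    count = ndimage.gaussian_filter1d(
        _onset_count(events, n_frames), sigma=max(smooth_s * fs, 1e-6)
    )
    pre_s = 2.0
    npre = int(round(pre_s * fs))
    npost = int(round(window_s * fs))
    lag_axis = np.arange(-npre, npost + 1) / fs
    lags: list[float] = []
    for b in bouts:
        i0 = int(round(b.start_s * fs))
        lo = max(i0 - npre, 0)
        if i0 + npost >= n_frames:
            warnings.warn("bout window truncated by session end; skipped", stacklevel=2)
            continue
        seg = count[lo : i0 + npost + 1]
        lags.append(_half_rise_lag(lag_axis[npre - (i0 - lo) :], seg))
    hist, _ = np.histogram(lags, bins=np.arange(0, window_s + 0.5, 0.5))
    return lags, hist


def neuron_responsive(
    onsets_s: np.ndarray,
    bouts: list[LocomotionBout],
    window_s: float = 4.0,
    min_frac: float = 0.5,
) -> bool:
    """Responsive iff >= 50% of bouts have a transient within 4 s of onset.

    The response window is the closed interval
    [bout start, bout start + ``window_s``].
    """
    if not bouts:
        raise ValueError("responsiveness is undefined without bouts")
    onsets = np.asarray(onsets_s, dtype=float)
    hits = sum(
        bool(np.any((onsets >= b.start_s) & (onsets <= b.start_s + window_s)))
        for b in bouts
    )
    return hits / len(bouts) >= min_frac
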