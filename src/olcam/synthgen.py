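"""Seeded synthetic two-photon sessions with full ground truth.

The generator emulates the statistical structure of microdomain Ca2+
activity in oligodendrocyte-lineage cells of an awake mouse on an
air-lifted homecage: micrometre-scale event footprints (mean area
4.64 um^2), Poisson event trains whose rate switches between a resting
and an active level a fixed lag after locomotion onset, pulse
amplitudes around 8.6 z and durations around 1.3 s, pixel shot noise,
slow drift, shared-channel rigid motion, and speed traces alternating
quiescence with square-wave exploration bouts.  Everything downstream
(registration, segmentation, detection, behavior alignment) can be
scored against the returned ground truth.

Morphology prototypes for the four lineage stages (OPC, pmOL1, pmOL2,
OL) are generated with controlled soma circularity, soma area and
branch-spacing dispersion, matching the staging thresholds in
:mod:`olcam.morphology`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .behavior import SpeedTrace
from .preprocess import TwoChannelMovie

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_speed",
    "simulate_session",
    "simulate_morphology",
    "STAGE_BANDS",
]


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-session parameters.

    Defaults follow the in vivo statistics of cortical OPC recordings:
    4.64 +/- 3.33 um^2 microdomain footprints, 24.89 (resting) and
    86.16 (active) events/min per cell, ~8.6 z amplitudes, ~1.3 s
    durations, and a ~3.6 s lag between locomotion onset and the rate
    switch.
    """

    duration_s: float = 600.0
    frame_rate_hz: float = 5.1
    field_um: float = 28.0
    pixel_size_um: float = 0.17
    n_microdomains: int = 40
    footprint_area_mean_um2: float = 4.64
    footprint_area_sd_um2: float = 3.33
    rate_resting_per_min: float = 24.89
    rate_active_per_min: float = 86.16
    amp_mean_z: float = 8.6
    amp_sd_z: float = 1.2
    dur_mean_s: float = 1.3
    dur_sd_s: float = 0.5
    # the in vivo duration statistics are measured after the 4-frame
    # floor of the detector, so the emulated (truncated-normal) draw
    # excludes sub-floor durations; None means 4 / frame_rate_hz
    dur_min_s: float | None = None
    min_footprint_area_um2: float = 1.0
    noise_sd: float = 10.0
    shot_noise: bool = False
    drift_slope: float = 0.005
    motion_amp_px: int = 1
    onset_lag_s: float = 3.6
    # behavior schedule
    n_bouts: int = 4
    bout_dur_s: float = 60.0
    bout_speed_mm_s: float = 60.0
    bout_edge_s: float = 1.0
    baseline_speed_sd: float = 2.0
    speed_hz: float = 20.0
    # baseline image model
    baseline_green: float = 100.0
    baseline_red: float = 100.0
    red_footprint_gain_sd: float = 5.0  # red footprint contrast, in noise SDs
    green_footprint_gain_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "frame_rate_hz", "field_um", "pixel_size_um",
            "footprint_area_mean_um2", "rate_resting_per_min",
            "rate_active_per_min", "amp_mean_z", "dur_mean_s", "speed_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_microdomains < 1:
            raise ValueError("n_microdomains must be >= 1")
        n_frames = self.duration_s * self.frame_rate_hz
        if abs(n_frames - round(n_frames)) > 1e-6:
            raise ValueError("frame_rate_hz * duration_s must be an integer")
        if self.n_bouts < 0 or self.bout_dur_s < 0:
            raise ValueError("bout schedule must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def side_px(self) -> int:
        return int(round(self.field_um / self.pixel_size_um))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_footprints: np.ndarray  # label image, 0 background
    true_events: list[tuple[int, int, float, int]]  # (roi, onset_frame, amp_z, dur_frames)
    true_bouts: list[tuple[float, float]]  # (start_s, end_s)
    true_motion: np.ndarray  # (T, 2) integer (dy, dx)


def _rngs(seed: int, n: int = 4) -> list[Generator]:
    return [default_rng(s) for s in SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# speed traces


def _bout_schedule(config: SimConfig, rng: Generator) -> list[tuple[float, float]]:
    """Bout (start, end) seconds, evenly spaced with ~10% start jitter."""
    n = config.n_bouts
    if n == 0:
        return []
    total_gap = config.duration_s - n * config.bout_dur_s
    if total_gap <= 0:
        raise ValueError("bout schedule does not fit in the session")
    gap = total_gap / (n + 1)
    bouts = []
    for i in range(n):
        start = gap + i * (gap + config.bout_dur_s)
        start += rng.uniform(-0.1, 0.1) * gap
        bouts.append((start, start + config.bout_dur_s))
    return bouts


def simulate_speed(
    config: SimConfig, rng: Generator | None = None
) -> tuple[SpeedTrace, list[tuple[float, float]]]:
    """Speed trace with quiescent stretches and exploration bouts.

    Quiescence is half-normal jitter around zero; bouts are square
    pulses with raised-cosine edges.  Returns the trace and the true
    bout intervals.
    """
    if config.duration_s < 60:
        raise ValueError("simulate_speed needs duration_s >= 60")
    if rng is None:
        rng = _rngs(config.seed)[0]

    t = np.arange(int(round(config.duration_s * config.speed_hz))) / config.speed_hz
    speed = np.abs(rng.normal(0.0, config.baseline_speed_sd, size=t.size))

    bouts = _bout_schedule(config, rng)
    edge = config.bout_edge_s
    for b0, b1 in bouts:
        inside = (t >= b0) & (t < b1)
        profile = np.ones(inside.sum())
        tt = t[inside] - b0
        rise = tt < edge
        profile[rise] = 0.5 * (1 - np.cos(np.pi * tt[rise] / edge))
        fall = tt > (b1 - b0) - edge
        profile[fall] = 0.5 * (1 - np.cos(np.pi * ((b1 - b0) - tt[fall]) / edge))
        speed[inside] += config.bout_speed_mm_s * profile

    return SpeedTrace(time_s=t, speed_mm_s=speed), bouts


# ---------------------------------------------------------------------------
# footprints


def _layout_footprints(config: SimConfig, rng: Generator) -> np.ndarray:
    """Non-overlapping elliptical footprints on a jittered grid.

    Areas are drawn from a gamma distribution with the configured
    mean/SD (strictly positive support); draws below the analysis floor
    (``min_footprint_area_um2``, so every ground-truth CaM is
    segmentable) or too large for a grid cell are redrawn, truncating
    both tails.
    """
    side = config.side_px
    margin = config.motion_amp_px + 2
    g = int(np.ceil(np.sqrt(config.n_microdomains)))
    cell = (side - 2 * margin) // g
    px2 = config.pixel_size_um**2
    mean_px = config.footprint_area_mean_um2 / px2
    if cell < 4 or cell * cell < 1.2 * mean_px:
        raise ValueError(
            f"field of {side} px cannot host {config.n_microdomains} "
            f"footprints of mean area {config.footprint_area_mean_um2} um^2"
        )
    max_px = int(0.7 * cell * cell)
    min_px = max(1, int(np.ceil(config.min_footprint_area_um2 / px2)))

    k = (config.footprint_area_mean_um2 / config.footprint_area_sd_um2) ** 2
    theta = config.footprint_area_mean_um2 / k

    cells = [(r, c) for r in range(g) for c in range(g)]
    rng.shuffle(cells)
    labels = np.zeros((side, side), dtype=np.int32)
    yy, xx = np.mgrid[0:cell, 0:cell]
    for roi, (r, c) in enumerate(cells[: config.n_microdomains], start=1):
        for _ in range(100):
            area_px = int(round(rng.gamma(k, theta) / px2))
            if min_px <= area_px <= max_px:
                break
        else:
            area_px = max_px
        cy = cell / 2 + rng.uniform(-0.1, 0.1) * cell
        cx = cell / 2 + rng.uniform(-0.1, 0.1) * cell
        q = rng.uniform(0.5, 1.0)  # ellipse aspect
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(phi) + dx * np.sin(phi)
        v = -dy * np.sin(phi) + dx * np.cos(phi)
        dist = (u / q) ** 2 + v**2
        pick = np.argsort(dist.ravel(), kind="stable")[:area_px]
        block = np.zeros(cell * cell, dtype=bool)
        block[pick] = True
        y0, x0 = margin + r * cell, margin + c * cell
        labels[y0 : y0 + cell, x0 : x0 + cell][block.reshape(cell, cell)] = roi
    return labels


# ---------------------------------------------------------------------------
# event trains and pulses


def _piecewise_rate_windows(
    config: SimConfig, bouts: Sequence[tuple[float, float]]
) -> list[tuple[float, float, float]]:
    """(start_s, end_s, rate/min) segments covering the session.

    The rate switches to the active level ``onset_lag_s`` after each
    bout start and back to resting the same lag after bout end.
    """
    cursor = 0.0
    segs: list[tuple[float, float, float]] = []
    lag = config.onset_lag_s
    for b0, b1 in bouts:
        a0 = min(b0 + lag, config.duration_s)
        a1 = min(b1 + lag, config.duration_s)
        if a0 > cursor:
            segs.append((cursor, a0, config.rate_resting_per_min))
        if a1 > a0:
            segs.append((a0, a1, config.rate_active_per_min))
        cursor = a1
    if cursor < config.duration_s:
        segs.append((cursor, config.duration_s, config.rate_resting_per_min))
    return segs


def _sample_event_times(
    segs: Sequence[tuple[float, float, float]], per_cam_frac: float, rng: Generator
) -> np.ndarray:
    """Inhomogeneous Poisson event times (s) for one microdomain."""
    times = []
    for t0, t1, rate_per_min in segs:
        lam = rate_per_min / 60.0 * per_cam_frac * (t1 - t0)
        n = rng.poisson(lam)
        times.append(rng.uniform(t0, t1, size=n))
    out = np.concatenate(times) if times else np.empty(0)
    return np.sort(out)


def _pulse_kernel(amp: float, dur_frames: int, fs: float) -> np.ndarray:
    """Linear 2-frame rise to ``amp`` then exponential decay, tau = dur/3."""
    tau = max(dur_frames / fs / 3.0, 1.0 / fs)
    n_decay = int(np.ceil(5 * tau * fs))
    k = np.empty(2 + n_decay)
    k[0] = 0.5 * amp
    k[1] = amp
    k[2:] = amp * np.exp(-np.arange(1, n_decay + 1) / (tau * fs))
    return k


def _int_shift(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with edge replication."""
    out = img
    if dy:
        out = np.roll(out, dy, axis=0)
        if dy > 0:
            out[:dy, :] = out[dy, :]
        else:
            out[dy:, :] = out[dy - 1, :]
    if dx:
        out = np.roll(out, dx, axis=1)
        if dx > 0:
            out[:, :dx] = out[:, dx : dx + 1]
        else:
            out[:, dx:] = out[:, dx - 1 : dx]
    return out


def simulate_session(
    config: SimConfig,
) -> tuple[TwoChannelMovie, SpeedTrace, GroundTruth]:
    """Dual-channel movie + speed trace + ground truth for one session.

    Green channel: baseline + faint static footprints + event pulses
    (footprint x rise/decay kernel) + drift + noise.  Red channel:
    baseline + bright static footprints + the same drift/noise
    statistics, no events.  Both channels undergo the same rigid
    integer-pixel motion walk.
    """
    rng_speed, rng_layout, rng_events, rng_noise = _rngs(config.seed)

    speed, true_bouts = simulate_speed(config, rng_speed)
    labels = _layout_footprints(config, rng_layout)
    T, side, fs = config.n_frames, config.side_px, config.frame_rate_hz

    segs = _piecewise_rate_windows(config, true_bouts)
    per_cam = 1.0 / config.n_microdomains
    # 1 z of configured amplitude in raw units; in the noiseless limit
    # one raw unit stands in for the z reference
    amp_raw_unit = config.noise_sd if config.noise_sd > 0 else 1.0

    cam_traces = np.zeros((config.n_microdomains, T), dtype=np.float32)
    true_events: list[tuple[int, int, float, int]] = []
    for roi in range(1, config.n_microdomains + 1):
        for t_ev in _sample_event_times(segs, per_cam, rng_events):
            onset = int(round(t_ev * fs))
            if onset >= T:
                continue
            amp_z = max(rng_events.normal(config.amp_mean_z, config.amp_sd_z), 1.0)
            dur_min = 4.0 / fs if config.dur_min_s is None else config.dur_min_s
            for _ in range(100):  # truncated normal: redraw below the floor
                dur_s = rng_events.normal(config.dur_mean_s, config.dur_sd_s)
                if dur_s >= dur_min:
                    break
            else:
                dur_s = dur_min
            dur_frames = max(int(round(dur_s * fs)), 2)
            kernel = _pulse_kernel(amp_z * amp_raw_unit, dur_frames, fs)
            stop = min(onset + kernel.size, T)
            cam_traces[roi - 1, onset:stop] += kernel[: stop - onset].astype(np.float32)
            true_events.append((roi, onset, float(amp_z), dur_frames))

    # motion: random walk clipped to +/- motion_amp_px, recentred on its
    # modal position so the unshifted scene is the registration reference
    motion = np.zeros((T, 2), dtype=int)
    if config.motion_amp_px > 0:
        steps = rng_noise.integers(-1, 2, size=(T, 2))
        walk = np.clip(np.cumsum(steps, axis=0), -config.motion_amp_px, config.motion_amp_px)
        pairs, counts = np.unique(walk, axis=0, return_counts=True)
        mode = pairs[np.argmax(counts)]
        motion = np.clip(walk - mode, -config.motion_amp_px, config.motion_amp_px)

    support = labels > 0
    green_static = (
        config.baseline_green
        + config.green_footprint_gain_sd * config.noise_sd * support
    ).astype(np.float32)
    red_static = (
        config.baseline_red
        + config.red_footprint_gain_sd * config.noise_sd * support
    ).astype(np.float32)
    drift = (config.drift_slope * np.arange(T)).astype(np.float32)

    # static scene, shifted per motion group (footprints sit inside the
    # margin, so integer shifts never clip them)
    green = np.zeros((T, side, side), dtype=np.float32)
    red = np.zeros_like(green)
    unique_shifts = sorted({tuple(m) for m in motion.tolist()})
    groups = {
        s: np.flatnonzero((motion[:, 0] == s[0]) & (motion[:, 1] == s[1]))
        for s in unique_shifts
    }
    for (dy, dx), idx in groups.items():
        green[idx] = _int_shift(green_static.copy(), dy, dx)
        red[idx] = _int_shift(red_static.copy(), dy, dx)

    gflat = green.reshape(T, -1)
    for roi_idx in range(config.n_microdomains):
        tr = cam_traces[roi_idx]
        active = np.flatnonzero(tr)
        if active.size == 0:
            continue
        ys, xs = np.nonzero(labels == roi_idx + 1)
        for (dy, dx), idx in groups.items():
            sub = np.intersect1d(active, idx, assume_unique=True)
            if sub.size == 0:
                continue
            pix = (ys + dy) * side + (xs + dx)
            gflat[np.ix_(sub, pix)] += tr[sub, None]

    green += drift[:, None, None]
    red += drift[:, None, None]

    if config.shot_noise:
        green[:] = rng_noise.poisson(np.clip(green, 0, None)).astype(np.float32)
        red[:] = rng_noise.poisson(np.clip(red, 0, None)).astype(np.float32)
    else:
        green += config.noise_sd * rng_noise.standard_normal(green.shape, dtype=np.float32)
        red += config.noise_sd * rng_noise.standard_normal(red.shape, dtype=np.float32)

    movie = TwoChannelMovie(
        green=green,
        red=red,
        frame_rate_hz=fs,
        pixel_size_um=config.pixel_size_um,
    )
    truth = GroundTruth(
        true_footprints=labels,
        true_events=true_events,
        true_bouts=true_bouts,
        true_motion=motion,
    )
    return movie, speed, truth


# ---------------------------------------------------------------------------
# morphology prototypes

# Per-stage generator bands: uniform draws inside these ranges.  The
# bands are mutually separated so that staging with the matched default
# thresholds recovers the generating stage.
STAGE_BANDS: dict[str, dict[str, tuple[float, float] | int]] = {
    "OPC": {"circularity": (0.55, 0.70), "soma_area_um2": (25.0, 50.0),
            "branch_spread": (0.18, 0.30), "n_branches": 6, "branch_len_um": 12.0},
    "pmOL1": {"circularity": (0.74, 0.82), "soma_area_um2": (55.0, 85.0),
              "branch_spread": (0.10, 0.16), "n_branches": 7, "branch_len_um": 10.0},
    "pmOL2": {"circularity": (0.84, 0.91), "soma_area_um2": (90.0, 130.0),
              "branch_spread": (0.05, 0.09), "n_branches": 8, "branch_len_um": 8.0},
    "OL": {"circularity": (0.93, 0.985), "soma_area_um2": (140.0, 190.0),
           "branch_spread": (0.0, 0.04), "n_branches": 9, "branch_len_um": 7.0},
}


def _soma_polygon(
    rng: Generator, target_circ: float, target_area_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radial polygon (y, x offsets) with controlled raster circularity.

    Boundary roughness (low-order radial harmonics) is bisected until
    the *measured* circularity of the rasterized mask matches the
    target; the radius is rescaled for the target pixel area.
    """
    from .morphology import soma_metrics  # local import to avoid a cycle at import time

    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    harmonics = np.zeros_like(theta)
    for kh in range(2, 7):
        harmonics += rng.uniform(0.5, 1.0) / kh * np.cos(kh * theta + rng.uniform(0, 2 * np.pi))
    harmonics /= np.abs(harmonics).max()

    def rasterize(eps: float) -> np.ndarray:
        from skimage.draw import polygon as draw_polygon

        r = 1.0 + eps * harmonics
        # polygon area in continuous units -> scale for pixel area
        area0 = 0.5 * np.abs(np.sum(r**2 * (2 * np.pi / theta.size)))
        scale = np.sqrt(target_area_px / area0)
        rr = scale * r
        pad = int(np.ceil(rr.max())) + 3
        mask = np.zeros((2 * pad, 2 * pad), dtype=bool)
        py, px = draw_polygon(pad + rr * np.sin(theta), pad + rr * np.cos(theta), mask.shape)
        mask[py, px] = True
        return mask

    lo, hi = 0.0, 0.55
    mask = rasterize(lo)
    if soma_metrics(mask, 1.0)[1] <= target_circ:
        return mask, theta
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        mask = rasterize(mid)
        circ = soma_metrics(mask, 1.0)[1]
        if circ > target_circ:
            lo = mid
        else:
            hi = mid
    return rasterize(0.5 * (lo + hi)), theta


def _gap_fractions(rng: Generator, n: int, target_sd: float) -> np.ndarray:
    """n positive fractions summing to 1 with the requested population SD."""
    if target_sd < 1e-6:
        return np.full(n, 1.0 / n)
    u = np.full(n, 1.0 / n)
    alpha = max(((n - 1) / (n**2 * target_sd**2) - 1) / n, 0.05)
    for _ in range(500):
        d = rng.dirichlet(np.full(n, alpha)) - u
        sd = d.std()
        if sd < 1e-9:
            continue
        gaps = u + d * (target_sd / sd)
        if gaps.min() > 0.01:
            return gaps
    raise RuntimeError(f"could not realize branch-gap SD {target_sd} with {n} branches")


def simulate_morphology(
    stage: str, seed: int = 0, pixel_size_um: float = 0.17
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic cell prototype of one lineage stage.

    Returns ``(cell_mask, soma_mask, branch_roots)`` where roots are
    (row, col) points on the soma perimeter.  Soma circularity, soma
    area and branch-spacing dispersion are drawn inside the
    stage-specific bands of :data:`STAGE_BANDS`.
    """
    if stage not in STAGE_BANDS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_BANDS)}")
    from skimage.draw import line as draw_line
    from scipy import ndimage

    band = STAGE_BANDS[stage]
    stage_index = list(STAGE_BANDS).index(stage)
    rng = default_rng(SeedSequence((stage_index, seed)))
    target_circ = rng.uniform(*band["circularity"])
    target_area = rng.uniform(*band["soma_area_um2"]) / pixel_size_um**2
    target_sd = rng.uniform(*band["branch_spread"])
    n_branches = int(band["n_branches"])
    branch_len = band["branch_len_um"] / pixel_size_um

    soma_small, theta = _soma_polygon(rng, target_circ, target_area)

    # embed in a larger canvas with room for branches
    pad = int(np.ceil(branch_len)) + 4
    h = soma_small.shape[0] + 2 * pad
    soma = np.zeros((h, h), dtype=bool)
    soma[pad : pad + soma_small.shape[0], pad : pad + soma_small.shape[1]] = soma_small
    cy, cx = ndimage.center_of_mass(soma)

    # branch roots at prescribed arc-length fractions of the perimeter,
    # matching how branch_spread measures inter-branch distances
    from .morphology import _boundary_arclength

    gaps = _gap_fractions(rng, n_branches, target_sd)
    contour, cum = _boundary_arclength(soma)
    total = cum[-1]
    s0 = rng.uniform(0, total)
    arcs = (s0 + total * np.concatenate(([0.0], np.cumsum(gaps[:-1])))) % total

    roots = []
    cell = soma.copy()
    for s in arcs:
        i = int(np.searchsorted(cum, s)) % contour.shape[0]
        r = int(round(contour[i, 0]))
        c = int(round(contour[i, 1]))
        r = int(np.clip(r, 0, h - 1))
        c = int(np.clip(c, 0, h - 1))
        ang = np.arctan2(r - cy, c - cx)
        tip_r = int(round(r + branch_len * np.sin(ang)))
        tip_c = int(round(c + branch_len * np.cos(ang)))
        roots.append((r, c))
        tip_r = int(np.clip(tip_r, 0, h - 1))
        tip_c = int(np.clip(tip_c, 0, h - 1))
        lr, lc = draw_line(r, c, tip_r, tip_c)
        cell[lr, lc] = True
    cell = ndimage.binary_dilation(cell, iterations=1) | soma

    return cell, soma, np.array(roots, dtype=int)
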