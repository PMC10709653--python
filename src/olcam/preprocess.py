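"""Movie preprocessing: rigid registration, trace extraction, z-scoring.

Registration is a rigid, integer-precision translation correction by FFT
phase correlation against a Ca2+-independent reference: the median
projection of the red (tdTomato) channel.  The same shift is applied to
both channels.  Per-microdomain traces are linearly detrended and
z-scored over the full trace; shared movement artifacts are removed by
subtracting the z-scored red trace from the z-scored green trace
(pseudo-ratiometric correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "TwoChannelMovie",
    "ZTrace",
    "register_rigid",
    "extract_traces",
    "detrend_zscore",
    "ratiometric_correct",
]


@dataclass
class TwoChannelMovie:
    """Registered or raw green (GCaMP) + red (tdTomato) frame stacks."""

    green: np.ndarray  # (T, H, W) fluorescence, arbitrary units
    red: np.ndarray  # (T, H, W)
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must share a shape")
        if self.green.ndim != 3:
            raise ValueError("movie stacks must be (T, H, W)")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape


@dataclass
class ZTrace:
    """Per-frame z-scores of one microdomain.

    ``degenerate`` flags traces whose post-detrend SD was zero (the
    z-trace is then all zeros rather than a division error).
    """

    values: np.ndarray
    frame_rate_hz: float
    roi_id: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("z-trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def _phase_shift(ref_f: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) of ``frame`` relative to the reference.

    ``ref_f`` is the precomputed 2D FFT of the reference image.  Returns
    the translation that maps the reference onto the frame, i.e. the
    motion the frame has undergone.
    """
    return tuple(int(v) for v in _phase_shift_stack(ref_f, frame[None])[0])


def _phase_shift_stack(ref_f: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Phase-correlation shifts of a (T, H, W) stack against ``ref_f``.

    ``ref_f`` is the half-spectrum (rfft2) of the reference image.
    """
    from scipy import fft as sfft

    H, W = frames.shape[1:]
    cross = ref_f[None] * np.conj(sfft.rfft2(frames.astype(np.float32), axes=(1, 2)))
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    cross /= mag
    corr = sfft.irfft2(cross, s=(H, W), axes=(1, 2))
    peaks = corr.reshape(corr.shape[0], -1).argmax(axis=1)
    dy = peaks // W
    dx = peaks % W
    dy[dy > H // 2] -= H
    dx[dx > W // 2] -= W
    return -np.stack([dy, dx], axis=1).astype(int)


def _shift_stack_inplace(stack: np.ndarray, idx: np.ndarray, dy: int, dx: int) -> None:
    """Integer-translate a subset of frames with edge replication."""
    sub = np.roll(stack[idx], (dy, dx), axis=(1, 2))
    if dy > 0:
        sub[:, :dy, :] = sub[:, dy : dy + 1, :]
    elif dy < 0:
        sub[:, dy:, :] = sub[:, dy - 1 : dy, :]
    if dx > 0:
        sub[:, :, :dx] = sub[:, :, dx : dx + 1]
    elif dx < 0:
        sub[:, :, dx:] = sub[:, :, dx - 1 : dx]
    stack[idx] = sub


def register_rigid(
    movie: TwoChannelMovie,
) -> tuple[TwoChannelMovie, np.ndarray]:
    """Correct rigid XY motion; returns the corrected movie and shifts.

    The reference is the median-intensity projection of the red channel
    (Ca2+-independent).  Each frame's translation is estimated on the red
    channel by phase correlation and the inverse shift is applied to both
    channels.  ``shifts[t]`` is the estimated (dy, dx) motion of frame t
    in pixels.  All-zero frames are skipped with a warning (zero shift).
    """
    if movie.n_frames < 2:
        raise ValueError("registration requires at least 2 frames")

    from scipy import fft as sfft

    T = movie.n_frames
    # median projection of the red channel; an even temporal subsample
    # is statistically equivalent for the static scene and much cheaper
    step = max(1, T // 1024)
    reference = np.median(movie.red[::step], axis=0)
    if not np.any(reference):
        warnings.warn("all-zero reference; registration skipped", stacklevel=2)
        return movie, np.zeros((T, 2), dtype=int)
    ref_f = sfft.rfft2(reference.astype(np.float32))
    shifts = np.zeros((T, 2), dtype=int)
    nonzero = movie.red.reshape(T, -1).any(axis=1)
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} all-zero frames; registration skipped for them",
            stacklevel=2,
        )
    live = np.flatnonzero(nonzero)
    chunk = 256
    for i in range(0, live.size, chunk):
        sel = live[i : i + chunk]
        shifts[sel] = _phase_shift_stack(ref_f, movie.red[sel])

    green = movie.green.copy()
    red = movie.red.copy()
    for dy, dx in {tuple(s) for s in shifts.tolist()}:
        if dy == 0 and dx == 0:
            continue
        idx = np.flatnonzero((shifts[:, 0] == dy) & (shifts[:, 1] == dx))
        _shift_stack_inplace(green, idx, -dy, -dx)
        _shift_stack_inplace(red, idx, -dy, -dx)

    corrected = TwoChannelMovie(
        green=green,
        red=red,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_size_um=movie.pixel_size_um,
    )
    return corrected, shifts


def extract_traces(stack: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    """Mean intensity of each labelled ROI per frame.

    ``stack`` is (T, H, W); ``labels`` an integer image with 0 background
    and ROIs 1..K.  Raises for ROIs with no member pixels.
    """
    stack = np.asarray(stack)
    labels = np.asarray(labels)
    if stack.shape[1:] != labels.shape:
        raise ValueError("stack and label image must share H x W")
    roi_ids = [int(k) for k in np.unique(labels) if k != 0]
    flat = stack.reshape(stack.shape[0], -1)
    lab_flat = labels.ravel()
    traces: dict[int, np.ndarray] = {}
    for k in roi_ids:
        member = np.flatnonzero(lab_flat == k)
        if member.size == 0:  # pragma: no cover - unique() guards this
            raise ValueError(f"ROI {k} has no member pixels")
        traces[k] = flat[:, member].mean(axis=1)
    if not traces and labels.max(initial=0) > 0:
        raise ValueError("label image has no labelled pixels")
    return traces


def detrend_zscore(
    raw: np.ndarray, frame_rate_hz: float, roi_id: int = 0
) -> ZTrace:
    """Remove the least-squares linear trend, then z-score the residual.

    The z statistics (mean, SD) are computed over the whole detrended
    trace.  A constant (or purely linear) input maps to an all-zero
    z-trace with ``degenerate=True`` rather than a division error.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 10:
        raise ValueError("detrend_zscore needs at least 10 frames")
    flat = signal.detrend(raw, type="linear")
    sd = flat.std()
    if sd < 1e-12 * max(1.0, np.abs(raw).max()):
        return ZTrace(
            values=np.zeros_like(flat),
            frame_rate_hz=frame_rate_hz,
            roi_id=roi_id,
            degenerate=True,
        )
    z = (flat - flat.mean()) / sd
    return ZTrace(values=z, frame_rate_hz=frame_rate_hz, roi_id=roi_id)


def robust_zscore(raw: np.ndarray, frame_rate_hz: float, roi_id: int = 0) -> ZTrace:
    """Median/1.4826*MAD variant of :func:`detrend_zscore`.

    Useful for event-rich traces where transients inflate the full-trace
    SD; not the default.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 10:
        raise ValueError("robust_zscore needs at least 10 frames")
    flat = signal.detrend(raw, type="linear")
    med = np.median(flat)
    mad = 1.4826 * np.median(np.abs(flat - med))
    if mad < 1e-12 * max(1.0, np.abs(raw).max()):
        return ZTrace(
            values=np.zeros_like(flat),
            frame_rate_hz=frame_rate_hz,
            roi_id=roi_id,
            degenerate=True,
        )
    return ZTrace(values=(flat - med) / mad, frame_rate_hz=frame_rate_hz, roi_id=roi_id)


def ratiometric_correct(green_z: ZTrace, red_z: ZTrace) -> ZTrace:
    """Subtract the z-scored red trace from the z-scored green trace.

    tdTomato fluorescence is Ca2+-independent, so rapid shared
    fluctuations are movement artifacts; subtraction in z units makes the
    two fluorophores' incommensurate brightness irrelevant.
    """
    if len(green_z) != len(red_z):
        raise ValueError("green and red traces differ in length")
    return ZTrace(
        values=green_z.values - red_z.values,
        frame_rate_hz=green_z.frame_rate_hz,
        roi_id=green_z.roi_id,
        degenerate=green_z.degenerate and red_z.degenerate,
    )
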