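"""Ca2+ microdomain (CaM) map segmentation and manual-ROI ingestion.

CaMs are micrometre-scale hotspots in the processes of
oligodendrocyte-lineage cells.  Segmentation scores every pixel by the
maximum of its ~1 s-smoothed z-trace, thresholds the score, and splits
touching hotspots by watershed; noisy data (e.g. noradrenergic fibers)
can bypass segmentation entirely with user-drawn masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "MicrodomainMap",
    "SegmentationParams",
    "segment_microdomains",
    "load_manual_rois",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class MicrodomainMap:
    """Label image of CaM ROIs (0 background, 1..K) with physical areas."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        present = np.unique(self.labels)
        present = present[present != 0]
        expected = np.arange(1, present.size + 1)
        if not np.array_equal(np.sort(present), expected):
            raise ValueError("labels must be contiguous 1..K")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def roi_ids(self) -> list[int]:
        return list(range(1, self.n_rois + 1))

    @property
    def areas_um2(self) -> dict[int, float]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)
        px2 = self.pixel_size_um**2
        return {k: float(counts[k] * px2) for k in self.roi_ids}


@dataclass(frozen=True)
class SegmentationParams:
    """Activity-map segmentation knobs.

    activity_thresh_z: per-pixel score cut (max of smoothed z-trace).
    smooth_hz: temporal smoothing bandwidth of the score (boxcar of
        ~frame_rate/smooth_hz frames).
    min_area_um2: ROIs smaller than this are dropped.
    split_min_dist_um: minimum separation of watershed seeds.
    detrend: remove the per-pixel linear trend before scoring (turn
        off for drift-free data or order-invariance needs).
    """

    activity_thresh_z: float = 3.0
    smooth_hz: float = 1.0
    min_area_um2: float = 1.0
    split_min_dist_um: float = 2.0
    detrend: bool = True


def _pixel_activity(
    stack: np.ndarray, frame_rate_hz: float, smooth_hz: float, detrend: bool = True
) -> np.ndarray:
    """Max over time of the per-pixel detrended, z-scored, smoothed trace."""
    T = stack.shape[0]
    flat = stack.reshape(T, -1).astype(np.float32)
    if detrend:  # vectorized linear fit per pixel
        t = np.arange(T, dtype=np.float32)
        t0 = t - t.mean()
        slope = (t0 @ flat) / (t0 @ t0)
        flat = flat - np.outer(t, slope)
    flat -= flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd < 1e-12] = np.inf  # constant pixels score 0
    flat /= sd
    win = max(1, int(round(frame_rate_hz / smooth_hz)))
    if win > 1:
        flat = ndimage.uniform_filter1d(flat, size=win, axis=0)
    return flat.max(axis=0).reshape(stack.shape[1:])


def segment_microdomains(
    stack: np.ndarray,
    frame_rate_hz: float,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> MicrodomainMap:
    """Segment CaMs from a registered green-channel stack.

    Pixels whose smoothed-z activity score reaches
    ``activity_thresh_z`` form the foreground; 8-connected components
    below ``min_area_um2`` are removed and touching hotspots are split
    by watershed seeded at activity maxima at least
    ``split_min_dist_um`` apart.  If nothing is active an empty map is
    returned with a warning.
    """
    params = params or SegmentationParams()
    stack = np.asarray(stack)
    activity = _pixel_activity(stack, frame_rate_hz, params.smooth_hz, params.detrend)
    mask = activity >= params.activity_thresh_z

    min_px = max(1, int(round(params.min_area_um2 / pixel_size_um**2)))
    if mask.any():
        comp, _ = ndimage.label(mask, structure=_STRUCT8)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_px)
        mask &= ~np.isin(comp, small)

    if not mask.any():
        warnings.warn("no pixel exceeds the activity threshold; empty map", stacklevel=2)
        return MicrodomainMap(labels=np.zeros(mask.shape, dtype=np.int32),
                              pixel_size_um=pixel_size_um)

    smooth = ndimage.gaussian_filter(activity, sigma=2.0)
    min_dist = max(1, int(round(params.split_min_dist_um / pixel_size_um)))
    seeds = peak_local_max(
        smooth, min_distance=min_dist, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    # distance suppression can leave a connected component seedless,
    # which watershed would silently drop: seed those at their maximum
    comp, n_comp = ndimage.label(mask, structure=_STRUCT8)
    next_id = markers.max() + 1
    seeded = set(np.unique(comp[markers > 0])) - {0}
    for k in range(1, n_comp + 1):
        if k in seeded:
            continue
        member = comp == k
        flat = np.flatnonzero(member)
        best = flat[np.argmax(smooth.ravel()[flat])]
        markers.ravel()[best] = next_id
        next_id += 1
    labels = watershed(-smooth, markers=markers, mask=mask, connectivity=2)

    # drop fragments under the size floor created by splitting, relabel 1..K
    sizes = np.bincount(labels.ravel())
    for k in np.flatnonzero(sizes < min_px):
        if k:
            labels[labels == k] = 0
    return MicrodomainMap(labels=_relabel(labels), pixel_size_um=pixel_size_um)


def _relabel(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels != 0]), start=1):
        out[labels == old] = new
    return out


def load_manual_rois(
    mask: np.ndarray, pixel_size_um: float, movie_shape: tuple[int, int] | None = None
) -> MicrodomainMap:
    """Convert a binary or labelled manual-ROI mask into a CaM map.

    Binary masks are split into 8-connected components; labelled masks
    are relabelled to contiguous 1..K with areas preserved.  Used for
    data where automatic segmentation hypersegments (e.g. noradrenergic
    fibers).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("manual ROI mask must be 2D")
    if movie_shape is not None and tuple(mask.shape) != tuple(movie_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match movie shape {tuple(movie_shape)}"
        )
    uniq = np.unique(mask)
    uniq = uniq[uniq != 0]
    if uniq.size <= 1 and (uniq.size == 0 or mask.dtype == bool or uniq[0] == 1):
        labels, _ = ndimage.label(mask != 0, structure=_STRUCT8)
        labels = labels.astype(np.int32)
    else:
        labels = _relabel(mask.astype(np.int64))
    return MicrodomainMap(labels=labels, pixel_size_um=pixel_size_um)
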