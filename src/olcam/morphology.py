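"""Morphometric staging of oligodendrocyte-lineage cells.

Three features computed from a 2D soma mask and the root points of the
primary processes separate the lineage stages: soma area, soma
circularity (4*pi*A/P^2), and the dispersion of the primary processes
around the soma (standard deviation of consecutive inter-branch
distances expressed as fractions of the soma circumference).  OPCs have
small irregular somata with unevenly spaced branches; differentiation
brings a rounder, larger soma and evenly distributed processes (pmOL1
-> pmOL2 -> OL).

Numeric cut values are configurable; the defaults are calibrated
against the package's synthetic morphology generator, not taken from
any published dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

__all__ = [
    "MorphoMetrics",
    "StageThresholds",
    "soma_metrics",
    "branch_spread",
    "classify_stage",
    "roots_from_skeleton",
]

STAGES = ("OPC", "pmOL1", "pmOL2", "OL")


@dataclass
class MorphoMetrics:
    soma_area_um2: float
    circularity: float
    branch_spread: float | None
    stage: str = "unknown"


@dataclass(frozen=True)
class StageThresholds:
    """Cut values of the staging cascade.

    Cells at or below ``circ_opc`` are OPCs; then pmOL1 up to
    ``circ_pmol1``, pmOL2 up to ``circ_pmol2``; above that OL, demoted
    to pmOL2 when branch spread exceeds ``spread_ol_max``.  A small,
    unevenly branched cell (area <= ``area_opc_max`` and spread >=
    ``spread_opc_min``) is an OPC regardless of circularity.  Values on
    a cut go to the less-differentiated class.
    """

    circ_opc: float = 0.72
    circ_pmol1: float = 0.83
    circ_pmol2: float = 0.92
    spread_ol_max: float = 0.045
    area_opc_max: float = 52.0
    spread_opc_min: float = 0.17


def soma_metrics(soma_mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Area (um^2) and circularity of a single connected soma mask.

    Circularity is 4*pi*A/P^2 with the perimeter measured as the length
    of the traced boundary polygon after a short circular smoothing of
    its vertices (corner correction): the raw staircase polygon biases
    circularity low for smooth shapes.  Rasterization can still push a
    near-perfect disk slightly above 1.
    """
    mask = np.asarray(soma_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty soma mask")
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        raise ValueError(f"soma mask must be a single connected component (got {n})")
    area_px = int(mask.sum())
    perim_px = _smooth_perimeter(mask)
    area = area_px * pixel_size_um**2
    circularity = 4 * np.pi * area_px / perim_px**2
    return float(area), float(circularity)


def _smooth_perimeter(mask: np.ndarray, window: int = 5) -> float:
    """Length of the boundary polygon with corner-corrected vertices."""
    contour = max(find_contours(mask.astype(float), 0.5), key=len)[:-1]
    smoothed = np.column_stack(
        [
            ndimage.uniform_filter1d(contour[:, 0], window, mode="wrap"),
            ndimage.uniform_filter1d(contour[:, 1], window, mode="wrap"),
        ]
    )
    diffs = np.diff(np.vstack([smoothed, smoothed[:1]]), axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def _boundary_arclength(soma_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordered boundary polygon of the soma and its cumulative arc length."""
    contours = find_contours(np.asarray(soma_mask).astype(float), 0.5)
    contour = max(contours, key=lambda c: c.shape[0])
    seglen = np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate(([0.0], np.cumsum(seglen)))
    return contour, cum


def branch_spread(
    soma_mask: np.ndarray, roots: np.ndarray
) -> float | None:
    """SD of consecutive inter-branch arc fractions of the circumference.

    Roots are snapped to the nearest boundary-polygon vertex, ordered
    along the boundary, and the wrapped consecutive arc lengths are
    divided by the total perimeter; the population standard deviation
    of these fractions is returned (0 for perfectly even spacing,
    at most 0.5).  Undefined (None) for fewer than 2 roots.
    """
    roots = np.atleast_2d(np.asarray(roots, dtype=float))
    if roots.shape[0] < 2:
        return None
    contour, cum = _boundary_arclength(soma_mask)
    total = cum[-1]
    positions = []
    for pt in roots:
        d2 = ((contour - pt) ** 2).sum(axis=1)
        positions.append(cum[int(np.argmin(d2))])
    positions = np.sort(np.asarray(positions))
    gaps = np.diff(np.concatenate((positions, [positions[0] + total]))) / total
    return float(np.std(gaps))


def classify_stage(
    metrics: MorphoMetrics, thresholds: StageThresholds | None = None
) -> str:
    """Deterministic staging cascade over the three features.

    Low circularity (or a small soma with high branch dispersion) means
    OPC; intermediate circularity splits pmOL1/pmOL2; high circularity
    with tightly even branches means mature OL.  Returns ``unknown``
    only when a needed feature is undefined.
    """
    th = thresholds or StageThresholds()
    circ = metrics.circularity
    spread = metrics.branch_spread
    if circ is None or metrics.soma_area_um2 is None:
        return "unknown"
    if circ <= th.circ_opc:
        return "OPC"
    if (
        spread is not None
        and metrics.soma_area_um2 <= th.area_opc_max
        and spread >= th.spread_opc_min
    ):
        return "OPC"
    if circ <= th.circ_pmol1:
        return "pmOL1"
    if circ <= th.circ_pmol2:
        return "pmOL2"
    if spread is None:
        return "unknown"
    return "OL" if spread < th.spread_ol_max else "pmOL2"


def roots_from_skeleton(
    soma_mask: np.ndarray, skeleton_mask: np.ndarray
) -> np.ndarray:
    """Branch roots as the first skeleton points just outside the soma.

    For each connected component of ``skeleton & ~soma`` that touches
    the soma, the component pixel nearest the soma boundary is taken as
    the root of that primary process.
    """
    soma = np.asarray(soma_mask).astype(bool)
    skel = np.asarray(skeleton_mask).astype(bool)
    outside = skel & ~soma
    near_soma = ndimage.binary_dilation(soma, np.ones((3, 3), dtype=bool))
    comp, n = ndimage.label(outside, structure=np.ones((3, 3), dtype=bool))
    dist = ndimage.distance_transform_edt(~soma)
    roots = []
    for k in range(1, n + 1):
        member = comp == k
        if not (member & near_soma).any():
            continue
        ys, xs = np.nonzero(member)
        i = int(np.argmin(dist[ys, xs]))
        roots.append((int(ys[i]), int(xs[i])))
    return np.array(roots, dtype=int)
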