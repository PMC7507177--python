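"""Stage (b): unit-width centerline extraction, pruning, and feature points.

The segmentation border is first consolidated (extensive neighbor filtering,
bridge/fill, majority smoothing, small-hole filling) so that thinning does
not produce spurious loops, then homotopic thinning with replication padding
yields the initial centerline.  The Euclidean distance transform of the
segmentation, sampled on the centerline, gives a per-pixel vessel radius;
segments whose mean radius falls below the thickness threshold are pruned.
Branchpoints (>=3 skeleton neighbors) and endpoints (exactly 1) are reported
excluding the outermost row/column, where edge effects cause false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_config import BinaryMask, PipelineParams
from .morphology import (
    NeighborRule,
    _neighbor_count,
    bwmorph_op,
    euclidean_distance_map,
    fill_small_holes,
    neighbor_filter,
    thin_replicate_pad,
)

__all__ = [
    "CenterlineResult",
    "VesselSegment",
    "presmooth_for_skeleton",
    "initial_centerline",
    "sample_radii",
    "split_into_segments",
    "prune_thin_segments",
    "find_branchpoints",
    "find_endpoints",
    "extract_centerline",
]

RadiusMap = dict[tuple[int, int], float]
_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class VesselSegment:
    """One branch of the network: an 8-connected centerline path between
    junctions (or free ends), with its mean local radius in pixels."""

    pixel_list: list[tuple[int, int]]
    mean_radius_px: float


@dataclass(frozen=True)
class CenterlineResult:
    centerline: BinaryMask
    radius_map: RadiusMap
    branchpoints: list[tuple[int, int]]
    endpoints: list[tuple[int, int]]
    segments: list[VesselSegment] = field(default_factory=list)


def _pixels_of(mask: np.ndarray | BinaryMask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask).astype(bool, copy=False)


def presmooth_for_skeleton(mask: np.ndarray | BinaryMask) -> np.ndarray:
    """Consolidate a segmentation before thinning.

    Applies, in order: 8 iterations of the extensive >=4-neighbor rule;
    4 applications of (bridge, fill); one majority filter; filling of
    background holes below 80 px.
    """
    out = _pixels_of(mask)
    grow = NeighborRule("set_if", 4)
    for _ in range(8):
        out = neighbor_filter(out, grow)
    for _ in range(4):
        out = bwmorph_op(out, "bridge")
        out = bwmorph_op(out, "fill")
    out = bwmorph_op(out, "majority")
    out = fill_small_holes(out, 80)
    return out


def initial_centerline(mask: np.ndarray | BinaryMask) -> np.ndarray:
    """Unit-width skeleton of the presmoothed segmentation."""
    return thin_replicate_pad(presmooth_for_skeleton(mask))


def sample_radii(
    seg_mask: np.ndarray | BinaryMask, centerline: np.ndarray | BinaryMask
) -> RadiusMap:
    """Sample the segmentation's distance transform on the centerline pixels.

    Centerline pixels lying outside the segmentation (possible because
    presmoothing is extensive) get radius 0 and trigger a warning.
    """
    seg = _pixels_of(seg_mask)
    cl = _pixels_of(centerline)
    edt = euclidean_distance_map(seg)
    rows, cols = np.nonzero(cl)
    radii = {(int(r), int(c)): float(edt[r, c]) for r, c in zip(rows, cols)}
    n_outside = sum(1 for v in radii.values() if v == 0.0)
    if n_outside:
        warnings.warn(
            f"{n_outside} centerline pixel(s) fall outside the segmentation; "
            "radius 0 recorded",
            stacklevel=2,
        )
    return radii


def _branch_pixel_mask(cl: np.ndarray) -> np.ndarray:
    """Centerline pixels with >=3 centerline 8-neighbors (no border rule)."""
    return cl & (_neighbor_count(cl) >= 3)


def _ordered_component(pixels: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order an 8-connected thin component as a path (loops start anywhere)."""
    def neighbors(p):
        return [
            (p[0] + dr, p[1] + dc) for dr, dc in _EIGHT if (p[0] + dr, p[1] + dc) in pixels
        ]

    start = None
    for p in sorted(pixels):
        if len(neighbors(p)) <= 1:
            start = p
            break
    if start is None:  # loop
        start = min(pixels)
    order: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    stack = [start]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        order.append(p)
        for q in sorted(neighbors(p), reverse=True):
            if q not in seen:
                stack.append(q)
    return order


def split_into_segments(
    centerline: np.ndarray | BinaryMask, radius_map: RadiusMap
) -> list[VesselSegment]:
    """Cut the centerline at its branchpoints into individual segments.

    Branchpoint pixels themselves belong to no segment; the union of all
    segment pixels plus the branchpoints reconstitutes the centerline.
    """
    cl = _pixels_of(centerline)
    body = cl & ~_branch_pixel_mask(cl)
    labels, n = ndimage.label(body, structure=np.ones((3, 3), dtype=int))
    segments: list[VesselSegment] = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        pixels = {(int(r), int(c)) for r, c in zip(rows, cols)}
        radii = [radius_map.get(p, 0.0) for p in pixels]
        segments.append(
            VesselSegment(
                pixel_list=_ordered_component(pixels),
                mean_radius_px=float(np.mean(radii)),
            )
        )
    return segments


def prune_thin_segments(
    centerline: np.ndarray | BinaryMask,
    radius_map: RadiusMap,
    thickness_threshold: float,
) -> np.ndarray:
    """Remove segments whose mean radius is below the thickness threshold.

    Branchpoint pixels are restored only where at least two surviving
    segments still meet, then the result is cleaned with one spur pass, one
    clean pass, and a final thinning to convergence.
    """
    if thickness_threshold < 0:
        raise ValueError("thickness_threshold must be >= 0")
    cl = _pixels_of(centerline)
    branch = _branch_pixel_mask(cl)
    segments = split_into_segments(cl, radius_map)

    survivors = [s for s in segments if not s.mean_radius_px < thickness_threshold]
    out = np.zeros_like(cl)
    for seg in survivors:
        for r, c in seg.pixel_list:
            out[r, c] = True

    # Restore junction pixels still joining >=2 surviving segments.  Thinning
    # can leave a junction as a small 8-connected cluster of branch pixels, so
    # the decision is made per cluster — restoring single pixels would leave
    # the meeting arms disconnected through the rest of the cluster.
    surviving_sets = [set(s.pixel_list) for s in survivors]
    clusters, n_clusters = ndimage.label(branch, structure=np.ones((3, 3), dtype=int))
    for i in range(1, n_clusters + 1):
        cluster = [(int(r), int(c)) for r, c in zip(*np.nonzero(clusters == i))]
        touching = sum(
            1
            for pix in surviving_sets
            if any(
                (r + dr, c + dc) in pix for r, c in cluster for dr, dc in _EIGHT
            )
        )
        if touching >= 2:
            for r, c in cluster:
                out[r, c] = True

    out = bwmorph_op(out, "spur", 1)
    out = bwmorph_op(out, "clean", 1)
    out = bwmorph_op(out, "thin", float("inf"))
    return out


def find_branchpoints(centerline: np.ndarray | BinaryMask) -> list[tuple[int, int]]:
    """One representative pixel per skeleton junction, border excluded.

    Junction pixels are centerline pixels with >=3 centerline 8-neighbors.
    A single geometric junction can thin to a small 8-connected cluster of
    such pixels (two adjacent T-configurations at an X-crossing, for
    example), so clusters are merged and reported once, as their row-major
    first pixel.  A cluster touching the outermost row/column is ignored
    entirely: edge effects cause false positives there.
    """
    cl = _pixels_of(centerline)
    branch = cl & (_neighbor_count(cl) >= 3)
    clusters, n = ndimage.label(branch, structure=np.ones((3, 3), dtype=int))
    points: list[tuple[int, int]] = []
    h, w = cl.shape
    for i in range(1, n + 1):
        rows, cols = np.nonzero(clusters == i)
        on_border = (
            (rows == 0).any()
            or (rows == h - 1).any()
            or (cols == 0).any()
            or (cols == w - 1).any()
        )
        if on_border:
            continue
        order = np.lexsort((cols, rows))
        points.append((int(rows[order[0]]), int(cols[order[0]])))
    points.sort()
    return points


def find_endpoints(centerline: np.ndarray | BinaryMask) -> list[tuple[int, int]]:
    """Centerline pixels with exactly 1 centerline 8-neighbor, border excluded."""
    cl = _pixels_of(centerline)
    hits = cl & (_neighbor_count(cl) == 1)
    hits[0, :] = hits[-1, :] = False
    hits[:, 0] = hits[:, -1] = False
    rows, cols = np.nonzero(hits)
    return [(int(r), int(c)) for r, c in zip(rows, cols)]  # row-major order


def extract_centerline(
    seg_mask: BinaryMask, params: PipelineParams | None = None
) -> CenterlineResult:
    """Full stage-(b) chain from a segmentation to a pruned centerline.

    The radius samples are always taken from the distance transform of the
    *input* segmentation (not the presmoothed one), so pruning thresholds
    refer to the measured vessel thickness.
    """
    if params is None:
        params = PipelineParams()
    from .segmentation import dilate_for_centerline  # avoid import cycle

    seg_mask = dilate_for_centerline(seg_mask, params)
    seg = seg_mask.pixels

    cl0 = initial_centerline(seg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        radii0 = sample_radii(seg, cl0)
    cl = prune_thin_segments(cl0, radii0, params.vessel_thickness_threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        radius_map = sample_radii(seg, cl)
    segments = split_into_segments(cl, radius_map)
    return CenterlineResult(
        centerline=BinaryMask(pixels=cl, pixel_size_um=seg_mask.pixel_size_um),
        radius_map=radius_map,
        branchpoints=find_branchpoints(cl),
        endpoints=find_endpoints(cl),
        segments=segments,
    )
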