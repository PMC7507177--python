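"""Binary-morphology primitives shared by the segmentation and centerline stages.

All functions operate on plain 2D boolean numpy arrays and pin exact
semantics (neighborhood definitions, strict/non-strict thresholds, border
handling) so that the pipeline built on top of them is bit-reproducible.

Conventions
-----------
* Foreground connectivity is 8, background/hole connectivity is 4
  (topological duals).
* Off-image neighbors count as background.
* Box filters of size ``k`` place the output pixel at offset ``floor(k/2)``
  inside the window, i.e. the window spans ``[-floor(k/2), k-1-floor(k/2)]``
  relative to the pixel; this is well defined for even ``k`` too.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "NeighborRule",
    "box_blur",
    "neighbor_filter",
    "remove_small_components",
    "fill_small_holes",
    "local_majority_smooth",
    "bwmorph_op",
    "thin_replicate_pad",
    "euclidean_distance_map",
]

MorphKind = Literal["bridge", "fill", "majority", "clean", "spur", "thin"]

# 8-neighborhood offsets in row-major order with their bit weights for the
# bridge lookup table.
_RING_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class NeighborMode(str, Enum):
    """Whether a neighbor-count rule removes or adds pixels."""

    keep_if = "keep_if"
    set_if = "set_if"


@dataclass(frozen=True)
class NeighborRule:
    """Threshold rule on the number of true 8-neighbors (self excluded).

    ``keep_if`` is anti-extensive: a true pixel survives iff it has at least
    ``min_neighbors`` true neighbors.  ``set_if`` is extensive: a false pixel
    is set iff it has at least ``min_neighbors`` true neighbors.
    """

    mode: NeighborMode
    min_neighbors: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_neighbors <= 8:
            raise ValueError("min_neighbors must lie in [0, 8]")
        object.__setattr__(self, "mode", NeighborMode(self.mode))


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2D mask")
    return mask.astype(bool, copy=False)


def box_blur(img: np.ndarray, k: int, padding: str = "replicate") -> np.ndarray:
    """Mean filter over a k×k window with edge-replication padding.

    Even ``k`` is allowed; the window is anchored with the output pixel at
    offset ``floor(k/2)``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if padding != "replicate":
        raise ValueError("only replicate padding is supported")
    if k < 1:
        raise ValueError("filter size must be >= 1")
    if k > min(img.shape):
        raise ValueError(
            f"filter size {k} exceeds the smallest image dimension {min(img.shape)}"
        )
    if k == 1:
        return img.copy()
    # scipy's window anchoring matches the floor(k/2) convention exactly.
    return ndimage.uniform_filter(img, size=k, mode="nearest")


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of true pixels among the 8-neighborhood, self excluded."""
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.correlate(
        mask.astype(np.uint8), kernel, mode="constant", cval=0
    )


def neighbor_filter(mask: np.ndarray, rule: NeighborRule) -> np.ndarray:
    """Apply a :class:`NeighborRule` to a binary mask."""
    mask = _as_bool(mask)
    hit = _neighbor_count(mask) >= rule.min_neighbors
    if rule.mode is NeighborMode.keep_if:
        return mask & hit
    return mask | hit


def remove_small_components(
    mask: np.ndarray, min_area: int, connectivity: int = 8
) -> np.ndarray:
    """Remove 8-connected components with area strictly below ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if connectivity != 8:
        raise ValueError("only 8-connectivity is supported for the foreground")
    mask = _as_bool(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def fill_small_holes(
    mask: np.ndarray, max_area: int, background_connectivity: int = 4
) -> np.ndarray:
    """Set true every 4-connected background component of area < ``max_area``.

    Border-touching background components are treated the same as interior
    holes; only their (usually large) area protects them.
    """
    if max_area < 1:
        raise ValueError("max_area must be >= 1")
    if background_connectivity != 4:
        raise ValueError("only 4-connectivity is supported for the background")
    mask = _as_bool(mask)
    comp = ~mask
    labels, n = ndimage.label(comp)  # default structure = 4-connectivity
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    fill = areas < max_area
    fill[0] = False
    return mask | fill[labels]


def local_majority_smooth(mask: np.ndarray, k: int, frac: float = 0.5) -> np.ndarray:
    """Smooth a mask's border by thresholding the blurred complement.

    A pixel is foreground iff the local complement fraction over the k×k
    window does not exceed ``frac``.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    mask = _as_bool(mask)
    comp = box_blur((~mask).astype(float), k)
    return ~(comp > frac)


def _bridge_lut() -> np.ndarray:
    """256-entry lookup: ring config -> has >=2 mutually disconnected groups.

    Two true ring cells belong to the same group iff they are 8-adjacent as
    pixels within the 3×3 patch (the center removed).
    """
    lut = np.zeros(256, dtype=bool)
    for code in range(256):
        cells = [
            _RING_OFFSETS[b] for b in range(8) if code >> b & 1
        ]
        if len(cells) < 2:
            continue
        # union-find over the ring cells
        parent = list(range(len(cells)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                di = abs(cells[i][0] - cells[j][0])
                dj = abs(cells[i][1] - cells[j][1])
                if max(di, dj) <= 1:
                    parent[find(i)] = find(j)
        lut[code] = len({find(i) for i in range(len(cells))}) >= 2
    return lut


_BRIDGE_LUT = _bridge_lut()
_RING_WEIGHTS = np.zeros((3, 3), dtype=np.int32)
for _b, (_dr, _dc) in enumerate(_RING_OFFSETS):
    _RING_WEIGHTS[_dr + 1, _dc + 1] = 1 << _b


def _ring_code(mask: np.ndarray) -> np.ndarray:
    return ndimage.correlate(
        mask.astype(np.int32), _RING_WEIGHTS, mode="constant", cval=0
    )


def _bridge(mask: np.ndarray) -> np.ndarray:
    return mask | (~mask & _BRIDGE_LUT[_ring_code(mask)])


def _fill(mask: np.ndarray) -> np.ndarray:
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
    count4 = ndimage.correlate(mask.astype(np.uint8), kernel, mode="constant", cval=0)
    return mask | (~mask & (count4 == 4))


def _majority(mask: np.ndarray) -> np.ndarray:
    count9 = _neighbor_count(mask) + mask.astype(np.uint8)
    return count9 >= 5


def _clean(mask: np.ndarray) -> np.ndarray:
    return mask & (_neighbor_count(mask) >= 1)


def _spur(mask: np.ndarray) -> np.ndarray:
    return mask & (_neighbor_count(mask) >= 2)


def _ring_components(code: int, *, cells_true: bool, four_connected: bool) -> list[set]:
    """Connected components of the (true or false) ring cells of a 3×3 patch."""
    cells = [
        _RING_OFFSETS[b] for b in range(8) if bool(code >> b & 1) == cells_true
    ]
    comps: list[set] = []
    for cell in cells:
        merged = {cell}
        rest = []
        for comp in comps:
            if any(
                (abs(cell[0] - q[0]) + abs(cell[1] - q[1]) == 1)
                if four_connected
                else (max(abs(cell[0] - q[0]), abs(cell[1] - q[1])) == 1)
                for q in comp
            ):
                merged |= comp
            else:
                rest.append(comp)
        comps = rest + [merged]
    # transitive closure (a cell can bridge two previously separate comps)
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(
                    (abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1)
                    if four_connected
                    else (max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1)
                    for a in comps[i]
                    for b in comps[j]
                ):
                    comps[i] |= comps[j]
                    del comps[j]
                    changed = True
                    break
            if changed:
                break
    return comps


def _simple_point_lut() -> np.ndarray:
    """LUT over 8-neighborhood configs: deleting the center preserves topology.

    A foreground pixel is (8,4)-simple iff its true ring cells form exactly
    one 8-connected component and its false ring cells form exactly one
    4-connected component containing a 4-neighbor of the center.
    """
    lut = np.zeros(256, dtype=bool)
    four_neighbors = {(-1, 0), (1, 0), (0, -1), (0, 1)}
    for code in range(256):
        fg = _ring_components(code, cells_true=True, four_connected=False)
        bg = _ring_components(code, cells_true=False, four_connected=True)
        bg_adj = [c for c in bg if c & four_neighbors]
        lut[code] = len(fg) == 1 and len(bg_adj) == 1
    return lut


_SIMPLE_LUT = _simple_point_lut()
_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint8)


def _thin_mask(mask: np.ndarray, max_passes: int | None) -> np.ndarray:
    """Sequential homotopic thinning.

    Each pass visits the north, east, south and west border pixels in turn
    (row-major within a sub-pass) and deletes a pixel only if it is still an
    (8,4)-simple point and not a line endpoint at the moment of deletion, so
    foreground 8-components and background 4-components are preserved by
    construction.  At convergence the result is unit-width and idempotent.
    """
    m = np.pad(mask, 1, constant_values=False)
    directions = ((-1, 0), (0, 1), (1, 0), (0, -1))
    passes = 0
    while max_passes is None or passes < max_passes:
        changed = False
        # Candidates for all four sub-passes are frozen at pass start so one
        # pass peels at most the current boundary layer (deletions in an
        # earlier sub-pass must not expose new candidates within the pass).
        interior = m[1:-1, 1:-1]
        cand_lists = []
        for dr, dc in directions:
            shifted = m[1 + dr : m.shape[0] - 1 + dr, 1 + dc : m.shape[1] - 1 + dc]
            cand_lists.append(np.argwhere(interior & ~shifted))
        for cand in cand_lists:
            for rr, cc in cand:
                r, c = rr + 1, cc + 1
                if not m[r, c]:
                    continue
                code = (
                    int(m[r - 1, c - 1])
                    | int(m[r - 1, c]) << 1
                    | int(m[r - 1, c + 1]) << 2
                    | int(m[r, c - 1]) << 3
                    | int(m[r, c + 1]) << 4
                    | int(m[r + 1, c - 1]) << 5
                    | int(m[r + 1, c]) << 6
                    | int(m[r + 1, c + 1]) << 7
                )
                if _SIMPLE_LUT[code] and _POPCOUNT[code] >= 2:
                    m[r, c] = False
                    changed = True
        passes += 1
        if not changed:
            break
    return m[1:-1, 1:-1]


def bwmorph_op(mask: np.ndarray, kind: MorphKind, n_iter: int | float = 1) -> np.ndarray:
    """Classic binary morphological operations on 2D masks.

    Parameters
    ----------
    kind:
        ``bridge``   — set a false pixel iff it has >=2 true 8-neighbors that
        are not 8-connected to each other within its 3×3 neighborhood.
        ``fill``     — set a false pixel iff all four 4-neighbors are true.
        ``majority`` — pixel true iff >=5 of the 9 pixels in its 3×3
        neighborhood (self included) are true.
        ``clean``    — remove isolated true pixels (0 true 8-neighbors).
        ``spur``     — remove endpoint pixels (<=1 true 8-neighbor).
        ``thin``     — homotopic thinning; at convergence the result is
        unit-width (no 2×2 all-true block) and idempotent.
    n_iter:
        Number of applications; ``math.inf`` (or ``None``) iterates to a
        fixed point.
    """
    mask = _as_bool(mask)
    infinite = n_iter is None or n_iter == float("inf")
    if not infinite and (int(n_iter) != n_iter or n_iter < 1):
        raise ValueError("n_iter must be a positive integer or inf")

    if kind == "thin":
        return _thin_mask(mask, None if infinite else int(n_iter))

    ops = {
        "bridge": _bridge,
        "fill": _fill,
        "majority": _majority,
        "clean": _clean,
        "spur": _spur,
    }
    try:
        op = ops[kind]
    except KeyError:
        raise ValueError(f"unknown operation {kind!r}") from None

    out = mask
    if infinite:
        while True:
            nxt = op(out)
            if np.array_equal(nxt, out):
                return nxt
            out = nxt
    for _ in range(int(n_iter)):
        out = op(out)
    return out


def thin_replicate_pad(mask: np.ndarray) -> np.ndarray:
    """Thin to convergence with edge-replication padding, then crop.

    Without padding, thinning retracts centerlines of vessels that cross the
    image border; replicating the border rows/columns lets the skeleton reach
    the edge.  The pad width adapts to the thickest structure present.
    """
    mask = _as_bool(mask)
    if not mask.any():
        return mask.copy()
    radius = float(euclidean_distance_map(mask).max())
    pad = int(np.ceil(radius)) + 2
    padded = np.pad(mask, pad, mode="edge")
    thinned = bwmorph_op(padded, "thin", n_iter=float("inf"))
    return thinned[pad:-pad, pad:-pad]


def euclidean_distance_map(mask: np.ndarray) -> np.ndarray:
    """Distance (px, center-to-center) from each pixel to the nearest false pixel.

    Zero on false pixels; sampled on a centerline it gives the local vessel
    radius.
    """
    mask = _as_bool(mask)
    return ndimage.distance_transform_edt(mask)
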