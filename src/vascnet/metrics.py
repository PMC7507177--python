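"""The four vessel-architecture metrics computed from a segmentation and
centerline pair.

* vessel length density — centerline pixel count converted to mm, divided by
  the field of view in mm² (no diagonal √2 correction: length is defined as
  the raw pixel count).
* vessel area fraction — fraction of segmented pixels, unitless.
* mean vessel diameter — mean over centerline pixels of (2·EDT − 1) scaled
  to µm, where EDT is the distance to the nearest background pixel.
* branchpoint count — number of detected skeleton junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .centerline import CenterlineResult
from .io_config import BinaryMask
from .morphology import euclidean_distance_map

__all__ = [
    "VesselMetrics",
    "vessel_area_fraction",
    "vessel_length_density",
    "mean_vessel_diameter",
    "branchpoint_count",
    "px_to_um",
    "px_area_to_um2",
    "quantify",
]


@dataclass(frozen=True)
class VesselMetrics:
    """Architecture metrics for one image.

    ``mean_vessel_diameter`` is NaN when the centerline is empty (reported
    as missing downstream, never as 0).
    """

    vessel_length_density: float  # mm / mm²
    vessel_area_fraction: float  # unitless
    mean_vessel_diameter: float  # µm
    branchpoint_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.vessel_area_fraction <= 1.0:
            raise ValueError("vessel_area_fraction must lie in [0, 1]")
        if self.vessel_length_density < 0:
            raise ValueError("vessel_length_density must be >= 0")
        if self.branchpoint_count < 0 or int(self.branchpoint_count) != self.branchpoint_count:
            raise ValueError("branchpoint_count must be a nonnegative integer")


def _pixels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def vessel_area_fraction(seg: BinaryMask | np.ndarray) -> float:
    """Fraction of true pixels in the segmentation."""
    px = _pixels(seg)
    return float(np.count_nonzero(px)) / px.size


def vessel_length_density(
    centerline: BinaryMask, pixel_size_um: float | None = None
) -> float:
    """Centerline length (mm) per field-of-view area (mm²)."""
    px = _pixels(centerline)
    if px.size == 0:
        raise ValueError("zero-size image")
    if pixel_size_um is None:
        pixel_size_um = centerline.pixel_size_um
    n_true = float(np.count_nonzero(px))
    length_mm = n_true * pixel_size_um * 1e-3
    area_mm2 = px.size * pixel_size_um**2 * 1e-6
    return length_mm / area_mm2


def mean_vessel_diameter(
    seg: BinaryMask,
    centerline: BinaryMask | np.ndarray,
    pixel_size_um: float | None = None,
) -> float:
    """Mean of (2·EDT − 1)·pixel_size over centerline pixels, in µm.

    Returns NaN for an empty centerline (the diameter is then undefined).
    """
    seg_px = _pixels(seg)
    cl_px = _pixels(centerline)
    if seg_px.shape != cl_px.shape:
        raise ValueError("segmentation and centerline shapes differ")
    if pixel_size_um is None:
        pixel_size_um = seg.pixel_size_um
    if not cl_px.any():
        return math.nan
    radii = euclidean_distance_map(seg_px)[cl_px]
    return float(np.mean(2.0 * radii - 1.0) * pixel_size_um)


def branchpoint_count(result: CenterlineResult) -> int:
    """Number of skeleton junction pixels detected (border excluded)."""
    return len(result.branchpoints)


def px_to_um(length_px: float, pixel_size_um: float) -> float:
    """Convert a length in pixels to µm."""
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    return length_px * pixel_size_um


def px_area_to_um2(area_px: float, pixel_size_um: float) -> float:
    """Convert an area in pixels to µm²."""
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    return area_px * pixel_size_um**2


def quantify(seg: BinaryMask, result: CenterlineResult) -> VesselMetrics:
    """Bundle the four metrics for one image."""
    return VesselMetrics(
        vessel_length_density=vessel_length_density(result.centerline),
        vessel_area_fraction=vessel_area_fraction(seg),
        mean_vessel_diameter=mean_vessel_diameter(seg, result.centerline),
        branchpoint_count=branchpoint_count(result),
    )
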