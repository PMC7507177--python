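"""Stage (a): binary vessel segmentation from an intensity image.

Vessels are detected by intensity over local background: a lightly blurred
copy of the image minus a heavily blurred background estimate is thresholded,
then the initial mask is cleaned with neighbor filtering, small-component
removal, border smoothing, hole filling and one thinning pass (which
compensates for the net one-pixel dilation the smoothing steps introduce).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_config import BinaryMask, IntensityImage, PipelineParams
from .morphology import (
    NeighborRule,
    box_blur,
    bwmorph_op,
    fill_small_holes,
    local_majority_smooth,
    neighbor_filter,
    remove_small_components,
)

__all__ = ["SegmentationResult", "background_subtract", "segment_vessels"]


@dataclass(frozen=True)
class SegmentationResult:
    """Final vessel mask plus the background-subtracted image for diagnostics."""

    mask: BinaryMask
    background_subtracted: np.ndarray
    params_used: PipelineParams


def background_subtract(
    img: IntensityImage | np.ndarray, light_k: int, heavy_k: int
) -> np.ndarray:
    """Lightly blurred image minus heavily blurred background estimate.

    Values may be negative (darker than local background); they are kept,
    since the subsequent threshold treats them identically either way.
    """
    if not light_k < heavy_k:
        raise ValueError("light blur size must be smaller than the background filter")
    pixels = img.pixels if isinstance(img, IntensityImage) else np.asarray(img, float)
    return box_blur(pixels, light_k) - box_blur(pixels, heavy_k)


def segment_vessels(img: IntensityImage, params: PipelineParams | None = None) -> SegmentationResult:
    """Segment the vessel network of a unit-range intensity image.

    Steps, in order: background subtraction; strict threshold at
    ``grey_to_binary_threshold``; keep pixels with >=4 true 8-neighbors;
    remove components below ``min_connected_component_area``; local majority
    smoothing of the border; fill background holes below
    ``hole_fill_area_seg``; one thinning pass; remove small components again.
    """
    if params is None:
        params = PipelineParams()

    subtracted = background_subtract(
        img, params.light_blur_size, params.averaging_filter_size
    )
    mask = subtracted > params.grey_to_binary_threshold
    mask = neighbor_filter(mask, NeighborRule("keep_if", 4))
    mask = remove_small_components(mask, params.min_connected_component_area)
    mask = local_majority_smooth(mask, params.smooth_filter_size, 0.5)
    mask = fill_small_holes(mask, params.hole_fill_area_seg)
    mask = bwmorph_op(mask, "thin", n_iter=1)
    mask = remove_small_components(mask, params.min_connected_component_area)

    return SegmentationResult(
        mask=BinaryMask(pixels=mask, pixel_size_um=img.pixel_size_um),
        background_subtracted=subtracted,
        params_used=params,
    )


def dilate_for_centerline(mask: BinaryMask, params: PipelineParams) -> BinaryMask:
    """Optional mask dilation before centerline extraction.

    Controlled by ``wire_dilation_threshold`` (default 0 = no-op): when
    positive, the mask is dilated by that many 8-connected iterations.
    """
    if params.wire_dilation_threshold <= 0:
        return mask
    dilated = ndimage.binary_dilation(
        mask.pixels,
        structure=np.ones((3, 3), dtype=bool),
        iterations=int(params.wire_dilation_threshold),
    )
    return BinaryMask(pixels=dilated, pixel_size_um=mask.pixel_size_um)
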