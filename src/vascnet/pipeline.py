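"""End-to-end convenience: intensity image -> masks + metrics."""

from __future__ import annotations

from dataclasses import dataclass

from .centerline import CenterlineResult, extract_centerline
from .io_config import IntensityImage, PipelineParams
from .metrics import VesselMetrics, quantify
from .segmentation import SegmentationResult, segment_vessels

__all__ = ["AnalysisResult", "analyze_image"]


@dataclass(frozen=True)
class AnalysisResult:
    segmentation: SegmentationResult
    centerline: CenterlineResult
    metrics: VesselMetrics


def analyze_image(
    img: IntensityImage, params: PipelineParams | None = None
) -> AnalysisResult:
    """Run segmentation, centerline extraction, and quantification."""
    if params is None:
        params = PipelineParams()
    seg = segment_vessels(img, params)
    cl = extract_centerline(seg.mask, params)
    return AnalysisResult(
        segmentation=seg, centerline=cl, metrics=quantify(seg.mask, cl)
    )
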