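"""Pixel-level and metric-level evaluation against a ground-truth analysis.

Confusion counts compare a predicted segmentation with a reference mask
pixel by pixel.  Metric-level evaluation uses the signed error E = Y − G,
the absolute error A = |E|, and a per-image precision statistic
P_i = |E_i − median(E)| (the Brown–Forsythe variable transform: absolute
deviation from the group median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_config import BinaryMask
from .metrics import VesselMetrics

__all__ = [
    "ConfusionCounts",
    "SegmentationScores",
    "ErrorRecord",
    "confusion_counts",
    "segmentation_scores",
    "error_table",
    "precision_residuals",
]

_METRIC_NAMES = (
    "vessel_length_density",
    "vessel_area_fraction",
    "mean_vessel_diameter",
    "branchpoint_count",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel classification tallies; tp+tn+fp+fn equals the image size."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class SegmentationScores:
    """Pixel-level agreement scores; undefined ratios are NaN.

    ``precision_ppv`` (TP/(TP+FP)) is reported alongside the standard
    sensitivity TP/(TP+FN) so both common readings are always available.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision_ppv: float


@dataclass(frozen=True)
class ErrorRecord:
    """Signed and absolute error of one metric on one image."""

    image_id: str
    metric_name: str
    measured: float
    truth: float
    error: float
    absolute_error: float


def _pixels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def confusion_counts(
    pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray
) -> ConfusionCounts:
    """Per-pixel TP/TN/FP/FN tallies of a prediction against a reference."""
    p = _pixels(pred)
    t = _pixels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def segmentation_scores(c: ConfusionCounts) -> SegmentationScores:
    """Accuracy, sensitivity, specificity and precision from confusion counts."""
    if c.total <= 0:
        raise ValueError("empty confusion counts")
    return SegmentationScores(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision_ppv=_ratio(c.tp, c.tp + c.fp),
    )


def error_table(
    measured: Sequence[tuple[str, VesselMetrics]],
    truth: Sequence[tuple[str, VesselMetrics]],
) -> list[ErrorRecord]:
    """Per-image, per-metric signed and absolute errors vs ground truth.

    The two lists must carry the same image ids in the same order.
    """
    if len(measured) != len(truth):
        raise ValueError("measured and truth lists differ in length")
    records: list[ErrorRecord] = []
    for (mid, m), (tid, g) in zip(measured, truth):
        if mid != tid:
            raise ValueError(f"image id mismatch: {mid!r} vs {tid!r}")
        for name in _METRIC_NAMES:
            y = float(getattr(m, name))
            gval = float(getattr(g, name))
            e = y - gval
            records.append(
                ErrorRecord(
                    image_id=mid,
                    metric_name=name,
                    measured=y,
                    truth=gval,
                    error=e,
                    absolute_error=abs(e),
                )
            )
    return records


def precision_residuals(errors: Sequence[float]) -> list[float]:
    """Absolute deviation of each error from the group median.

    For an even number of images the median is the midpoint of the two
    central order statistics.
    """
    if len(errors) == 0:
        raise ValueError("need at least one error value")
    arr = np.asarray(errors, dtype=float)
    med = float(np.median(arr))
    return [float(abs(e - med)) for e in arr]
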