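"""Percent-area collagen coverage after global thresholding.

The coverage readout follows the conventional SHG workflow: a single
threshold, chosen once for a whole study, converts every image to binary,
and coverage is the percentage of (ROI) pixels above threshold. For
z-stacks coverage is reported per depth and at its peak. An Otsu threshold
pooled over all study images is provided as a reproducible stand-in for a
manually chosen global value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import EmptyRoiError
from .images import ImageStack, RoiMask, SHGImage

__all__ = [
    "BinaryMask",
    "CoverageResult",
    "binarize",
    "coverage_fraction",
    "coverage_by_depth",
    "pooled_otsu_threshold",
]


@dataclass(frozen=True)
class BinaryMask:
    """Binary (above-threshold) image, same shape as its source."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class CoverageResult:
    coverage_percent: float
    n_roi_pixels: int
    threshold_used: float
    by_depth: tuple[tuple[float, float], ...] | None = None  # (depth_um, percent)
    peak_coverage_percent: float | None = None


def binarize(img: SHGImage, threshold: float) -> BinaryMask:
    """Pixel is foreground iff its intensity is strictly above ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(img.pixels > threshold)


def coverage_fraction(
    mask: BinaryMask, roi: RoiMask | None = None, threshold_used: float = float("nan")
) -> CoverageResult:
    """Percentage of ROI pixels (whole image if ``roi`` is None) that are foreground."""
    if roi is not None:
        if roi.shape != mask.shape:
            raise ValueError("ROI shape does not match mask shape")
        sel = roi.pixels
        n = int(sel.sum())
        if n == 0:
            raise EmptyRoiError("ROI contains no pixels")
        covered = int((mask.pixels & sel).sum())
    else:
        n = mask.pixels.size
        covered = int(mask.pixels.sum())
    return CoverageResult(100.0 * covered / n, n, threshold_used)


def coverage_by_depth(
    stack: ImageStack, threshold: float, roi: RoiMask | None = None
) -> CoverageResult:
    """Per-slice coverage profile and its peak; depth = slice index × depth step."""
    by_depth = []
    for k, img in enumerate(stack):
        r = coverage_fraction(binarize(img, threshold), roi, threshold_used=threshold)
        by_depth.append((k * stack.depth_step_um, r.coverage_percent))
    percents = [p for _, p in by_depth]
    first = coverage_fraction(binarize(stack.slices[0], threshold), roi, threshold)
    return CoverageResult(
        coverage_percent=percents[0],
        n_roi_pixels=first.n_roi_pixels,
        threshold_used=threshold,
        by_depth=tuple(by_depth),
        peak_coverage_percent=max(percents),
    )


def pooled_otsu_threshold(images, roi_by_image=None) -> float:
    """Otsu threshold on the pooled intensity histogram of all study images.

    A reproducible surrogate for a single manually chosen global threshold:
    computed once on the pooled data, then applied unchanged to every image.
    """
    pools = []
    for k, img in enumerate(images):
        px = img.pixels
        if roi_by_image is not None and roi_by_image[k] is not None:
            px = px[roi_by_image[k].pixels]
        pools.append(px.ravel())
    pooled = np.concatenate(pools)
    if pooled.min() == pooled.max():
        return float(pooled.min())
    return float(threshold_otsu(pooled))
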