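"""Quantitative artifact and homogeneity measures.

All measures operate on HU images with explicit regions of interest:
streak artifact (affected-minus-remote mean), cupping (darkest-minus-
brightest small-ROI means inside a region), ROI homogeneity (SD of ROI
means along the myocardium) and flow-map coefficient of variation.
Every measure except the cupping-reduction percentage is invariant to a
global HU offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .perfusion import FlowMap

__all__ = [
    "circular_roi",
    "streak_artifact",
    "cupping",
    "cupping_reduction",
    "roi_homogeneity",
    "flow_cov",
    "ArtifactReport",
]


def circular_roi(
    shape: tuple[int, int],
    center_xy_mm: tuple[float, float],
    radius_mm: float,
    pixel_size_mm: float,
) -> np.ndarray:
    """Boolean mask of a circular ROI given in physical coordinates (y up)."""
    n = shape[0]
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:shape[1]]
    x = (cols - c) * pixel_size_mm
    y = (c - rows) * pixel_size_mm
    mask = (x - center_xy_mm[0]) ** 2 + (y - center_xy_mm[1]) ** 2 <= radius_mm**2
    if not mask.any():
        raise ValueError("ROI lies outside the image")
    return mask


def streak_artifact(
    values: np.ndarray, roi_affected: np.ndarray, roi_remote: np.ndarray
) -> float:
    """mean(affected) - mean(remote); negative when the artifact darkens."""
    roi_affected = np.asarray(roi_affected, dtype=bool)
    roi_remote = np.asarray(roi_remote, dtype=bool)
    if (roi_affected & roi_remote).any():
        raise ValueError("affected and remote ROIs overlap")
    return float(values[roi_affected].mean() - values[roi_remote].mean())


def cupping(
    values: np.ndarray, region: np.ndarray, roi_size: int = 3,
    median_size: int = 3,
) -> float:
    """Darkest-minus-brightest small-ROI means within a region (<= 0 for cupping).

    The extreme points are located on a median-filtered copy so single
    noisy pixels do not define them; the means themselves are taken over
    ``roi_size`` x ``roi_size`` boxes of the original values.
    """
    region = np.asarray(region, dtype=bool)
    if region.sum() < 2 * roi_size * roi_size:
        raise ValueError("region too small for two cupping ROIs")
    smooth = ndimage.median_filter(np.asarray(values, dtype=float), median_size)
    masked = np.where(region, smooth, np.nan)
    dark = np.unravel_index(np.nanargmin(masked), masked.shape)
    bright = np.unravel_index(np.nanargmax(masked), masked.shape)

    def box_mean(center):
        h = roi_size // 2
        r0, c0 = center
        sl = np.s_[max(r0 - h, 0):r0 + h + 1, max(c0 - h, 0):c0 + h + 1]
        return float(np.asarray(values, dtype=float)[sl].mean())

    return box_mean(dark) - box_mean(bright)


def cupping_reduction(cupping_original: float, cupping_corrected: float) -> float:
    """Percent reduction: |original - corrected| / |original| * 100."""
    if cupping_original == 0:
        raise ZeroDivisionError("original cupping is zero")
    return (
        abs(abs(cupping_original) - abs(cupping_corrected))
        / abs(cupping_original)
        * 100.0
    )


def roi_homogeneity(values: np.ndarray, rois: list[np.ndarray]) -> float:
    """Sample SD of per-ROI mean HU across the myocardium."""
    if len(rois) < 2:
        raise ValueError("need at least two ROIs")
    means = [float(values[np.asarray(r, dtype=bool)].mean()) for r in rois]
    return float(np.std(means, ddof=1))


def flow_cov(fmap: FlowMap, mask: np.ndarray | None = None) -> float:
    """Coefficient of variation (%) of super-pixel flows, 100*SD/mean."""
    if mask is None:
        flows = fmap.region_flows
    else:
        v = fmap.values[np.asarray(mask, dtype=bool)]
        flows = v[np.isfinite(v)]
    if flows.size < 2:
        raise ValueError("need at least two fitted flow values")
    mean = float(np.mean(flows))
    if mean == 0:
        raise ZeroDivisionError("zero mean flow")
    return 100.0 * float(np.std(flows)) / mean


@dataclass
class ArtifactReport:
    """Collected artifact measures for one experiment."""

    streak_hu: float | None = None
    cupping_hu: float | None = None
    cupping_reduction_pct: float | None = None
    roi_means_hu: list[float] = field(default_factory=list)
    roi_sd_hu: float | None = None
    flow_cov_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "streak_hu": self.streak_hu,
            "cupping_hu": self.cupping_hu,
            "cupping_reduction_pct": self.cupping_reduction_pct,
            "roi_means_hu": self.roi_means_hu,
            "roi_sd_hu": self.roi_sd_hu,
            "flow_cov_pct": self.flow_cov_pct,
        }
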