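"""Widefield quantification: background flattening, cluster counting/sizing,
surface/total membrane ratio, and ratiometric chloride-probe traces.

Cluster detection runs on a background-flattened image, but every intensity
measurement is taken on the raw image — the flattened image only outlines
the clusters. The detection threshold is a user/config value fixed per
experiment batch (conditions compared were acquired with identical exposure),
never auto-chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_KERNEL_SIZE = 3
DEFAULT_PIXEL_SIZE_NM = 190.0


@dataclass
class ClusterSet:
    """Per-ROI cluster quantification (areas in µm², raw-image intensities)."""

    labels: np.ndarray
    areas_um2: np.ndarray
    mean_raw_intensities: np.ndarray
    roi_area_um2: float

    @property
    def n_clusters(self) -> int:
        return self.areas_um2.size

    @property
    def density_per_um2(self) -> float:
        return self.n_clusters / self.roi_area_um2

    def to_frame(self, metadata: dict | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"area_um2": self.areas_um2, "mean_raw_intensity": self.mean_raw_intensities}
        )
        if metadata:
            for k, v in metadata.items():
                df[k] = v
        return df


@dataclass
class RatioTrace:
    """Background-subtracted ratiometric readout per timepoint."""

    ratios: np.ndarray
    valid: np.ndarray
    period_s: float = 30.0

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios[self.valid].mean())


def flatten_background(img: np.ndarray, kernel_size: int = DEFAULT_KERNEL_SIZE) -> np.ndarray:
    """Subtract the local median background (kernel_size × kernel_size),
    clipping at zero. Enhances cluster outlines for detection only."""
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    if kernel_size > min(img.shape):
        raise ValueError("kernel larger than image")
    bg = ndimage.median_filter(img.astype(float), size=kernel_size)
    return np.clip(img.astype(float) - bg, 0.0, None)


def segment_clusters(
    flattened: np.ndarray,
    raw: np.ndarray,
    roi: np.ndarray,
    threshold: float,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> ClusterSet:
    """Threshold the flattened image within an ROI and measure clusters.

    Connected components of ``flattened >= threshold`` inside the ROI; per
    cluster the pixel area (µm²) and the mean intensity on the *raw* image;
    the cluster count divided by the ROI area gives the density.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    roi = roi.astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    binary = (flattened >= threshold) & roi
    labels, n_lab = ndimage.label(binary, structure=np.ones((3, 3)))
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    areas, intensities = [], []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        areas.append(sel.sum() * px_area_um2)
        intensities.append(float(raw[sel].mean()))
    return ClusterSet(
        labels=labels,
        areas_um2=np.asarray(areas),
        mean_raw_intensities=np.asarray(intensities),
        roi_area_um2=float(roi.sum()) * px_area_um2,
    )


def roi_mean_intensity(img: np.ndarray, roi: np.ndarray) -> float:
    """Average raw pixel intensity inside an ROI."""
    roi = roi.astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return float(img[roi].mean())


def surface_total_ratio(
    surface_img: np.ndarray, total_img: np.ndarray, roi: np.ndarray
) -> float:
    """Mean(surface)/mean(total) within a common dendritic ROI."""
    num = roi_mean_intensity(surface_img, roi)
    den = roi_mean_intensity(total_img, roi)
    if den == 0:
        raise ZeroDivisionError("total-channel ROI mean is zero")
    return num / den


def ratiometric_trace(
    num_stack: np.ndarray,
    den_stack: np.ndarray,
    roi: np.ndarray,
    bg_roi: np.ndarray,
    period_s: float = 30.0,
) -> RatioTrace:
    """Background-subtracted per-frame ratio of two image stacks.

    ratio(t) = (mean_num(roi) − mean_num(bg)) / (mean_den(roi) − mean_den(bg));
    frames whose denominator is ≤ 0 after background subtraction are flagged
    invalid and excluded from the summary mean.
    """
    if num_stack.shape != den_stack.shape:
        raise ValueError("numerator and denominator stacks differ in shape")
    n = num_stack.shape[0]
    ratios = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        num = roi_mean_intensity(num_stack[t], roi) - roi_mean_intensity(num_stack[t], bg_roi)
        den = roi_mean_intensity(den_stack[t], roi) - roi_mean_intensity(den_stack[t], bg_roi)
        if den > 0:
            ratios[t] = num / den
            valid[t] = True
    return RatioTrace(ratios=ratios, valid=valid, period_s=period_s)
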