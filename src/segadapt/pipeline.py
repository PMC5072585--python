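"""Parameterized feedforward segmentation pipeline.

Stages: mean-filter pre-processing (window ``w``), segmentation by manual
intensity threshold, Otsu threshold or Sobel edge detection (threshold
``t``), morphological opening (disk of diameter ``s``), and 8-connected
component labeling.  All images are float arrays normalized to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "METHODS",
    "ParameterVector",
    "ParameterError",
    "DegenerateImageError",
    "mean_filter",
    "threshold_segment",
    "otsu_threshold",
    "auto_edge_threshold",
    "sobel_magnitude",
    "sobel_segment",
    "mask_from_magnitude",
    "opening",
    "label_mask",
    "run_pipeline",
]

#: closed set of segmentation methods
METHODS = ("manual_threshold", "otsu", "sobel_edge")


class ParameterError(ValueError):
    """Invalid pipeline parameter (even window size, t out of range, ...)."""


class DegenerateImageError(ValueError):
    """Input unsuitable for a data-driven threshold (e.g. constant image)."""


@dataclass(frozen=True)
class ParameterVector:
    """Pipeline parameters ``(w, t, s)``: convolution window side, threshold
    and opening structuring-element diameter."""

    w: int = 1
    t: float = 0.5
    s: int = 1

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise ParameterError(f"w must be odd and >= 1, got {self.w}")
        if self.s < 1 or self.s % 2 == 0:
            raise ParameterError(f"s must be odd and >= 1, got {self.s}")
        if not 0.0 <= self.t <= 1.0:
            raise ParameterError(f"t must lie in [0, 1], got {self.t}")


def mean_filter(image: np.ndarray, w: int) -> np.ndarray:
    """Convolve with a ``w x w`` box kernel of weights ``1 / w**2``,
    replicate padding at the border."""
    if w < 1 or w % 2 == 0:
        raise ParameterError(f"w must be odd and >= 1, got {w}")
    if w == 1:
        return np.asarray(image, dtype=float).copy()
    return ndimage.uniform_filter(np.asarray(image, dtype=float), size=w, mode="nearest")


def threshold_segment(image: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of pixels strictly above ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"t must lie in [0, 1], got {t}")
    return np.asarray(image) > t


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold minimizing within-class intensity variance.

    Raises
    ------
    DegenerateImageError
        If the image has fewer than two distinct gray values.
    """
    image = np.asarray(image, dtype=float)
    if image.min() == image.max():
        raise DegenerateImageError("constant image has no Otsu threshold")
    return float(filters.threshold_otsu(image, nbins=nbins))


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(gx**2 + gy**2), replicate padding."""
    return filters.sobel(np.asarray(image, dtype=float), mode="nearest")


def auto_edge_threshold(image: np.ndarray) -> float:
    """Data-driven edge threshold: a scaled mean of the gradient magnitude
    (factor 4), the classic toolbox auto-selection heuristic.

    Used as the fixed threshold of the feedforward edge method.
    """
    return min(1.0, 4.0 * float(np.mean(sobel_magnitude(image))))


def sobel_segment(image: np.ndarray, t_edge: float) -> np.ndarray:
    """Edge-based segmentation: threshold the Sobel gradient magnitude,
    dilate with a 3x3 square so contours close, fill enclosed holes so
    closed contours become solid BLOBs, then erode with the same 3x3 square
    to cancel the dilation bias at the outer boundary.

    The fill + compensating erosion are extensions over plain
    dilate-the-edges; without them small objects carry a systematic
    boundary ring that dominates their area.
    """
    if not 0.0 <= t_edge <= 1.0:
        raise ParameterError(f"t_edge must lie in [0, 1], got {t_edge}")
    return mask_from_magnitude(sobel_magnitude(image), t_edge)


def mask_from_magnitude(magnitude: np.ndarray, t_edge: float) -> np.ndarray:
    """Edge-mask post-processing shared by cached and uncached paths:
    threshold, 3x3 dilation, hole fill, compensating 3x3 erosion."""
    square = np.ones((3, 3), dtype=bool)
    edges = magnitude > t_edge
    dilated = ndimage.binary_dilation(edges, structure=square)
    filled = ndimage.binary_fill_holes(dilated)
    return ndimage.binary_erosion(filled, structure=square)


def opening(mask: np.ndarray, s: int) -> np.ndarray:
    """Morphological opening with a disk of diameter ``s`` (radius s // 2).

    Anti-extensive (result is a subset of the input); ``s == 1`` is the
    identity.
    """
    if s < 1 or s % 2 == 0:
        raise ParameterError(f"s must be odd and >= 1, got {s}")
    mask = np.asarray(mask, dtype=bool)
    if s == 1:
        return mask.copy()
    footprint = morphology.disk(s // 2)
    return morphology.dilation(morphology.erosion(mask, footprint), footprint)


def label_mask(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling; labels 1..n, background 0."""
    return measure.label(np.asarray(mask, dtype=bool), connectivity=2).astype(np.int32)


def run_pipeline(image: np.ndarray, p: ParameterVector, method: str) -> np.ndarray:
    """Run the full pipeline and return the labeled object mask.

    For ``method == "otsu"`` the ``t`` component of ``p`` is ignored and the
    data-driven Otsu threshold of the pre-processed image is used instead; a
    constant pre-processed image yields an empty labeling.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    smoothed = mean_filter(image, p.w)
    if method == "manual_threshold":
        mask = threshold_segment(smoothed, p.t)
    elif method == "otsu":
        try:
            mask = threshold_segment(smoothed, otsu_threshold(smoothed))
        except DegenerateImageError:
            mask = np.zeros(smoothed.shape, dtype=bool)
    else:
        mask = sobel_segment(smoothed, p.t)
    return label_mask(opening(mask, p.s))
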