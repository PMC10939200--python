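"""Basement-membrane fibril fraction on basal-surface images.

The BM at the follicle basal surface is a homogeneous matrix overlaid with
oriented fibrils.  The fibril fraction (FF) is the percentage of total BM
fluorescence in the analysis region that falls on fibrillar pixels.  The
fibril segmenter is a robust-threshold operator: after large-scale
flat-field removal, pixels brighter than the homogeneous level by more
than ``k`` noise-sigmas (MAD-estimated) are kept, cleaned morphologically,
and components shorter than a minimum skeleton length are dropped.  All
knobs (k, flat-field scale, minimum length) are exposed; FF values are
comparable within this operator's definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening, skeletonize

from .core_io import PlanarROI
from .geometry import rasterize_polygon


@dataclass
class FibrilResult:
    fibril_mask: np.ndarray
    ff_percent: float | None      # None when total fluorescence is 0
    homogeneous_level: float
    spread: float                 # sigma-scaled MAD
    params: dict = field(default_factory=dict)


def _region_mask(image: np.ndarray, region: PlanarROI, pixel_size: float
                 ) -> np.ndarray:
    mask = rasterize_polygon(region.vertices, image.shape, pixel_size)
    if not mask.any():
        raise ValueError("analysis region rasterizes to an empty mask")
    return mask


def _flatten(image: np.ndarray, pixel_size: float, flatfield_um: float,
             smooth_px: float) -> np.ndarray:
    """Remove large-scale shading (grey opening at a scale well above the
    fibril width) while preserving the absolute intensity level; then an
    optional light Gaussian smooth to tame pixel noise."""
    img = np.asarray(image, dtype=float)
    radius = max(int(round(flatfield_um / pixel_size)), 1)
    background = opening(img, disk(radius, decomposition="sequence"))
    flat = img - background + float(np.median(background))
    if smooth_px > 0:
        flat = ndimage.gaussian_filter(flat, smooth_px)
    return flat


def estimate_homogeneous_level(bm_image: np.ndarray, analysis_region: PlanarROI,
                               pixel_size: float, flatfield_um: float = 5.0,
                               smooth_px: float = 0.0
                               ) -> tuple[float, float]:
    """Median homogeneous-matrix level and robust spread within the region.

    The spread is a one-sided MAD scaled to the normal distribution: only
    deviations *below* the median enter, because fibrils only add signal,
    so the lower tail is noise-dominated even at high fibril coverage.
    Requires a region of more than 100 pixels.
    """
    region = _region_mask(bm_image, analysis_region, pixel_size)
    if region.sum() <= 100:
        raise ValueError("analysis region must exceed 100 pixels")
    flat = _flatten(bm_image, pixel_size, flatfield_um, smooth_px)
    return _robust_level(flat[region])


def _robust_level(values: np.ndarray) -> tuple[float, float]:
    """Median + one-sided MAD, refined once by excluding pixels more than
    two sigmas above the level (fibril flanks bias a plain median upward)."""
    level = float(np.median(values))
    spread = _lower_mad(values, level)
    if spread > 0:
        kept = values[values < level + 2.0 * spread]
        if kept.size > 100:
            level = float(np.median(kept))
            spread = _lower_mad(kept, level)
    return level, spread


def _lower_mad(values: np.ndarray, level: float) -> float:
    """Sigma-scaled MAD of the deviations below ``level``."""
    below = level - values[values < level]
    if below.size == 0:
        return 0.0
    return float(np.median(below)) / 0.67448975019608171


def segment_fibrils(bm_image: np.ndarray, analysis_region: PlanarROI,
                    pixel_size: float, k: float = 4.0,
                    min_length_um: float = 1.5, flatfield_um: float = 5.0,
                    smooth_px: float = 0.0) -> np.ndarray:
    """Fibril mask: flattened intensity above level + k·spread, closed with a
    1-pixel element, components with skeleton length < min_length removed."""
    region = _region_mask(bm_image, analysis_region, pixel_size)
    if region.sum() <= 100:
        raise ValueError("analysis region must exceed 100 pixels")
    flat = _flatten(bm_image, pixel_size, flatfield_um, smooth_px)
    level, spread = _robust_level(flat[region])
    raw = (flat > level + k * spread) & region
    if not raw.any():
        return raw
    cleaned = ndimage.binary_closing(raw, disk(1)) & region
    labels, n = ndimage.label(cleaned)
    if n == 0:
        return cleaned
    skel = skeletonize(cleaned)
    min_px = min_length_um / pixel_size
    skel_len = ndimage.sum_labels(skel, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(skel_len >= min_px) + 1
    return np.isin(labels, keep)


def fibril_fraction(bm_image: np.ndarray, analysis_region: PlanarROI,
                    mask: np.ndarray, pixel_size: float,
                    params: dict | None = None,
                    level_spread: tuple[float, float] | None = None
                    ) -> FibrilResult:
    """FF = 100 · Σ(raw intensity on mask) / Σ(raw intensity on region).

    Raw (unsubtracted) intensities on purpose: FF is defined relative to
    the *total* BM fluorescence of the region.
    """
    img = np.asarray(bm_image, dtype=float)
    region = _region_mask(img, analysis_region, pixel_size)
    mask = np.asarray(mask, dtype=bool)
    if np.any(mask & ~region):
        raise ValueError("fibril mask extends outside the analysis region")
    if level_spread is None:
        level_spread = estimate_homogeneous_level(img, analysis_region,
                                                  pixel_size)
    level, spread = level_spread
    total = float(img[region].sum())
    if total <= 0:
        ff = None
    elif not mask.any():
        ff = 0.0
    else:
        ff = 100.0 * float(img[mask].sum()) / total
    return FibrilResult(fibril_mask=mask, ff_percent=ff,
                        homogeneous_level=level, spread=spread,
                        params=params or {})


def measure_fibril_fraction(bm_image: np.ndarray, analysis_region: PlanarROI,
                            pixel_size: float, k: float = 4.0,
                            min_length_um: float = 1.5,
                            flatfield_um: float = 5.0,
                            smooth_px: float = 0.0) -> FibrilResult:
    """Segment fibrils and report FF in one call."""
    level, spread = estimate_homogeneous_level(
        bm_image, analysis_region, pixel_size, flatfield_um, smooth_px)
    mask = segment_fibrils(bm_image, analysis_region, pixel_size, k,
                           min_length_um, flatfield_um, smooth_px)
    return fibril_fraction(
        bm_image, analysis_region, mask, pixel_size,
        level_spread=(level, spread),
        params={"k": k, "min_length_um": min_length_um,
                "flatfield_um": flatfield_um, "smooth_px": smooth_px})
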