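"""Sagittal-section and suprabasal-projection polarity measurements.

Three measurements drawn on hand (or generator-emitted) ROIs:

* apical fraction — mean gray value of a thick line along the apical wall
  relative to apical + basal, per ROI pair on a sagittal section;
* basal intensity — mean gray value per µm² in a basal-wall ROI;
* trailing/front edge ratio — background-subtracted mean gray values of
  thick lines on the trailing edge and a front-lateral side of a cell,
  measured on a short mean projection just above the basal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ImageStack, PlanarROI
from .geometry import rasterize_polygon, rasterize_polyline_band


@dataclass
class RoiPair:
    apical: PlanarROI
    basal: PlanarROI
    follicle_id: str = ""
    region_id: str = ""

    def __post_init__(self):
        for roi in (self.apical, self.basal):
            if roi.kind != "polyline":
                raise ValueError("RoiPair expects polyline ROIs")
        if abs(self.apical.line_width - self.basal.line_width) > 1e-9:
            raise ValueError("apical and basal lines must share one width")


@dataclass
class EdgeMeasurement:
    cell_id: str
    trailing_mean: float
    front_mean: float
    background_mean: float
    ratio: float | None             # None when front <= background
    flags: list[str] = field(default_factory=list)


def _roi_pixels(image: np.ndarray, roi: PlanarROI, pixel_size: float
                ) -> np.ndarray:
    if roi.kind == "polyline":
        mask = rasterize_polyline_band(roi.vertices, roi.line_width,
                                       image.shape, pixel_size)
    else:
        mask = rasterize_polygon(roi.vertices, image.shape, pixel_size)
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r} rasterizes to an empty mask")
    return mask


def mean_gray(image: np.ndarray, roi: PlanarROI, pixel_size: float) -> float:
    """Mean gray value over the rasterized ROI (thick-line band for
    polylines, interior for polygons)."""
    mask = _roi_pixels(np.asarray(image, float), roi, pixel_size)
    return float(np.asarray(image, float)[mask].mean())


def apical_fraction(section: np.ndarray, pairs: list[RoiPair],
                    pixel_size: float,
                    background: PlanarROI | None = None
                    ) -> tuple[list[float | None], float | None]:
    """Per-pair apical fraction (%) and the follicle mean over pairs.

    fraction = 100·Ā/(Ā+B̄) with Ā, B̄ the mean gray values of the apical
    and basal thick lines.  No background subtraction by default; pass a
    background ROI to subtract its mean from both lines first.
    """
    if not pairs:
        raise ValueError("need at least one ROI pair")
    bg = mean_gray(section, background, pixel_size) if background is not None else 0.0
    fractions: list[float | None] = []
    for pair in pairs:
        a = mean_gray(section, pair.apical, pixel_size) - bg
        b = mean_gray(section, pair.basal, pixel_size) - bg
        fractions.append(100.0 * a / (a + b) if a + b > 0 else None)
    defined = [f for f in fractions if f is not None]
    return fractions, (float(np.mean(defined)) if defined else None)


def basal_intensity(section: np.ndarray, basal_roi: PlanarROI,
                    pixel_size: float) -> float:
    """Summed intensity per µm² over the rasterized basal-wall ROI."""
    mask = _roi_pixels(np.asarray(section, float), basal_roi, pixel_size)
    area_um2 = int(mask.sum()) * pixel_size ** 2
    return float(np.asarray(section, float)[mask].sum()) / area_um2


def project_suprabasal(stack: ImageStack, channel: str = "signal",
                       start_um: float = 0.15, span_um: float = 0.45,
                       direction: int = +1) -> np.ndarray:
    """Mean projection of the planes covering [start, start+span) from the
    basal surface toward the cell interior (direction=+1) or outward (-1).

    With the default 0.15 µm z-step and 0.15/0.45 µm window this is planes
    basal+1 .. basal+3.
    """
    zs = stack.voxel_size_z
    first = int(round(start_um / zs))
    count = int(round(span_um / zs))
    if count < 1:
        raise ValueError("projection span shorter than one z-step")
    planes = [stack.z_origin + direction * (first + i) for i in range(count)]
    if min(planes) < 0 or max(planes) >= stack.n_planes:
        raise ValueError(
            f"projection needs planes {planes}, stack has {stack.n_planes}")
    return np.asarray(stack.channel(channel), float)[planes].mean(axis=0)


def edge_ratio(projection: np.ndarray, trailing: PlanarROI, front: PlanarROI,
               background: PlanarROI, pixel_size: float,
               cell_id: str = "cell") -> EdgeMeasurement:
    """Trailing/front ratio of background-subtracted mean gray values."""
    widths = {trailing.line_width, front.line_width, background.line_width}
    if max(widths) - min(widths) > 1e-9:
        raise ValueError("all three polylines must share one line width")
    t = mean_gray(projection, trailing, pixel_size)
    f = mean_gray(projection, front, pixel_size)
    b = mean_gray(projection, background, pixel_size)
    flags: list[str] = []
    if f - b <= 0:
        flags.append("nonpositive_front_signal")
        ratio = None
    else:
        ratio = (t - b) / (f - b)
    return EdgeMeasurement(cell_id=cell_id, trailing_mean=t, front_mean=f,
                           background_mean=b, ratio=ratio, flags=flags)
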