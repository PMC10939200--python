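"""Basal-plane detection and cortex segmentation from the F-actin channel.

The pipeline is manual-first: outlines drawn by hand (ROI files) are
first-class inputs, and the automated tracer below exists mainly so that
synthetic ground-truth data can be processed end to end without human
clicks.  The tracer is deterministic: per-plane ridge enhancement followed
by a shortest-path closed contour in polar parametrization around a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sato

from .core_io import CellOutline, ImageStack, PlanarROI
from .geometry import rotate_points


class DegenerateInputError(ValueError):
    pass


class SeedError(ValueError):
    pass


class SegmentationError(RuntimeError):
    pass


@dataclass
class BasalPlaneReport:
    z_index: int
    score_profile: np.ndarray


def detect_basal_plane(actin: np.ndarray, voxel_size_xy: float,
                       fiber_width_um: tuple[float, float] = (0.3, 0.5)
                       ) -> BasalPlaneReport:
    """Find the plane with the strongest stress-fibre (elongated ridge) signal.

    Score per plane = summed tubeness (Sato) response at the stress-fibre
    scale.  The response is built from image second derivatives, so the
    choice is invariant to a global intensity offset and to positive
    rescaling; ties break toward smaller z.
    """
    actin = np.asarray(actin, dtype=float)
    if actin.ndim != 3 or actin.shape[0] < 3:
        raise DegenerateInputError("need a (Z, Y, X) channel with >= 3 planes")
    if not np.any(actin > actin.min()):
        raise DegenerateInputError("actin channel is constant (no signal)")
    sigmas = [w / 2.355 / voxel_size_xy for w in fiber_width_um]
    scores = np.array([
        float(sato(plane, sigmas=sigmas, black_ridges=False).sum())
        for plane in actin])
    return BasalPlaneReport(z_index=int(np.argmax(scores)), score_profile=scores)


def _polar_trace(plane: np.ndarray, seed_px: np.ndarray, r_max_px: float,
                 n_theta: int) -> np.ndarray | None:
    """Closed ridge contour around ``seed_px`` as per-angle radii (pixels).

    Dynamic programme over a polar resampling of the plane: states are radii,
    steps move by at most one radial bin per angular column.  The column axis
    is tiled three times and the middle copy kept, which approximates the
    cyclic optimum while staying deterministic.
    """
    n_r = int(r_max_px)
    if n_r < 4:
        return None
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    radii = np.arange(1, n_r + 1, dtype=float)
    xs = seed_px[0] + radii[:, None] * np.cos(thetas)[None, :]
    ys = seed_px[1] + radii[:, None] * np.sin(thetas)[None, :]
    polar = ndimage.map_coordinates(plane, [ys, xs], order=1, mode="nearest")
    span = polar.max() - polar.min()
    if span <= 0:
        return None
    cost = 1.0 - (polar - polar.min()) / span          # ridges are cheap
    tiled = np.concatenate([cost, cost, cost], axis=1)
    n_cols = tiled.shape[1]
    acc = tiled.copy()
    back = np.zeros_like(tiled, dtype=np.int32)
    for j in range(1, n_cols):
        prev = acc[:, j - 1]
        stacked = np.stack([np.roll(prev, 1), prev, np.roll(prev, -1)])
        stacked[0, 0] = np.inf       # no wrap across the radial axis
        stacked[2, -1] = np.inf
        choice = np.argmin(stacked, axis=0)
        acc[:, j] += stacked[choice, np.arange(len(prev))]
        back[:, j] = choice - 1
    r_idx = np.zeros(n_cols, dtype=np.int32)
    r_idx[-1] = int(np.argmin(acc[:, -1]))
    for j in range(n_cols - 1, 0, -1):
        r_idx[j - 1] = r_idx[j] + back[r_idx[j], j]
    middle = r_idx[n_theta:2 * n_theta]
    if abs(int(r_idx[n_theta]) - int(r_idx[2 * n_theta - 1])) > 2:
        return None                   # contour failed to close
    return radii[middle]


def segment_cortex(stack: ImageStack, seed_xy_um: tuple[float, float],
                   z_range: range | list[int], channel: str = "actin",
                   n_theta: int = 120, r_max_um: float = 8.0,
                   smooth_um: float = 0.12, cell_id: str = "cell",
                   migration_angle: float = 0.0) -> CellOutline:
    """Trace the cortical F-actin ridge enclosing ``seed_xy_um`` per plane.

    Raises SeedError when the seed sits on background (local intensity below
    the plane median) and SegmentationError when a plane's ridge cannot be
    closed or its area falls outside [10%, 300%] of the median across planes.
    """
    actin = stack.channel(channel)
    px = stack.voxel_size_xy
    planes = list(z_range)
    if not planes or min(planes) < 0 or max(planes) >= stack.n_planes:
        raise ValueError(f"z_range {planes} outside stack of {stack.n_planes} planes")
    seed_px = np.asarray(seed_xy_um, dtype=float) / px
    sigma = smooth_um / px

    # validate the seed on the first (basal) plane, where the cell interior
    # carries stress-fibre signal; interior planes are legitimately hollow
    first = ndimage.gaussian_filter(np.asarray(actin[planes[0]], float),
                                    0.5 / px)
    iy, ix = int(round(seed_px[1])), int(round(seed_px[0]))
    if not (0 <= iy < first.shape[0] and 0 <= ix < first.shape[1]):
        raise SeedError(f"seed {seed_xy_um} outside the image")
    med = float(np.median(first))
    mad = float(np.median(np.abs(first - med)))
    if first[iy, ix] <= med + 0.5 * mad:
        raise SeedError(f"seed {seed_xy_um} lies on background "
                        f"in plane {planes[0]}")

    polygons: dict[int, PlanarROI] = {}
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    for z in planes:
        plane = ndimage.gaussian_filter(np.asarray(actin[z], dtype=float), sigma)
        r = _polar_trace(plane, seed_px, r_max_um / px, n_theta)
        if r is None:
            raise SegmentationError(f"cannot close cortex ridge in plane {z}")
        verts = np.column_stack([seed_px[0] + r * np.cos(thetas),
                                 seed_px[1] + r * np.sin(thetas)]) * px
        polygons[z] = PlanarROI("polygon", verts, plane=z,
                                name=f"{cell_id}-z{z}")

    areas = np.array([polygons[z].area for z in planes])
    med = float(np.median(areas))
    bad = [z for z, a in zip(planes, areas) if not 0.1 * med <= a <= 3.0 * med]
    if bad:
        raise SegmentationError(
            f"implausible cortex area in planes {bad} (median {med:.2f} um^2)")
    return CellOutline(cell_id=cell_id, polygons=polygons,
                       migration_angle=migration_angle)


def orientation_rotation(migration_angle: float) -> float:
    """CCW rotation (degrees) mapping the trailing direction to +90°."""
    return -90.0 - migration_angle


def orient_to_migration(outline: CellOutline,
                        migration_angle: float | None = None) -> CellOutline:
    """Rotate an outline about its basal-plane centroid so the trailing edge
    (opposite of migration) points to +90°; the result's migration angle is
    -90° by construction."""
    m = outline.migration_angle if migration_angle is None else migration_angle
    if not np.isfinite(m):
        raise ValueError("migration angle must be finite")
    delta = orientation_rotation(m)
    origin = outline.basal_polygon.centroid
    polygons = {
        z: PlanarROI("polygon", rotate_points(roi.vertices, delta, origin),
                     plane=z, name=roi.name)
        for z, roi in outline.polygons.items()}
    return CellOutline(cell_id=outline.cell_id, polygons=polygons,
                       migration_angle=-90.0)
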