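"""Single-cell basement-membrane secretion quantification.

Lateral secretion is integrated in a *hollow cylinder*: a band of stated
thickness (default 1.5 µm) straddling the segmented cortex on each lateral
plane.  Basal secretion is integrated in a *full cylinder*: the basal
outline eroded inward (default 0.75 µm, so it clears the hollow band) and
projected on the slices beyond the basal surface.  Background is removed as
the mean intensity of a user-drawn background region restricted to the same
planes as each signal mask.  The lateral fraction is the percentage of
background-subtracted signal in the hollow cylinder relative to the total
over both cylinders.

The planar-polarization vector of the lateral signal is the displacement
from the hollow cylinder's isobarycenter (unweighted centroid of its voxel
centres) to its intensity-weighted centre of mass, reported in µm in the
oriented frame where the cell's trailing edge points to +90°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import CellOutline, ImageStack, PlanarROI
from .geometry import (erode_polygon, rasterize_boundary_band,
                       rasterize_polygon)
from .segmentation import orientation_rotation


class MaskError(ValueError):
    pass


class EmptyMaskError(MaskError):
    pass


@dataclass
class VoxelMask:
    """Boolean voxel grid aligned to a parent ImageStack."""

    mask: np.ndarray                # (Z, Y, X) bool
    label: str                      # "lateral" | "basal" | "background"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise MaskError("mask must be (Z, Y, X)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def planes(self) -> list[int]:
        return [int(z) for z in np.flatnonzero(self.mask.any(axis=(1, 2)))]


@dataclass
class SecretionResult:
    cell_id: str
    lateral_intensity: float
    basal_intensity: float
    lateral_fraction: float | None   # %, None when L + B == 0
    background_per_voxel_lateral: float
    background_per_voxel_basal: float
    flags: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class PolarizationVector:
    dx: float                        # µm, oriented frame
    dy: float
    total_weight: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    @property
    def angle(self) -> float | None:
        """Degrees CCW from +x; None for zero weight or zero magnitude."""
        if self.total_weight <= 0 or self.magnitude == 0:
            return None
        return float(np.rad2deg(np.arctan2(self.dy, self.dx)) % 360.0)


@dataclass
class CircularStats:
    n: int
    n_excluded: int
    circular_mean: float | None      # degrees in [0, 360)
    resultant_length: float          # R in [0, 1]
    angles: np.ndarray


# ---------------------------------------------------------------------------
# mask construction


def build_hollow_cylinder(outline: CellOutline, stack: ImageStack,
                          thickness_um: float = 1.5) -> VoxelMask:
    """Band of ``thickness_um`` straddling the cortex polygon (half inside,
    half outside) on every plane of the outline."""
    if thickness_um <= 0:
        raise MaskError("thickness must be > 0")
    px = stack.voxel_size_xy
    half = thickness_um / 2.0
    if thickness_um < px:
        warnings.warn(
            f"hollow-cylinder thickness {thickness_um} um is below one pixel "
            f"({px} um); enforcing a minimum one-pixel band", stacklevel=2)
        half = px * np.sqrt(2.0) / 2.0   # guarantees a closed pixel ring
    mask = np.zeros(stack.shape_zyx, dtype=bool)
    for z in outline.planes:
        if not 0 <= z < stack.n_planes:
            raise MaskError(f"outline plane {z} outside the stack")
        mask[z] = rasterize_boundary_band(outline.polygons[z].vertices,
                                          stack.shape_zyx[1:], px, half)
    return VoxelMask(mask, "lateral",
                     params={"thickness_um": thickness_um,
                             "planes": outline.planes})


def build_basal_cylinder(basal_polygon: PlanarROI, stack: ImageStack,
                         shrink_um: float = 0.75, n_planes: int = 3,
                         basal_plane: int | None = None,
                         cell_id: str = "cell") -> VoxelMask:
    """Full cylinder: the basal outline eroded inward by ``shrink_um`` and
    replicated on the ``n_planes`` slices beyond (outside) the basal surface
    (z = basal-1 ... basal-n)."""
    if shrink_um < 0 or n_planes < 1:
        raise MaskError("shrink must be >= 0 and n_planes >= 1")
    b = stack.z_origin if basal_plane is None else basal_plane
    planes = [b - k for k in range(1, n_planes + 1)]
    if min(planes) < 0:
        raise MaskError(
            f"stack has only {b} slices beyond the basal surface; "
            f"{n_planes} requested")
    eroded = erode_polygon(basal_polygon.vertices, shrink_um)
    if eroded is None:
        raise EmptyMaskError(
            f"cell {cell_id}: eroding the basal outline by {shrink_um} um "
            "annihilates the polygon")
    disk = rasterize_polygon(eroded, stack.shape_zyx[1:], stack.voxel_size_xy)
    if not disk.any():
        raise EmptyMaskError(f"cell {cell_id}: eroded basal outline rasterizes "
                             "to an empty mask")
    mask = np.zeros(stack.shape_zyx, dtype=bool)
    for z in planes:
        mask[z] = disk
    return VoxelMask(mask, "basal",
                     params={"shrink_um": shrink_um, "n_planes": n_planes,
                             "planes": planes})


def build_background_mask(background_roi: PlanarROI, stack: ImageStack,
                          planes: list[int] | None = None) -> VoxelMask:
    """Project a background polygon onto the given planes (default: all)."""
    disk = rasterize_polygon(background_roi.vertices, stack.shape_zyx[1:],
                             stack.voxel_size_xy)
    mask = np.zeros(stack.shape_zyx, dtype=bool)
    for z in (range(stack.n_planes) if planes is None else planes):
        mask[z] = disk
    return VoxelMask(mask, "background", params={"planes": planes})


def assert_disjoint(lateral: VoxelMask, basal: VoxelMask) -> None:
    if np.any(lateral.mask & basal.mask):
        raise MaskError("lateral and basal masks intersect")


# ---------------------------------------------------------------------------
# measurements


def _restricted_background_mean(secreted: np.ndarray, background: VoxelMask,
                                planes: list[int]) -> float:
    sub = background.mask.copy()
    keep = np.zeros(sub.shape[0], dtype=bool)
    keep[planes] = True
    sub[~keep] = False
    n = int(sub.sum())
    if n == 0:
        raise MaskError(f"background mask empty on planes {planes}")
    return float(secreted[sub].sum()) / n


def measure_secretion(secreted: np.ndarray, lateral: VoxelMask,
                      basal: VoxelMask, background: VoxelMask,
                      cell_id: str = "cell") -> SecretionResult:
    """Background-subtracted cylinder intensities and the lateral fraction.

    The background mean is computed separately on the lateral and basal
    plane sets; negative post-subtraction sums clamp to 0 with a QC flag.
    """
    secreted = np.asarray(secreted, dtype=float)
    for m in (lateral, basal, background):
        if m.mask.shape != secreted.shape:
            raise MaskError(f"{m.label} mask shape {m.mask.shape} does not "
                            f"match stack {secreted.shape}")
    assert_disjoint(lateral, basal)
    if np.any(background.mask & (lateral.mask | basal.mask)):
        raise MaskError("background mask overlaps a signal mask")

    flags: list[str] = []
    b_lat = _restricted_background_mean(secreted, background, lateral.planes)
    b_bas = _restricted_background_mean(secreted, background, basal.planes)
    L = float(secreted[lateral.mask].sum()) - lateral.n_voxels * b_lat
    B = float(secreted[basal.mask].sum()) - basal.n_voxels * b_bas
    if L < 0:
        flags.append("lateral_clamped_negative")
        L = 0.0
    if B < 0:
        flags.append("basal_clamped_negative")
        B = 0.0
    if L + B > 0:
        fraction = 100.0 * L / (L + B)
    else:
        fraction = None
        flags.append("undefined_fraction")
    return SecretionResult(
        cell_id=cell_id, lateral_intensity=L, basal_intensity=B,
        lateral_fraction=fraction,
        background_per_voxel_lateral=b_lat, background_per_voxel_basal=b_bas,
        flags=flags,
        params={**lateral.params, **{f"basal_{k}": v
                                     for k, v in basal.params.items()}})


def polarization_vector(secreted: np.ndarray, lateral: VoxelMask,
                        voxel_size_xy: float,
                        background_per_voxel: float = 0.0,
                        migration_angle: float | None = None
                        ) -> PolarizationVector:
    """Vector from the hollow cylinder's isobarycenter to its
    intensity-weighted centre of mass (xy only, µm).

    Weights are background-subtracted intensities clamped at zero.  When
    ``migration_angle`` is given the vector is rotated into the oriented
    frame (trailing edge at +90°).
    """
    secreted = np.asarray(secreted, dtype=float)
    if lateral.n_voxels == 0:
        raise EmptyMaskError("lateral mask is empty")
    zz, yy, xx = np.nonzero(lateral.mask)
    x_um = xx * voxel_size_xy
    y_um = yy * voxel_size_xy
    iso = np.array([x_um.mean(), y_um.mean()])
    w = np.clip(secreted[zz, yy, xx] - background_per_voxel, 0.0, None)
    total = float(w.sum())
    if total <= 0:
        return PolarizationVector(0.0, 0.0, 0.0)
    com = np.array([float((w * x_um).sum()) / total,
                    float((w * y_um).sum()) / total])
    dx, dy = com - iso
    if migration_angle is not None:
        t = np.deg2rad(orientation_rotation(migration_angle))
        dx, dy = (dx * np.cos(t) - dy * np.sin(t),
                  dx * np.sin(t) + dy * np.cos(t))
    return PolarizationVector(float(dx), float(dy), total)


def circular_summary(vectors_or_angles) -> CircularStats:
    """Circular mean and resultant length of polarization angles.

    Accepts PolarizationVector objects or plain angles in degrees; vectors
    with undefined angle are excluded (counted).  mean = atan2(Σsin, Σcos),
    R = |Σ e^{iθ}| / n; the mean is None when R < 1e-12.
    """
    angles = []
    excluded = 0
    for v in vectors_or_angles:
        a = v.angle if isinstance(v, PolarizationVector) else float(v)
        if a is None:
            excluded += 1
        else:
            angles.append(float(a))
    if not angles:
        raise ValueError("no vectors with a defined angle")
    t = np.deg2rad(np.asarray(angles))
    s, c = np.sin(t).sum(), np.cos(t).sum()
    r = float(np.hypot(s, c)) / len(angles)
    mean = float(np.rad2deg(np.arctan2(s, c)) % 360.0) if r >= 1e-12 else None
    return CircularStats(n=len(angles), n_excluded=excluded,
                         circular_mean=mean, resultant_length=r,
                         angles=np.asarray(angles))


def suprabasal_band_height(secreted: np.ndarray, lateral: VoxelMask,
                           voxel_size_z: float, fraction: float = 0.8,
                           background_per_voxel: float = 0.0) -> float:
    """Height (µm) of the smallest contiguous z-band holding at least
    ``fraction`` of the background-subtracted lateral signal."""
    secreted = np.asarray(secreted, dtype=float)
    sums = []
    for z in lateral.planes:
        m = lateral.mask[z]
        sums.append(float(np.clip(secreted[z][m] - background_per_voxel,
                                  0.0, None).sum()))
    sums = np.asarray(sums)
    total = sums.sum()
    if total <= 0:
        raise ValueError("no lateral signal above background")
    target = fraction * total
    best = len(sums)
    for width in range(1, len(sums) + 1):
        window = np.convolve(sums, np.ones(width), mode="valid")
        if window.max() >= target - 1e-9 * total:
            best = width
            break
    return best * voxel_size_z
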