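"""Calibrated image / ROI data model and file I/O.

Conventions (package-wide):

* voxel arrays are indexed ``(z, y, x)`` with channels on a separate leading
  axis; ``z`` increases from the basal surface toward the cell interior once
  the stack is basally aligned (``z_origin`` marks the basal plane);
* pixel coordinates are 0-based with pixel centres at integer coordinates;
  physical position (µm) = pixel index × voxel size;
* ROI vertices are stored in µm.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .geometry import ensure_ccw, polygon_area, polygon_centroid


class ConfigurationError(ValueError):
    pass


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class ImageStack:
    """Multi-channel 3-D fluorescence stack with physical calibration.

    voxels: float array of shape (C, Z, Y, X), arbitrary fluorescence units.
    z_origin: index of the basal plane after alignment (z increases toward
    the cell interior).
    """

    voxels: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float
    channel_names: tuple[str, ...]
    z_origin: int = 0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValidationError("voxels must have shape (C, Z, Y, X)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels")
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise ValidationError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValidationError("intensities must be finite and >= 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.voxels[self.channel_names.index(name)]
        except ValueError:
            raise ConfigurationError(
                f"no channel {name!r}; have {self.channel_names}") from None

    def plane_height_um(self, z_index: int) -> float:
        """Physical height of a plane above the basal surface (µm)."""
        return (z_index - self.z_origin) * self.voxel_size_z


def read_stack(path, voxel_size_xy: float, voxel_size_z: float,
               channel_names=("channel0",), layout: str = "czyx",
               z_origin: int = 0) -> ImageStack:
    """Read a TIFF stack, split channels, attach calibration.

    layout: axis order of the stored array once squeezed — "czyx", "zcyx"
    or "zyx" (single channel).  Intensities are preserved bit-exactly.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if layout == "zyx" or arr.ndim == 3:
        arr = arr[None]
    elif layout == "zcyx":
        arr = np.moveaxis(arr, 1, 0)
    elif layout != "czyx":
        raise ConfigurationError(f"unknown layout {layout!r}")
    if arr.shape[0] != len(channel_names):
        raise ConfigurationError(
            f"stack has {arr.shape[0]} channels, expected "
            f"{len(channel_names)} ({channel_names})")
    return ImageStack(arr.astype(np.float64), voxel_size_xy, voxel_size_z,
                      tuple(channel_names), z_origin)


def write_stack(stack: ImageStack, path) -> None:
    """Write (C, Z, Y, X) voxels as a multi-page TIFF (czyx layout)."""
    tifffile.imwrite(str(path), stack.voxels.astype(np.float32))


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class PlanarROI:
    """A polygon or thick polyline in a single plane, in µm coordinates."""

    kind: str                       # "polygon" | "polyline"
    vertices: np.ndarray            # (N, 2) µm
    line_width: float | None = None  # µm, polylines only
    plane: int | str = "projection"
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.kind == "polygon":
            if len(self.vertices) < 3:
                raise ValidationError(f"polygon {self.name!r}: < 3 vertices")
            poly = Polygon(self.vertices)
            if not poly.is_valid:
                raise ValidationError(
                    f"polygon ROI {self.name!r} is invalid (self-intersecting?)")
            if poly.area <= 0:
                raise ValidationError(f"polygon {self.name!r}: zero area")
            self.vertices = ensure_ccw(self.vertices)
        elif self.kind == "polyline":
            if len(self.vertices) < 2:
                raise ValidationError(f"polyline {self.name!r}: < 2 vertices")
            if self.line_width is None or self.line_width <= 0:
                raise ValidationError(
                    f"polyline {self.name!r}: line_width must be > 0")
        else:
            raise ValidationError(f"unknown ROI kind {self.kind!r}")

    @property
    def area(self) -> float:
        if self.kind != "polygon":
            raise ValidationError("area defined for polygons only")
        return abs(polygon_area(self.vertices))

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.vertices)

    def scaled(self, factor: float) -> "PlanarROI":
        out = replace(self, vertices=self.vertices * factor)
        if out.line_width is not None:
            out.line_width = self.line_width * factor
        return out


@dataclass
class CellOutline:
    """Per-plane cortex polygons for one cell over a contiguous z range."""

    cell_id: str
    polygons: dict[int, PlanarROI] = field(default_factory=dict)
    migration_angle: float = 0.0    # degrees, direction of cell movement

    def __post_init__(self):
        planes = self.planes
        if planes:
            if list(planes) != list(range(planes[0], planes[-1] + 1)):
                raise ValidationError(
                    f"cell {self.cell_id}: plane indices not contiguous: {planes}")
            diam = 2.0 * np.sqrt(max(p.area for p in self.polygons.values()) / np.pi)
            cents = [self.polygons[z].centroid for z in planes]
            for c0, c1 in zip(cents, cents[1:]):
                if np.linalg.norm(c1 - c0) >= diam:
                    raise ValidationError(
                        f"cell {self.cell_id}: centroid drift exceeds cell diameter")

    @property
    def planes(self) -> list[int]:
        return sorted(self.polygons)

    @property
    def basal_polygon(self) -> PlanarROI:
        return self.polygons[self.planes[0]]


# ---------------------------------------------------------------------------
# ROI file I/O — native JSON dialect

ROI_SCHEMA_VERSION = 1


def write_roi_set(rois: list[PlanarROI], path) -> None:
    """Write ROIs to the native JSON dialect (µm coordinates)."""
    payload = {"schema": "bmsecq-roi", "version": ROI_SCHEMA_VERSION, "rois": []}
    for roi in rois:
        rec = {"name": roi.name, "kind": roi.kind, "plane": roi.plane,
               "coords": "um", "vertices": np.asarray(roi.vertices).tolist()}
        if roi.line_width is not None:
            rec["line_width"] = roi.line_width
        payload["rois"].append(rec)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_set(path, dialect: str = "json",
                 pixel_size_um: float = 1.0) -> list[PlanarROI]:
    """Read ROIs from the native JSON dialect or ImageJ .roi/.zip files.

    Pixel-coordinate dialects are converted to µm via ``pixel_size_um``;
    polygons are returned counter-clockwise.
    """
    path = Path(path)
    if dialect == "json":
        return _read_roi_json(path, pixel_size_um)
    if dialect == "imagej-roi":
        if path.suffix.lower() == ".zip":
            rois = []
            with zipfile.ZipFile(path) as zf:
                for info in sorted(zf.namelist()):
                    if info.lower().endswith(".roi"):
                        rois.append(_decode_imagej_roi(
                            zf.read(info), pixel_size_um, Path(info).stem))
            return rois
        return [_decode_imagej_roi(path.read_bytes(), pixel_size_um, path.stem)]
    raise ConfigurationError(f"unknown ROI dialect {dialect!r}")


def _read_roi_json(path: Path, pixel_size_um: float) -> list[PlanarROI]:
    payload = json.loads(path.read_text())
    rois = []
    for rec in payload.get("rois", []):
        verts = np.asarray(rec["vertices"], dtype=float)
        width = rec.get("line_width")
        if rec.get("coords", "um") == "pixel":
            verts = verts * pixel_size_um
            if width is not None:
                width = width * pixel_size_um
        rois.append(PlanarROI(kind=rec.get("kind", "polygon"), vertices=verts,
                              line_width=width, plane=rec.get("plane", "projection"),
                              name=rec.get("name", "")))
    return rois


# ImageJ .roi binary layout (big-endian), per the public RoiDecoder format:
# 0-3 "Iout", 4-5 version, 6 type, 8-15 top/left/bottom/right (shorts),
# 16-17 nCoordinates, 34-35 strokeWidth (short), 64.. x coords relative to
# left (shorts) then y coords relative to top (shorts).
_IJ_POLYGON_TYPES = {0: "polygon", 7: "polygon", 8: "polygon"}
_IJ_POLYLINE_TYPES = {4: "polyline", 5: "polyline"}
_IJ_LINE = 3


def _decode_imagej_roi(data: bytes, pixel_size_um: float, name: str) -> PlanarROI:
    if data[:4] != b"Iout":
        raise IOError(f"{name}: not an ImageJ ROI file")
    roi_type = data[6]
    top, left = struct.unpack(">hh", data[8:12])
    n = struct.unpack(">h", data[16:18])[0]
    stroke_px = struct.unpack(">h", data[34:36])[0]
    if roi_type == _IJ_LINE:
        # straight line: float endpoints at offsets 18-33, no coord arrays
        x1, y1, x2, y2 = struct.unpack(">ffff", data[18:34])
        verts = np.array([[x1, y1], [x2, y2]]) * pixel_size_um
        return PlanarROI("polyline", verts,
                         line_width=max(stroke_px, 1) * pixel_size_um,
                         plane="projection", name=name)
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    verts = np.column_stack([xs, ys]) * pixel_size_um
    if roi_type in _IJ_POLYGON_TYPES:
        return PlanarROI("polygon", verts, plane="projection", name=name)
    if roi_type in _IJ_POLYLINE_TYPES:
        width = max(stroke_px, 1) * pixel_size_um
        return PlanarROI("polyline", verts, line_width=width,
                         plane="projection", name=name)
    raise IOError(f"{name}: unsupported ImageJ ROI type {roi_type}")


# ---------------------------------------------------------------------------
# result tables


class ResultTable:
    """Long-format measurement table; every row carries the parameters
    needed to recompute it."""

    COLUMNS = ["item_id", "metric", "value", "units", "params"]

    def __init__(self, rows: list[dict] | None = None):
        self._rows: list[dict] = list(rows) if rows else []

    def add(self, item_id: str, metric: str, value, units: str = "",
            **params) -> None:
        self._rows.append({"item_id": item_id, "metric": metric,
                           "value": value, "units": units,
                           "params": json.dumps(params, sort_keys=True)})

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)


def write_results(table: ResultTable, path) -> None:
    if len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    table.to_frame().to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False,
                       na_values=[""], dtype={"params": str})
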