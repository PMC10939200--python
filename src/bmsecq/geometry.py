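"""Planar geometry on calibrated pixel grids.

All functions work in physical micrometres.  The pixel grid convention is
fixed package-wide: pixel centres sit at integer multiples of the pixel
size, ``x = column * pixel_size`` and ``y = row * pixel_size``; angles are
measured in degrees, counter-clockwise from +x toward +y.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area (positive for counter-clockwise vertex order)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        return v.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return np.array([cx, cy])


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return vertices in counter-clockwise order (reversed if clockwise)."""
    v = np.asarray(vertices, dtype=float)
    return v if polygon_area(v) >= 0 else v[::-1].copy()


def rotate_points(points: np.ndarray, angle_deg: float,
                  origin=(0.0, 0.0)) -> np.ndarray:
    """Rotate ``points`` (N, 2) by ``angle_deg`` CCW about ``origin``."""
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    p = np.asarray(points, dtype=float) - np.asarray(origin, dtype=float)
    return p @ rot.T + np.asarray(origin, dtype=float)


def pixel_centers(shape_yx: tuple[int, int], pixel_size: float):
    """x and y coordinate grids (µm) for an image of shape (rows, cols)."""
    ny, nx = shape_yx
    ys = np.arange(ny, dtype=float) * pixel_size
    xs = np.arange(nx, dtype=float) * pixel_size
    return np.meshgrid(xs, ys)


def distance_to_segments(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Minimum distance from each point to the closed polygon boundary.

    points: (N, 2); vertices: (M, 2), implicitly closed.  Pure numpy so it
    serves both mask construction and the synthetic generator without a
    per-point geometry-library round trip.
    """
    p = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    a = v                       # segment starts (M, 2)
    b = np.roll(v, -1, axis=0)  # segment ends
    ab = b - a                  # (M, 2)
    ab2 = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
    # squared-distance algebra on (N, M) arrays only:
    # |pa - t*ab|^2 = |pa|^2 - t * (2*dot - t*|ab|^2), t clamped to [0, 1]
    dot = p @ ab.T - np.sum(a * ab, axis=1)[None, :]
    pa2 = (np.sum(p * p, axis=1)[:, None] - 2.0 * (p @ a.T)
           + np.sum(a * a, axis=1)[None, :])
    t = np.clip(dot / ab2[None, :], 0.0, 1.0)
    d2 = pa2 - t * (2.0 * dot - t * ab2[None, :])
    return np.sqrt(np.maximum(d2.min(axis=1), 0.0))


def _bbox_slice(vertices: np.ndarray, margin: float, shape_yx, pixel_size: float):
    v = np.asarray(vertices, dtype=float)
    ny, nx = shape_yx
    x0 = max(int(np.floor((v[:, 0].min() - margin) / pixel_size)), 0)
    x1 = min(int(np.ceil((v[:, 0].max() + margin) / pixel_size)) + 1, nx)
    y0 = max(int(np.floor((v[:, 1].min() - margin) / pixel_size)), 0)
    y1 = min(int(np.ceil((v[:, 1].max() + margin) / pixel_size)) + 1, ny)
    return slice(y0, y1), slice(x0, x1)


def rasterize_polygon(vertices: np.ndarray, shape_yx, pixel_size: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie strictly inside the polygon."""
    mask = np.zeros(shape_yx, dtype=bool)
    sy, sx = _bbox_slice(vertices, pixel_size, shape_yx, pixel_size)
    if sy.stop <= sy.start or sx.stop <= sx.start:
        return mask
    cols = np.arange(sx.start, sx.stop)
    rows = np.arange(sy.start, sy.stop)
    xg, yg = np.meshgrid(cols * pixel_size, rows * pixel_size)
    poly = Polygon(np.asarray(vertices, dtype=float))
    inside = shapely.contains_xy(poly, xg.ravel(), yg.ravel())
    mask[sy, sx] = inside.reshape(xg.shape)
    return mask


def rasterize_boundary_band(vertices: np.ndarray, shape_yx, pixel_size: float,
                            half_width: float) -> np.ndarray:
    """Pixels whose centres lie within ``half_width`` of the polygon boundary."""
    mask = np.zeros(shape_yx, dtype=bool)
    sy, sx = _bbox_slice(vertices, half_width + pixel_size, shape_yx, pixel_size)
    if sy.stop <= sy.start or sx.stop <= sx.start:
        return mask
    cols = np.arange(sx.start, sx.stop)
    rows = np.arange(sy.start, sy.stop)
    xg, yg = np.meshgrid(cols * pixel_size, rows * pixel_size)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    d = distance_to_segments(pts, vertices)
    mask[sy, sx] = (d <= half_width).reshape(xg.shape)
    return mask


def rasterize_polyline_band(vertices: np.ndarray, line_width: float,
                            shape_yx, pixel_size: float) -> np.ndarray:
    """Stroked band of a polyline: pixel centres within width/2 of the line.

    Flat end caps — the band terminates at the line endpoints, matching the
    behaviour of a thick segmented-line selection.
    """
    line = LineString(np.asarray(vertices, dtype=float))
    band = line.buffer(line_width / 2.0, cap_style="flat")
    mask = np.zeros(shape_yx, dtype=bool)
    sy, sx = _bbox_slice(np.asarray(vertices, float), line_width, shape_yx, pixel_size)
    if sy.stop <= sy.start or sx.stop <= sx.start:
        return mask
    cols = np.arange(sx.start, sx.stop)
    rows = np.arange(sy.start, sy.stop)
    xg, yg = np.meshgrid(cols * pixel_size, rows * pixel_size)
    inside = shapely.contains_xy(band, xg.ravel(), yg.ravel())
    mask[sy, sx] = inside.reshape(xg.shape)
    return mask


def erode_polygon(vertices: np.ndarray, distance: float) -> np.ndarray | None:
    """Inward offset of a polygon by ``distance`` µm.

    Returns the vertex array of the largest resulting ring, or None when the
    erosion annihilates the polygon.
    """
    if distance == 0:
        return np.asarray(vertices, dtype=float)
    poly = Polygon(np.asarray(vertices, dtype=float)).buffer(-abs(distance))
    if poly.is_empty:
        return None
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    if poly.area <= 0:
        return None
    return np.asarray(poly.exterior.coords[:-1], dtype=float)
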