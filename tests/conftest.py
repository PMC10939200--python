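import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, Polygon

from bmsecq.pipeline import secretion_study


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately written point-by-point with shapely so
# they share no code path with the vectorized mask construction


def oracle_band_mask(vertices, shape_yx, pixel_size, half_width):
    """Pixel centres within half_width of the polygon boundary."""
    boundary = Polygon(vertices).exterior
    mask = np.zeros(shape_yx, dtype=bool)
    for r in range(shape_yx[0]):
        for c in range(shape_yx[1]):
            p = Point(c * pixel_size, r * pixel_size)
            mask[r, c] = boundary.distance(p) <= half_width
    return mask


def oracle_polygon_mask(vertices, shape_yx, pixel_size):
    poly = Polygon(vertices)
    mask = np.zeros(shape_yx, dtype=bool)
    for r in range(shape_yx[0]):
        for c in range(shape_yx[1]):
            mask[r, c] = poly.contains(Point(c * pixel_size, r * pixel_size))
    return mask


def oracle_polyline_mask(vertices, line_width, shape_yx, pixel_size):
    band = LineString(vertices).buffer(line_width / 2.0, cap_style="flat")
    mask = np.zeros(shape_yx, dtype=bool)
    for r in range(shape_yx[0]):
        for c in range(shape_yx[1]):
            mask[r, c] = band.contains(Point(c * pixel_size, r * pixel_size))
    return mask


def oracle_masked_sum(volume, mask3d):
    """Voxel-by-voxel accumulation over an explicit boolean grid."""
    total = 0.0
    nz, ny, nx = volume.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if mask3d[z, y, x]:
                    total += volume[z, y, x]
    return total


def oracle_weighted_centroid(volume, mask3d, pixel_size):
    sw = sx = sy = 0.0
    nz, ny, nx = volume.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if mask3d[z, y, x]:
                    w = volume[z, y, x]
                    sw += w
                    sx += w * x * pixel_size
                    sy += w * y * pixel_size
    return np.array([sx / sw, sy / sw]) if sw > 0 else None


def regular_polygon(radius, n=64, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


# ---------------------------------------------------------------------------
# the 30-cell control study under default noise; shared by the acceptance
# checks on the lateral fraction, the orientation convention and the
# suprabasal band height


@pytest.fixture(scope="session")
def control_study():
    return secretion_study(n_cells=30, seed=1, preset="control")
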