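"""Synthetic-microscopy ground truth for every pipeline stage.

The generator emulates the imaging situations the pipeline quantifies in the
fly follicular epithelium:

* ``gen_single_cell`` — a columnar follicle cell seen in a two-channel 3-D
  stack: an F-actin cortex ridge on every plane (with stress fibres marking
  the basal plane), and a secreted-protein channel split between a
  rear-biased lateral band hugging the cortex just above the basal surface
  and small basal foci on the planes beyond the cell surface;
* ``gen_bm_surface`` — the basal BM as a homogeneous matrix plus oriented
  fibrils, with the fibril share of total fluorescence solved exactly;
* ``gen_sagittal`` — a cross-section with apical and basal BM walls whose
  intensity split realises a chosen apical fraction;
* ``gen_edge_stack`` — a hexagonal cortex whose trailing edge carries a
  chosen multiple of the front-lateral intensity.

Every dataset carries the generating parameters and truth labels, so each
measurement stage can be validated by parameter recovery.  Identical
(params, seed) pairs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from shapely.geometry import Point, Polygon

from .core_io import CellOutline, ImageStack, PlanarROI
from .geometry import distance_to_segments, pixel_centers, rasterize_polygon


@dataclass
class SynthParams:
    """Generating parameters; defaults are the wild-type ("control") regime."""

    # --- single-cell stack geometry
    pixel_size_um: float = 0.1
    z_step_um: float = 0.15          # focal-plane spacing
    n_planes: int = 12               # 3 sub-basal slices + basal + 8 lateral
    basal_plane: int = 3             # z index of the basal surface
    fov_um: float = 18.0
    cell_radius_um: float = 5.0      # mean cortex radius
    radius_jitter: float = 0.12      # relative radial perturbation of vertices
    n_cortex_vertices: int = 12

    # --- secretion ground truth
    lateral_fraction_true: float = 70.0   # % of secreted signal in the lateral band
    band_height_um: float = 0.8           # lateral band confined below this height
    polar_sigma_deg: float = 35.0         # azimuthal spread of the lateral band
    polar_jitter_deg: float = 12.0        # per-cell jitter of the band direction
    migration_angle_deg: float | None = None  # None -> random per cell
    basal_foci_n: int = 6
    basal_foci_sigma_um: float = 0.18
    rear_bias: bool = True

    # --- intensity model
    total_signal: float = 2.0e5      # photons summed over the secreted channel
    cortex_amp: float = 120.0        # F-actin cortex peak (photons)
    cortex_sigma_um: float = 0.12
    lateral_sigma_um: float = 0.15   # radial width of the lateral band
    stress_fiber_amp: float = 90.0
    background_offset: float = 8.0   # photons, uniform
    read_noise_sigma: float = 2.0
    noise_scale: float = 1.0         # 0 disables all noise

    # --- basal BM surface
    bm_size_um: float = 40.0
    bm_pixel_um: float = 0.2
    matrix_level: float = 100.0
    ff_true: float = 25.0            # fibril fraction (%) to realise
    fibril_amplitude: float | None = None  # set -> use directly, skip solving
    fibril_width_um: float = 0.7
    fibril_length_um: tuple[float, float] = (6.0, 18.0)
    fibril_orientation_deg: float = 0.0
    fibril_orientation_spread_deg: float = 15.0
    bm_snr: float = 10.0             # fibril amplitude / Gaussian noise sigma

    # --- sagittal sections
    apical_fraction_true: float = 5.0
    wall_amp_total: float = 200.0
    wall_sigma_um: float = 0.4
    sagittal_size_um: tuple[float, float] = (30.0, 20.0)
    sagittal_pixel_um: float = 0.15
    roi_line_width_um: float = 1.14

    # --- edge-ratio stacks
    edge_ratio_true: float = 3.0
    edge_amp: float = 100.0

    seed: int = 0

    def __post_init__(self):
        for name in ("lateral_fraction_true", "ff_true", "apical_fraction_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.polar_sigma_deg < 0:
            raise ValueError("polar_sigma_deg must be >= 0")
        if self.band_height_um >= (self.n_planes - self.basal_plane) * self.z_step_um:
            raise ValueError("band_height_um exceeds the lateral stack depth")


# Phenotype presets encode only the directional anchors of the biology they
# mimic: Rab10 gain drives lateral/fibrillar secretion, Rab10 loss and Rab8
# gain drive basal/homogeneous secretion, exocyst (Exo70) loss abolishes
# basal deposition while the lateral band persists, and loss of Dystrophin
# depolarizes trailing-edge enrichment without changing the lateral fraction.
PRESETS: dict[str, dict] = {
    "control": {},
    "rab10_oe": dict(lateral_fraction_true=95.0, basal_foci_n=2, ff_true=40.0),
    "rab10_kd": dict(lateral_fraction_true=45.0, basal_foci_n=10, ff_true=8.0,
                     apical_fraction_true=30.0),
    "rab8_oe": dict(lateral_fraction_true=45.0, basal_foci_n=10, ff_true=10.0),
    "exo70_null": dict(lateral_fraction_true=100.0, basal_foci_n=0, ff_true=10.0),
    "dys_null": dict(edge_ratio_true=1.0, polar_sigma_deg=90.0),
    "hyperpolarized": dict(edge_ratio_true=3.0),
    "depolarized": dict(edge_ratio_true=1.0),
}


def get_preset(name: str, **overrides) -> SynthParams:
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    return SynthParams(**{**base, **overrides})


@dataclass
class SynthDataset:
    """Images + truth labels + the parameter snapshot that generated them."""

    images: dict                  # stage-dependent: ImageStack or 2-D arrays
    labels: dict                  # ground-truth annotations
    truth: dict                   # resolved SynthParams as a plain dict


def _noise(rng: np.random.Generator, photons: np.ndarray,
           p: SynthParams) -> np.ndarray:
    """Scaled-Poisson shot noise plus Gaussian read noise; variance scales
    with ``noise_scale`` and vanishes at 0."""
    if p.noise_scale == 0:
        return photons.copy()
    g = p.noise_scale
    out = rng.poisson(np.maximum(photons, 0.0) / g).astype(float) * g
    out += rng.normal(0.0, p.read_noise_sigma * np.sqrt(g), photons.shape)
    return np.clip(out, 0.0, None)


def _cell_polygon(rng: np.random.Generator, p: SynthParams) -> np.ndarray:
    """Irregular star-convex cortex polygon centred in the field."""
    c = p.fov_um / 2.0
    ang = np.linspace(0, 2 * np.pi, p.n_cortex_vertices, endpoint=False)
    radii = p.cell_radius_um * (1.0 + rng.uniform(-p.radius_jitter,
                                                  p.radius_jitter,
                                                  p.n_cortex_vertices))
    return np.column_stack([c + radii * np.cos(ang), c + radii * np.sin(ang)])


def gen_single_cell(params: SynthParams | None = None, seed: int = 0) -> SynthDataset:
    """Two-channel single-cell stack with secretion ground truth.

    The secreted channel carries ``lateral_fraction_true`` percent of its
    total signal in a cortical band confined below ``band_height_um`` above
    the basal surface and azimuthally concentrated at the cell rear; the
    remainder sits in small foci on the sub-basal planes, rear-biased when
    ``rear_bias`` is set.
    """
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    px, zs = p.pixel_size_um, p.z_step_um
    n_px = int(round(p.fov_um / px))
    shape_yx = (n_px, n_px)
    xg, yg = pixel_centers(shape_yx, px)
    pts = np.column_stack([xg.ravel(), yg.ravel()])

    poly = _cell_polygon(rng, p)
    centroid = poly.mean(axis=0)
    if p.migration_angle_deg is None:
        migration = float(rng.uniform(0.0, 360.0))
    else:
        migration = float(p.migration_angle_deg)
    rear = (migration + 180.0) % 360.0
    polar_angle = rear + (rng.normal(0.0, p.polar_jitter_deg)
                          if p.polar_jitter_deg > 0 else 0.0)

    d_boundary = distance_to_segments(pts, poly).reshape(shape_yx)
    inside = rasterize_polygon(poly, shape_yx, px)

    # ---- F-actin channel: cortex ridge everywhere, stress fibres basally
    cortex = p.cortex_amp * np.exp(-d_boundary ** 2 / (2 * p.cortex_sigma_um ** 2))
    theta = np.deg2rad(migration)
    normal = np.array([-np.sin(theta), np.cos(theta)])   # perpendicular to travel
    u = (pts - centroid) @ normal
    offsets = np.arange(-p.cell_radius_um, p.cell_radius_um + 1e-9, 1.0)
    fibers = np.zeros(len(pts))
    for o in offsets:
        fibers += np.exp(-(u - o) ** 2 / (2 * 0.12 ** 2))
    fibers = (p.stress_fiber_amp * fibers.reshape(shape_yx)) * inside
    actin = np.repeat(cortex[None], p.n_planes, axis=0)
    actin[p.basal_plane] += fibers

    # ---- secreted channel
    secreted = np.zeros((p.n_planes,) + shape_yx)
    f = p.lateral_fraction_true / 100.0

    # lateral band: radial Gaussian on the cortex x azimuthal von Mises x
    # exponential decay in height, truncated at band_height_um
    sigma_rad = np.deg2rad(max(p.polar_sigma_deg, 1e-3))
    kappa = 1.0 / sigma_rad ** 2
    az = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    w_az = np.exp(kappa * (np.cos(az - np.deg2rad(polar_angle)) - 1.0))
    w_rad = np.exp(-d_boundary.ravel() ** 2 / (2 * p.lateral_sigma_um ** 2))
    profile_xy = (w_az * w_rad).reshape(shape_yx)
    lateral = np.zeros_like(secreted)
    for k in range(p.basal_plane, p.n_planes):
        h = (k - p.basal_plane) * zs
        if h >= p.band_height_um:
            break
        lateral[k] = profile_xy * np.exp(-h / (p.band_height_um / 2.0))
    lat_sum = lateral.sum()
    if lat_sum > 0 and f > 0:
        secreted += lateral * (f * p.total_signal / lat_sum)

    # basal foci on the sub-basal slices, centres kept clear of the eroded
    # basal-cylinder boundary so the full cylinder captures them
    foci_xy = []
    if p.basal_foci_n > 0 and f < 1.0:
        margin = 0.75 + 3.0 * p.basal_foci_sigma_um
        safe = Polygon(poly).buffer(-margin)
        for _ in range(p.basal_foci_n):
            for _attempt in range(200):
                if p.rear_bias:
                    a = rng.vonmises(np.deg2rad(rear), 2.0)
                else:
                    a = rng.uniform(-np.pi, np.pi)
                r = p.cell_radius_um * np.sqrt(rng.uniform(0.05, 0.8))
                cand = centroid + r * np.array([np.cos(a), np.sin(a)])
                if safe.contains(Point(cand)):
                    foci_xy.append(cand)
                    break
        basal = np.zeros_like(secreted)
        zw = {p.basal_plane - 1: 0.5, p.basal_plane - 2: 0.3, p.basal_plane - 3: 0.2}
        for cx, cy in foci_xy:
            spot = np.exp(-((xg - cx) ** 2 + (yg - cy) ** 2)
                          / (2 * p.basal_foci_sigma_um ** 2))
            for k, w in zw.items():
                if 0 <= k < p.basal_plane:
                    basal[k] += w * spot
        b_sum = basal.sum()
        if b_sum > 0:
            secreted += basal * ((1.0 - f) * p.total_signal / b_sum)

    actin = _noise(rng, actin + p.background_offset, p)
    secreted = _noise(rng, secreted + p.background_offset, p)

    stack = ImageStack(np.stack([actin, secreted]), px, zs,
                       ("actin", "secreted"), z_origin=p.basal_plane)

    lateral_planes = list(range(p.basal_plane, p.n_planes - 0))[:9]
    outline = CellOutline(
        cell_id=f"synth-{seed}",
        polygons={z: PlanarROI("polygon", poly, plane=z, name=f"cell-z{z}")
                  for z in lateral_planes},
        migration_angle=migration)
    bg_roi = PlanarROI("polygon",
                       np.array([[0.5, 0.5], [3.0, 0.5], [3.0, 3.0], [0.5, 3.0]]),
                       plane="projection", name="background")
    truth = asdict(replace(p, migration_angle_deg=migration, seed=seed))
    truth["polar_angle_true_deg"] = float(polar_angle % 360.0)
    return SynthDataset(
        images={"stack": stack},
        labels={"outline": outline, "basal_plane": p.basal_plane,
                "migration_angle_deg": migration,
                "background_roi": bg_roi,
                "cortex_polygon": poly, "centroid": centroid,
                "foci_xy": np.array(foci_xy).reshape(-1, 2)},
        truth=truth)


# ---------------------------------------------------------------------------
# basal BM surface


def _fibril_profile(rng, p: SynthParams, shape_yx):
    """Accumulated unit-amplitude fibril profile and the truth mask."""
    px = p.bm_pixel_um
    xg, yg = pixel_centers(shape_yx, px)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    sigma = p.fibril_width_um / 2.355          # FWHM = stated width
    size = p.bm_size_um
    coverage_target = 0.55 * p.ff_true / 100.0
    mean_len = float(np.mean(p.fibril_length_um))
    n_fibrils = max(1, int(round(coverage_target * size * size
                                 / (p.fibril_width_um * mean_len))))
    profile = np.zeros(len(pts))
    dist_min = np.full(len(pts), np.inf)
    for _ in range(n_fibrils):
        ori = np.deg2rad(p.fibril_orientation_deg
                         + rng.normal(0.0, p.fibril_orientation_spread_deg))
        length = rng.uniform(*p.fibril_length_um)
        c = rng.uniform(0.1 * size, 0.9 * size, size=2)
        u = np.array([np.cos(ori), np.sin(ori)])
        a, b = c - u * length / 2.0, c + u * length / 2.0
        d = distance_to_segments(pts, np.array([a, b, b]))  # degenerate "polygon"
        profile += np.exp(-d ** 2 / (2 * sigma ** 2))
        dist_min = np.minimum(dist_min, d)
    mask = (dist_min < p.fibril_width_um / 2.0).reshape(shape_yx)
    return profile.reshape(shape_yx), mask


def gen_bm_surface(params: SynthParams | None = None, seed: int = 0) -> SynthDataset:
    """2-D basal BM image: homogeneous matrix plus oriented fibrils.

    When ``fibril_amplitude`` is unset, the amplitude is solved so that the
    share of total noiseless fluorescence falling on the truth fibril mask
    equals ``ff_true`` (to float precision).  Noise is Gaussian with sigma =
    amplitude / ``bm_snr``.
    """
    p = params or SynthParams()
    if p.ff_true > 95.0:
        raise ValueError(f"ff_true {p.ff_true} > 95% is not realizable")
    rng = np.random.default_rng(seed)
    n = int(round(p.bm_size_um / p.bm_pixel_um))
    shape = (n, n)
    m = p.matrix_level

    if p.ff_true == 0.0 or p.fibril_amplitude == 0.0:
        profile = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        amp = 0.0
    else:
        profile, mask = _fibril_profile(rng, p, shape)
        if p.fibril_amplitude is not None:
            amp = float(p.fibril_amplitude)
        else:
            s = p.ff_true / 100.0
            n_tot, n_mask = mask.size, int(mask.sum())
            p_tot, p_mask = float(profile.sum()), float(profile[mask].sum())
            denom = p_mask - s * p_tot
            amp = m * (s * n_tot - n_mask) / denom if denom > 0 else -1.0
            if amp <= 0:
                raise ValueError(
                    f"ff_true {p.ff_true}% infeasible for this fibril geometry")

    clean = m + amp * profile
    noisy = clean.copy()
    if p.noise_scale > 0 and amp > 0:
        noisy += rng.normal(0.0, p.noise_scale * amp / p.bm_snr, shape)
        noisy = np.clip(noisy, 0.0, None)
    region = PlanarROI("polygon", np.array(
        [[0.0, 0.0], [p.bm_size_um, 0.0],
         [p.bm_size_um, p.bm_size_um], [0.0, p.bm_size_um]]), name="analysis")
    share = 100.0 * float(clean[mask].sum()) / float(clean.sum())
    truth = asdict(replace(p, seed=seed))
    truth["fibril_amplitude"] = amp
    truth["ff_noiseless"] = share
    return SynthDataset(images={"bm": noisy, "bm_clean": clean},
                        labels={"fibril_mask": mask, "analysis_region": region,
                                "matrix_level": m},
                        truth=truth)


# ---------------------------------------------------------------------------
# sagittal sections


def gen_sagittal(params: SynthParams | None = None, seed: int = 0) -> SynthDataset:
    """Cross-section with apical and basal BM walls; intensity split realises
    ``apical_fraction_true``.  Emits ROI pairs along both walls."""
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    px = p.sagittal_pixel_um
    wx, wy = p.sagittal_size_um
    shape = (int(round(wy / px)), int(round(wx / px)))
    xg, yg = pixel_centers(shape, px)
    y_apical, y_basal = 0.3 * wy, 0.7 * wy
    frac = p.apical_fraction_true / 100.0
    a_amp = frac * p.wall_amp_total
    b_amp = (1.0 - frac) * p.wall_amp_total
    img = (a_amp * np.exp(-(yg - y_apical) ** 2 / (2 * p.wall_sigma_um ** 2))
           + b_amp * np.exp(-(yg - y_basal) ** 2 / (2 * p.wall_sigma_um ** 2)))
    if p.noise_scale > 0:
        img = np.clip(img + rng.normal(0.0, p.read_noise_sigma * p.noise_scale,
                                       shape), 0.0, None)
    pairs = []
    spans = [(0.1 * wx, 0.4 * wx), (0.4 * wx, 0.7 * wx), (0.7 * wx, 0.95 * wx)]
    for i, (x0, x1) in enumerate(spans):
        apical = PlanarROI("polyline", np.array([[x0, y_apical], [x1, y_apical]]),
                           line_width=p.roi_line_width_um, name=f"apical-{i}")
        basal = PlanarROI("polyline", np.array([[x0, y_basal], [x1, y_basal]]),
                          line_width=p.roi_line_width_um, name=f"basal-{i}")
        pairs.append((apical, basal))
    return SynthDataset(images={"section": img},
                        labels={"roi_pairs": pairs,
                                "y_apical_um": y_apical, "y_basal_um": y_basal},
                        truth=asdict(replace(p, seed=seed)))


# ---------------------------------------------------------------------------
# edge-ratio stacks


def gen_edge_stack(params: SynthParams | None = None, seed: int = 0) -> SynthDataset:
    """Hexagonal cortex stack whose trailing (rear, +90°) edge carries
    ``edge_ratio_true`` times the front-lateral edge intensity.

    Emits the trailing / front / background measurement polylines.  The
    stack is already oriented: migration points to -90°, the rear to +90°.
    """
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    px = p.pixel_size_um
    n_px = int(round(p.fov_um / px))
    shape = (n_px, n_px)
    n_planes = 5
    xg, yg = pixel_centers(shape, px)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    c = p.fov_um / 2.0
    # 10° phase keeps every edge off the pixel-grid axes, so thick-line
    # bands rasterize with unbiased pixel coverage
    ang = np.deg2rad(np.arange(0, 360, 60) + 10.0)
    hexagon = np.column_stack([c + p.cell_radius_um * np.cos(ang),
                               c + p.cell_radius_um * np.sin(ang)])

    # per-pixel nearest hexagon edge -> edge-dependent amplitude
    segs = np.stack([hexagon, np.roll(hexagon, -1, axis=0)], axis=1)
    dists = np.stack([distance_to_segments(pts, np.array([a, b, b]))
                      for a, b in segs])                       # (6, N)
    nearest = np.argmin(dists, axis=0)
    d = dists[nearest, np.arange(len(pts))]
    mid_angles = np.rad2deg(np.arctan2(
        segs[:, :, 1].mean(axis=1) - c, segs[:, :, 0].mean(axis=1) - c)) % 360
    rear_edge = int(np.argmin(np.abs(((mid_angles - 90) + 180) % 360 - 180)))
    amps = np.full(6, p.edge_amp)
    amps[rear_edge] = p.edge_amp * p.edge_ratio_true
    plane_img = (amps[nearest] * np.exp(-d ** 2 / (2 * 0.15 ** 2))).reshape(shape)

    stack_arr = np.zeros((n_planes,) + shape)
    for k in (1, 2, 3):                       # suprabasal cortex band
        stack_arr[k] = plane_img
    stack_arr[0] = 0.3 * plane_img
    stack_arr[4] = 0.3 * plane_img
    stack_arr = _noise(rng, stack_arr + p.background_offset, p)
    stack = ImageStack(stack_arr[None], px, p.z_step_um, ("signal",), z_origin=0)

    def _edge_line(i: int) -> np.ndarray:
        a, b = segs[i]
        return np.array([a + 0.15 * (b - a), a + 0.85 * (b - a)])

    # front-lateral side: the edge adjacent to the front (-90°) edge
    front_edge = int(np.argmin(np.abs(((mid_angles + 90) + 180) % 360 - 180)))
    front_lateral = (front_edge + 1) % 6
    width = p.roi_line_width_um
    trailing = PlanarROI("polyline", _edge_line(rear_edge), line_width=width,
                         name="trailing")
    front = PlanarROI("polyline", _edge_line(front_lateral), line_width=width,
                      name="front")
    background = PlanarROI("polyline", np.array([[1.0, 1.0], [4.0, 1.0]]),
                           line_width=width, name="background")
    return SynthDataset(
        images={"stack": stack},
        labels={"trailing": trailing, "front": front, "background": background,
                "hexagon": hexagon, "migration_angle_deg": -90.0},
        truth=asdict(replace(p, seed=seed)))
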