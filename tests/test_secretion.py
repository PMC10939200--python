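import numpy as np
import pytest
from scipy.stats import circmean as scipy_circmean

from bmsecq import gen_single_cell
from bmsecq.core_io import CellOutline, ImageStack, PlanarROI
from bmsecq.pipeline import analyze_cell, derive_seed, secretion_study
from bmsecq.secretion import (EmptyMaskError, MaskError, VoxelMask,
                              build_background_mask, build_basal_cylinder,
                              build_hollow_cylinder, circular_summary,
                              measure_secretion, polarization_vector,
                              suprabasal_band_height)
from bmsecq.synth import SynthParams
from conftest import regular_polygon


def _stack(shape_zyx=(12, 200, 200), px=0.05, zs=0.15, z_origin=3):
    return ImageStack(np.zeros((1,) + shape_zyx), px, zs, ("secreted",),
                      z_origin=z_origin)


def _outline(poly, planes, migration=0.0):
    return CellOutline("c", {z: PlanarROI("polygon", poly, plane=z)
                             for z in planes}, migration_angle=migration)


class TestHollowCylinder:
    def test_circle_band_area_matches_annulus_closed_form(self):
        stack = _stack((12, 260, 260))
        circle = regular_polygon(5.0, n=256, center=(6.5, 6.5))
        mask = build_hollow_cylinder(_outline(circle, range(3, 12)), stack,
                                     thickness_um=1.5)
        per_plane = mask.mask[5].sum() * stack.voxel_size_xy ** 2
        expected = np.pi * (5.75 ** 2 - 4.25 ** 2)      # 15*pi
        assert per_plane == pytest.approx(expected, rel=0.02)
        assert mask.planes == list(range(3, 12))

    def test_square_band_area_close_to_perimeter_times_thickness(self):
        stack = _stack((12, 300, 300))
        square = np.array([[2.0, 2.0], [12.0, 2.0], [12.0, 12.0], [2.0, 12.0]])
        mask = build_hollow_cylinder(_outline(square, [3]), stack, 1.5)
        area = mask.mask[3].sum() * stack.voxel_size_xy ** 2
        assert area == pytest.approx(40.0 * 1.5, rel=0.10)

    def test_subpixel_thickness_warns_and_keeps_a_ring(self):
        stack = _stack((12, 100, 100), px=0.2)
        circle = regular_polygon(5.0, n=128, center=(8, 8))
        with pytest.warns(UserWarning, match="minimum one-pixel band"):
            mask = build_hollow_cylinder(_outline(circle, [3]), stack, 0.01)
        assert mask.mask[3].sum() > 0


class TestBasalCylinder:
    def test_circle_erodes_to_smaller_disk_on_three_sub_basal_planes(self):
        stack = _stack((12, 260, 260))
        circle = PlanarROI("polygon", regular_polygon(5.0, 256, (6.5, 6.5)))
        mask = build_basal_cylinder(circle, stack, shrink_um=0.75, n_planes=3)
        assert mask.planes == [0, 1, 2]
        per_plane = mask.mask[0].sum() * stack.voxel_size_xy ** 2
        assert per_plane == pytest.approx(np.pi * 4.25 ** 2, rel=0.02)
        np.testing.assert_array_equal(mask.mask[0], mask.mask[1])

    def test_zero_shrink_keeps_projected_roi(self):
        stack = _stack((12, 260, 260))
        circle = PlanarROI("polygon", regular_polygon(5.0, 256, (6.5, 6.5)))
        mask = build_basal_cylinder(circle, stack, shrink_um=0.0)
        per_plane = mask.mask[0].sum() * stack.voxel_size_xy ** 2
        assert per_plane == pytest.approx(np.pi * 25.0, rel=0.02)

    def test_erosion_annihilating_polygon_raises(self):
        stack = _stack()
        tiny = PlanarROI("polygon", regular_polygon(0.5, 64, (5, 5)))
        with pytest.raises(EmptyMaskError):
            build_basal_cylinder(tiny, stack, shrink_um=0.75)

    def test_lateral_and_basal_masks_are_disjoint(self):
        ds = gen_single_cell(SynthParams(), seed=9)
        stack = ds.images["stack"]
        outline = ds.labels["outline"]
        lat = build_hollow_cylinder(outline, stack)
        bas = build_basal_cylinder(outline.basal_polygon, stack)
        assert not np.any(lat.mask & bas.mask)


class TestMeasureSecretion:
    def test_pure_lateral_signal_gives_100_percent(self):
        ds = gen_single_cell(SynthParams(lateral_fraction_true=100.0,
                                         basal_foci_n=0, noise_scale=0.0,
                                         background_offset=0.0), seed=1)
        stack = ds.images["stack"]
        outline = ds.labels["outline"]
        lat = build_hollow_cylinder(outline, stack)
        bas = build_basal_cylinder(outline.basal_polygon, stack)
        bg = build_background_mask(ds.labels["background_roi"], stack)
        res = measure_secretion(stack.channel("secreted"), lat, bas, bg)
        assert res.lateral_fraction == pytest.approx(100.0, abs=1e-6)

    def test_hand_placed_intensities_match_brute_force_sums(self):
        rng = np.random.default_rng(12)
        vol = rng.integers(0, 50, (12, 20, 20)).astype(float)
        lat = np.zeros_like(vol, bool)
        bas = np.zeros_like(vol, bool)
        bg = np.zeros_like(vol, bool)
        lat[3:12, 5:9, 5:9] = True
        bas[0:3, 10:14, 10:14] = True
        bg[:, 0:3, 0:3] = True
        res = measure_secretion(vol, VoxelMask(lat, "lateral"),
                                VoxelMask(bas, "basal"),
                                VoxelMask(bg, "background"))
        # brute-force enumeration of in-mask voxels
        b_lat = vol[3:12, 0:3, 0:3].mean()
        b_bas = vol[0:3, 0:3, 0:3].mean()
        L = sum(vol[z, y, x] for z in range(3, 12) for y in range(5, 9)
                for x in range(5, 9)) - lat.sum() * b_lat
        B = sum(vol[z, y, x] for z in range(3) for y in range(10, 14)
                for x in range(10, 14)) - bas.sum() * b_bas
        assert res.lateral_intensity == pytest.approx(max(L, 0.0), abs=1e-9)
        assert res.basal_intensity == pytest.approx(max(B, 0.0), abs=1e-9)

    def test_fraction_invariant_to_offset_and_scale(self):
        ds = gen_single_cell(SynthParams(noise_scale=0.0), seed=6)
        stack = ds.images["stack"]
        outline = ds.labels["outline"]
        lat = build_hollow_cylinder(outline, stack)
        bas = build_basal_cylinder(outline.basal_polygon, stack)
        bg = build_background_mask(ds.labels["background_roi"], stack)
        vol = stack.channel("secreted")
        base = measure_secretion(vol, lat, bas, bg).lateral_fraction
        offset = measure_secretion(vol + 11.0, lat, bas, bg).lateral_fraction
        scaled = measure_secretion(vol * 4.2, lat, bas, bg).lateral_fraction
        assert offset == pytest.approx(base, abs=1e-6)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_signal_reports_null_fraction_not_zero(self):
        vol = np.full((12, 20, 20), 5.0)
        lat = np.zeros_like(vol, bool); lat[3:, 5:8, 5:8] = True
        bas = np.zeros_like(vol, bool); bas[:3, 10:12, 10:12] = True
        bg = np.zeros_like(vol, bool); bg[:, 0:3, 0:3] = True
        res = measure_secretion(vol, VoxelMask(lat, "lateral"),
                                VoxelMask(bas, "basal"),
                                VoxelMask(bg, "background"))
        assert res.lateral_fraction is None
        assert "undefined_fraction" in res.flags

    def test_overlapping_masks_rejected(self):
        vol = np.zeros((12, 20, 20))
        a = np.zeros_like(vol, bool); a[3, 5:10, 5:10] = True
        bg = np.zeros_like(vol, bool); bg[:, 0:2, 0:2] = True
        with pytest.raises(MaskError):
            measure_secretion(vol, VoxelMask(a, "lateral"),
                              VoxelMask(a, "basal"),
                              VoxelMask(bg, "background"))


class TestPolarizationVector:
    def test_uniform_ring_has_no_direction(self):
        stack = _stack((12, 260, 260))
        circle = regular_polygon(5.0, 256, (6.5, 6.5))
        lat = build_hollow_cylinder(_outline(circle, range(3, 12)), stack)
        vol = np.where(lat.mask, 10.0, 0.0)
        v = polarization_vector(vol, lat, stack.voxel_size_xy)
        assert v.magnitude < 0.02
        # degenerate: zero weight -> null angle
        v0 = polarization_vector(np.zeros_like(vol), lat,
                                 stack.voxel_size_xy)
        assert v0.angle is None and v0.magnitude == 0.0

    def test_single_voxel_due_north_gives_90_degrees(self):
        stack = _stack((12, 260, 260))
        circle = regular_polygon(5.0, 256, (6.5, 6.5))
        lat = build_hollow_cylinder(_outline(circle, range(3, 12)), stack)
        vol = np.zeros(stack.shape_zyx)
        # brightest voxel on the ring straight up (+y) from the centroid
        iy, ix = int(round(11.5 / 0.05)), int(round(6.5 / 0.05))
        assert lat.mask[5, iy, ix]
        vol[5, iy, ix] = 1000.0
        v = polarization_vector(vol, lat, stack.voxel_size_xy)
        assert v.angle == pytest.approx(90.0, abs=1.0)

    def test_rotation_equivariance_under_quarter_turns(self):
        ds = gen_single_cell(SynthParams(noise_scale=0.0), seed=13)
        stack = ds.images["stack"]
        outline = ds.labels["outline"]
        lat = build_hollow_cylinder(outline, stack)
        vol = stack.channel("secreted")
        v = polarization_vector(vol, lat, stack.voxel_size_xy)
        # rotate volume and mask 90 deg CCW in the (x, y) frame
        vol_r = np.rot90(vol, k=1, axes=(2, 1))
        mask_r = np.rot90(lat.mask, k=1, axes=(2, 1))
        v_r = polarization_vector(vol_r, VoxelMask(mask_r, "lateral"),
                                  stack.voxel_size_xy)
        assert v_r.dx == pytest.approx(-v.dy, abs=1e-6)
        assert v_r.dy == pytest.approx(v.dx, abs=1e-6)


class TestCircularSummary:
    def test_identical_angles(self):
        s = circular_summary([90.0, 90.0, 90.0])
        assert s.circular_mean == pytest.approx(90.0)
        assert s.resultant_length == pytest.approx(1.0)

    def test_antipodal_angles_cancel(self):
        s = circular_summary([0.0, 180.0])
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert s.circular_mean is None

    def test_wrapped_normal_sample_matches_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 20.0
        angles = (90.0 + rng.normal(0, sigma, 100)) % 360.0
        s = circular_summary(list(angles))
        assert s.circular_mean == pytest.approx(90.0, abs=5.0)
        expected_r = np.exp(-np.deg2rad(sigma) ** 2 / 2.0)
        assert s.resultant_length == pytest.approx(expected_r, abs=0.05)
        ref = np.rad2deg(scipy_circmean(np.deg2rad(angles))) % 360.0
        assert s.circular_mean == pytest.approx(ref, abs=1e-9)

    def test_all_null_vectors_rejected(self):
        from bmsecq.secretion import PolarizationVector
        with pytest.raises(ValueError):
            circular_summary([PolarizationVector(0.0, 0.0, 0.0)])


class TestSuprabasalBand:
    def test_band_height_on_synthetic_profile(self):
        vol = np.zeros((12, 10, 10))
        mask = np.zeros_like(vol, bool)
        mask[3:12, 4:6, 4:6] = True
        vol[3] = 50.0
        vol[4] = 40.0
        vol[5] = 10.0          # 90/100 in two planes
        h = suprabasal_band_height(vol, VoxelMask(mask, "lateral"), 0.15,
                                   fraction=0.8)
        assert h == pytest.approx(0.30)


class TestParameterRecovery:
    def test_lateral_fraction_ladder_recovered_within_5_points(self):
        for f in (10.0, 30.0, 50.0, 70.0, 90.0):
            study = secretion_study(n_cells=20, seed=17,
                                    lateral_fraction_true=f)
            assert study["mean_lateral_fraction"] == pytest.approx(f, abs=5.0)
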