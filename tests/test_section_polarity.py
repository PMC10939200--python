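import numpy as np
import pytest

from bmsecq import gen_edge_stack, gen_sagittal, get_preset
from bmsecq.core_io import ImageStack, PlanarROI
from bmsecq.section_polarity import (RoiPair, apical_fraction, basal_intensity,
                                     edge_ratio, mean_gray,
                                     project_suprabasal)
from bmsecq.synth import SynthParams
from conftest import oracle_polyline_mask

PX = 0.15


def _line(y, x0=2.0, x1=10.0, width=1.14, name=""):
    return PlanarROI("polyline", np.array([[x0, y], [x1, y]]),
                     line_width=width, name=name)


class TestApicalFraction:
    def test_dark_apical_wall_is_zero_percent(self):
        img = np.zeros((100, 100))
        img[60:64, :] = 50.0                      # basal wall at y=9.0-9.6
        pair = RoiPair(apical=_line(3.0), basal=_line(9.2))
        fractions, follicle = apical_fraction(img, [pair], PX)
        assert fractions[0] == pytest.approx(0.0)
        assert follicle == pytest.approx(0.0)

    def test_equal_walls_give_50_percent(self):
        img = np.zeros((100, 100))
        img[20:24, :] = 80.0
        img[60:64, :] = 80.0
        pair = RoiPair(apical=_line(3.15), basal=_line(9.15))
        _, follicle = apical_fraction(img, [pair], PX)
        assert follicle == pytest.approx(50.0, abs=0.5)

    def test_zero_total_signal_is_null(self):
        pair = RoiPair(apical=_line(3.0), basal=_line(9.0))
        fractions, follicle = apical_fraction(np.zeros((100, 100)), [pair], PX)
        assert fractions == [None]
        assert follicle is None

    def test_offset_with_background_roi_and_scale_invariance(self):
        ds = gen_sagittal(SynthParams(apical_fraction_true=30.0,
                                      noise_scale=0.0), seed=1)
        img = ds.images["section"]
        pairs = [RoiPair(apical=a, basal=b) for a, b in ds.labels["roi_pairs"]]
        bg = _line(1.0, x0=3.0, x1=27.0)
        _, base = apical_fraction(img, pairs, PX)
        _, offset = apical_fraction(img + 25.0, pairs, PX, background=bg)
        _, scaled = apical_fraction(img * 3.0, pairs, PX)
        assert offset == pytest.approx(base, abs=1e-6)
        assert scaled == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("true_frac", [5.0, 30.0, 95.0])
    def test_generator_fraction_recovered(self, true_frac):
        vals = []
        for s in range(5):
            ds = gen_sagittal(SynthParams(apical_fraction_true=true_frac),
                              seed=70 + s)
            pairs = [RoiPair(apical=a, basal=b)
                     for a, b in ds.labels["roi_pairs"]]
            vals.append(apical_fraction(ds.images["section"], pairs, PX)[1])
        assert np.mean(vals) == pytest.approx(true_frac, abs=3.0)


class TestMeanGrayAndBasalIntensity:
    def test_mean_gray_matches_pointwise_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 100, (60, 60)).astype(float)
        roi = PlanarROI("polyline", np.array([[1.3, 2.1], [7.9, 6.4]]),
                        line_width=1.14)
        mask = oracle_polyline_mask(roi.vertices, roi.line_width,
                                    img.shape, PX)
        assert mean_gray(img, roi, PX) == pytest.approx(img[mask].mean(),
                                                        abs=1e-9)

    def test_basal_intensity_is_sum_over_area(self):
        img = np.full((40, 40), 7.0)
        roi = PlanarROI("polygon", np.array([[1, 1], [4, 1], [4, 4], [1, 4]],
                                            float))
        # constant field: sum/area = c * (pixel count) * ... / area = c/px^2
        val = basal_intensity(img, roi, PX)
        assert val == pytest.approx(7.0 / PX ** 2, rel=0.05)
        assert basal_intensity(img * 2, roi, PX) == pytest.approx(2 * val)


class TestProjectSuprabasal:
    def test_mean_of_three_constant_planes(self):
        vox = np.zeros((1, 5, 8, 8))
        vox[0, 1], vox[0, 2], vox[0, 3] = 10.0, 20.0, 30.0
        stack = ImageStack(vox, 0.1, 0.15, ("signal",), z_origin=0)
        proj = project_suprabasal(stack, "signal")
        np.testing.assert_allclose(proj, 20.0)

    def test_plane_indexing_from_basal_origin(self):
        vox = np.zeros((1, 8, 4, 4))
        marked = [3, 4, 5]                 # basal plane 2 -> planes 3,4,5
        for z in marked:
            vox[0, z] = 1.0
        stack = ImageStack(vox, 0.1, 0.15, ("signal",), z_origin=2)
        proj = project_suprabasal(stack, "signal")
        np.testing.assert_allclose(proj, 1.0)

    def test_insufficient_planes_raise(self):
        vox = np.zeros((1, 3, 4, 4))
        stack = ImageStack(vox, 0.1, 0.15, ("signal",), z_origin=2)
        with pytest.raises(ValueError):
            project_suprabasal(stack, "signal")


class TestEdgeRatio:
    def test_forced_arithmetic(self):
        img = np.full((100, 100), 50.0)
        img[19:28, 10:70] = 150.0          # trailing band at y=3.45
        img[59:68, 10:70] = 100.0          # front band at y=9.45
        m = edge_ratio(img, _line(3.45, 1.5, 10.5), _line(9.45, 1.5, 10.5),
                       _line(13.0, 1.5, 10.5), PX)
        assert m.ratio == pytest.approx(2.0, abs=0.05)

    def test_equal_edges_give_ratio_one(self):
        img = np.full((100, 100), 30.0)
        img[19:28, :] = 90.0
        img[59:68, :] = 90.0
        m = edge_ratio(img, _line(3.45), _line(9.45), _line(13.0), PX)
        assert m.ratio == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_front_signal_gives_null(self):
        img = np.full((100, 100), 20.0)
        m = edge_ratio(img, _line(3.0), _line(9.0), _line(13.0), PX)
        assert m.ratio is None
        assert "nonpositive_front_signal" in m.flags

    def test_offset_invariance_exact(self):
        ds = gen_edge_stack(SynthParams(edge_ratio_true=2.0,
                                        noise_scale=0.0), seed=3)
        proj = project_suprabasal(ds.images["stack"], "signal")
        args = (ds.labels["trailing"], ds.labels["front"],
                ds.labels["background"])
        a = edge_ratio(proj, *args, 0.1).ratio
        b = edge_ratio(proj + 123.0, *args, 0.1).ratio
        assert b == pytest.approx(a, abs=1e-9)

    def test_polarized_and_depolarized_presets(self):
        ratios = {}
        for preset in ("hyperpolarized", "depolarized"):
            vals = []
            for s in range(3):
                ds = gen_edge_stack(get_preset(preset), seed=80 + s)
                proj = project_suprabasal(ds.images["stack"], "signal")
                vals.append(edge_ratio(proj, ds.labels["trailing"],
                                       ds.labels["front"],
                                       ds.labels["background"], 0.1).ratio)
            ratios[preset] = np.mean(vals)
        assert ratios["hyperpolarized"] > 1.5
        assert ratios["depolarized"] == pytest.approx(1.0, abs=0.15)
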