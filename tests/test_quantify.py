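"""Morphometric geometry: reference line, LCD, width chord, LCCD, LCCI."""

import numpy as np
import pytest

from lamina_quant.core import BMOPair
from lamina_quant.phantom import PhantomSpec, analytic_morphometry, generate_phantom
from lamina_quant.postprocess import LCCurveModel, fit_lc_curve
from lamina_quant.quantify import (
    WidthIntersectionError,
    bmo_reference_line,
    lc_width,
    lccd,
    lcci,
    lcd,
    quantify_all,
)


def poly_curve(coeffs, x_lo, x_hi):
    xs = np.arange(x_lo, x_hi + 1, dtype=float)
    ys = np.polynomial.polynomial.polyval(xs, np.asarray(coeffs))
    return fit_lc_curve(np.column_stack([xs, ys]), degree=len(coeffs) - 1, ridge_lambda=0.0)


class TestReferenceLine:
    def test_passes_through_both_points(self):
        ref = bmo_reference_line(BMOPair((10.0, 20.0), (110.0, 25.0)))
        assert ref.p_left == (10.0, 20.0) and ref.p_right == (110.0, 25.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            bmo_reference_line(BMOPair((10.0, 20.0), (10.0 + 1e-12, 20.0)))


class TestLCD:
    def test_flat_curve_below_horizontal_chord(self):
        bmo = BMOPair((20.0, 50.0), (180.0, 50.0))
        curve = poly_curve([130.0], 0, 200)  # constant depth 80 px
        value = lcd(curve, bmo_reference_line(bmo), scale=4.0)
        assert value == pytest.approx(80 * 4.0, rel=1e-6)

    def test_parabola_apex_depth(self):
        bmo = BMOPair((50.0, 40.0), (250.0, 40.0))
        # parabola through (50, 100), (250, 100) with apex +30 at x=150
        coeffs = np.polynomial.polynomial.polyfit([50, 150, 250], [100, 130, 100], 2)
        curve = poly_curve(coeffs, 30, 270)
        value = lcd(curve, bmo_reference_line(bmo), scale=4.0)
        assert value == pytest.approx((130 - 40) * 4.0, rel=1e-4)

    def test_curve_above_line_rejected(self):
        bmo = BMOPair((20.0, 200.0), (180.0, 200.0))
        curve = poly_curve([100.0], 0, 200)  # above the chord (smaller y)
        with pytest.raises(ValueError):
            lcd(curve, bmo_reference_line(bmo), scale=4.0)


class TestWidth:
    def test_horizontal_chord_vertical_perpendiculars(self):
        bmo = BMOPair((60.0, 50.0), (220.0, 50.0))
        curve = poly_curve([120.0, 0.0, 1e-4], 30, 260)
        (q_l, q_r), _ = lc_width(curve, bmo, scale=4.0)
        assert q_l[0] == pytest.approx(60.0, abs=1e-6)
        assert q_r[0] == pytest.approx(220.0, abs=1e-6)

    def test_flat_lc_directly_below(self):
        bmo = BMOPair((50.0, 40.0), (300.0, 40.0))  # 250 px apart at 4 um/px
        curve = poly_curve([140.0], 20, 330)
        _, w = lc_width(curve, bmo, scale=4.0)
        assert w == pytest.approx(250 * 4.0, rel=1e-9)

    def test_tilted_chord_matches_dense_intersection_oracle(self):
        bmo = BMOPair((60.0, 45.0), (260.0, 75.0))
        coeffs = np.polynomial.polynomial.polyfit([60, 160, 260], [150, 190, 170], 2)
        curve = poly_curve(coeffs, 30, 290)
        (q_l, q_r), _ = lc_width(curve, bmo, scale=4.0)
        # oracle: brute-force over dense samples for the point minimizing
        # |chord-tangential coordinate - target|
        p_l = np.array(bmo.left)
        p_r = np.array(bmo.right)
        u = (p_r - p_l) / np.linalg.norm(p_r - p_l)
        xs = np.arange(30, 290, 0.01)
        pts = np.column_stack([xs, np.asarray(curve(xs))])
        t = (pts - p_l) @ u
        x_left = xs[np.argmin(np.abs(t))]
        x_right = xs[np.argmin(np.abs(t - np.linalg.norm(p_r - p_l)))]
        assert q_l[0] == pytest.approx(x_left, abs=0.5)
        assert q_r[0] == pytest.approx(x_right, abs=0.5)

    def test_missing_intersection_names_the_side(self):
        bmo = BMOPair((60.0, 50.0), (220.0, 50.0))
        xs = np.arange(100.0, 260.0)  # curve support starts right of left foot
        model = LCCurveModel.from_points(np.column_stack([xs, np.full_like(xs, 120.0)]))
        with pytest.raises(WidthIntersectionError, match="left"):
            lc_width(model, bmo, scale=4.0)


class TestLCCD:
    def test_straight_line_curve_zero(self):
        bmo = BMOPair((40.0, 50.0), (200.0, 50.0))
        curve = poly_curve([120.0, 0.05], 10, 230)
        ref = bmo_reference_line(bmo)
        chord, _ = lc_width(curve, bmo, ref, scale=4.0)
        assert lccd(curve, chord, scale=4.0) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_parabola_apex(self):
        bmo = BMOPair((50.0, 40.0), (250.0, 40.0))
        coeffs = np.polynomial.polynomial.polyfit([50, 150, 250], [100, 125, 100], 2)
        curve = poly_curve(coeffs, 20, 280)
        chord, _ = lc_width(curve, bmo, scale=4.0)
        assert lccd(curve, chord, scale=4.0) == pytest.approx(25 * 4.0, rel=1e-4)


class TestLCCI:
    @pytest.mark.parametrize("d, w, expected", [(0.0, 500.0, 0.0), (50.0, 1000.0, 5.0)])
    def test_ratio(self, d, w, expected):
        assert lcci(d, w) == pytest.approx(expected)

    def test_equal_depth_and_width_gives_100(self):
        assert lcci(700.0, 700.0) == pytest.approx(100.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            lcci(10.0, 0.0)


class TestQuantifyAll:
    def test_matches_phantom_analytic_oracle(self, small_cohort):
        for spec, scene, truth in small_cohort:
            curve = fit_lc_curve(scene.lc_boundary)
            morph = quantify_all(scene.bmo, curve, spec.microns_per_pixel)
            px_um = spec.microns_per_pixel
            assert abs(morph.lcd - truth.lcd) <= px_um
            assert abs(morph.lccd - truth.lccd) <= px_um
            assert abs(morph.width - truth.width) <= px_um
            assert abs(morph.lcci - truth.lcci) <= 0.1

    def test_flat_phantom_degenerates_cleanly(self):
        spec = PhantomSpec.create(depth_left=85, depth_right=85, sag=0.0)
        scene = generate_phantom(spec)
        curve = fit_lc_curve(scene.lc_boundary)
        morph = quantify_all(scene.bmo, curve, 4.0)
        assert morph.lcd == pytest.approx(85 * 4.0, abs=2.0)
        assert morph.lccd == pytest.approx(0.0, abs=1.0)
        assert morph.lcci == pytest.approx(0.0, abs=0.05)

    def test_uniform_scale_change_fixes_lcci(self, default_scene):
        curve = fit_lc_curve(default_scene.lc_boundary)
        m1 = quantify_all(default_scene.bmo, curve, 4.0)
        m2 = quantify_all(default_scene.bmo, curve, 8.0)
        assert m2.lcd == pytest.approx(2 * m1.lcd, rel=1e-9)
        assert m2.width == pytest.approx(2 * m1.width, rel=1e-9)
        assert m2.lcci == pytest.approx(m1.lcci, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        """Rotating the whole analytic scene changes each output < 0.5%."""
        base = dict(depth_left=90.0, depth_right=90.0, sag=12.0)
        spec = PhantomSpec.create(**base)
        truth = analytic_morphometry(spec)
        # rotate BMO points and curve samples by 3 degrees about the center
        theta = np.deg2rad(3.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        center = np.array([380.0, 250.0])
        xs = np.arange(*spec.lc_x_range)
        pts = np.column_stack([xs, np.asarray(spec.curve_y(xs))])
        rot_pts = (pts - center) @ rot.T + center
        curve = fit_lc_curve(rot_pts, degree=4, ridge_lambda=0.0)
        left = tuple((np.array(spec.bmo_left) - center) @ rot.T + center)
        right = tuple((np.array(spec.bmo_right) - center) @ rot.T + center)
        morph = quantify_all(BMOPair(left, right), curve, 4.0)
        assert morph.lcd == pytest.approx(truth.lcd, rel=0.005)
        assert morph.lccd == pytest.approx(truth.lccd, rel=0.005, abs=0.5)
        assert morph.width == pytest.approx(truth.width, rel=0.005)
        assert morph.lcci == pytest.approx(truth.lcci, abs=0.05)

    def test_all_outputs_non_negative_and_lcci_bounded(self, small_cohort):
        for spec, scene, _ in small_cohort:
            curve = fit_lc_curve(scene.lc_boundary)
            m = quantify_all(scene.bmo, curve, spec.microns_per_pixel)
            assert min(m.lcd, m.lccd, m.width) >= 0
            assert 0 <= m.lcci <= 100
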