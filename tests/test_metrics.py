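"""Normalized printing-accuracy metrics on synthetic structures."""

import numpy as np
import pytest

from printability.imaging import BinaryStructureImage, binarize, segment
from printability.metrics import (
    CadTarget,
    analyze_angle,
    analyze_circle,
    analyze_line,
    fit_circle,
)
from printability.synthetic import RenderSpec, render_structure
from printability.workflow import analyze_structure_image

from conftest import disc_mask


class TestLine:
    def test_ideal_print_scores_one(self, line_components):
        m = analyze_line(line_components, CadTarget(kind="line"))
        assert m.normalized_width == pytest.approx(1.0, abs=0.05)
        assert m.normalized_length == pytest.approx(1.0, abs=0.01)
        assert m.segment_count == 1
        assert not m.interrupted

    def test_wide_short_print(self):
        # 1.5x stroke, 95% length: the metrics report exactly those ratios
        spec = RenderSpec(
            cad=CadTarget(kind="line"), seed=21, stroke_width=0.915, gaps=((28.5, 1.5),)
        )
        img, truth = render_structure(spec)
        m = analyze_line(segment(binarize(img)), CadTarget(kind="line"))
        assert m.normalized_width == pytest.approx(0.915 / 0.61, abs=0.05)
        assert m.normalized_length == pytest.approx(truth.covered_length_mm / 30.0, abs=0.01)

    def test_gap_marks_interrupted(self):
        spec = RenderSpec(cad=CadTarget(kind="line"), seed=22, gaps=((13.0, 2.0),))
        img, _ = render_structure(spec)
        m = analyze_line(segment(binarize(img)), CadTarget(kind="line"))
        assert m.interrupted
        assert m.segment_count == 2

    def test_width_equals_area_over_length_on_rectangle(self):
        # cross-section counting against the area/length oracle on an exact bar
        ppm = 52.0
        mask = np.zeros((200, 1700), dtype=bool)
        mask[90:122, 50:1610] = True  # 32 px x 1560 px = 0.615 mm x 30 mm
        comps = segment(BinaryStructureImage(mask=mask, px_per_mm=ppm))
        m = analyze_line(comps, CadTarget(kind="line"))
        oracle = comps.largest.area_mm2 / (1560 / ppm)
        assert m.width == pytest.approx(oracle, rel=0.02)


class TestCircle:
    def test_ideal_print_scores_one(self, circle_components):
        m = analyze_circle(circle_components, CadTarget(kind="circle"))
        assert m.normalized_radii == pytest.approx(1.0, abs=0.005)
        assert m.normalized_width == pytest.approx(1.0, abs=0.05)
        # symmetric stroke: r_i and r_o straddle the 15 mm midline by w/2
        assert m.inner_radius == pytest.approx(15.0 - 0.305, abs=0.05)
        assert m.outer_radius == pytest.approx(15.0 + 0.305, abs=0.05)

    def test_displaced_midline_shows_in_normalized_radii(self):
        # a ring printed at 15.3 mm instead of 15 mm scores (14.995+15.605)/30
        spec = RenderSpec(cad=CadTarget(kind="circle", circle_radius=15.3), seed=23)
        img, _ = render_structure(spec)
        m = analyze_circle(segment(binarize(img)), CadTarget(kind="circle"))
        assert m.normalized_radii == pytest.approx(15.3 / 15.0, abs=0.005)

    def test_wide_stroke_keeps_radii_score_at_one(self):
        spec = RenderSpec(cad=CadTarget(kind="circle"), seed=24, stroke_width=0.915)
        img, _ = render_structure(spec)
        m = analyze_circle(segment(binarize(img)), CadTarget(kind="circle"))
        assert m.normalized_width == pytest.approx(1.5, abs=0.05)
        assert m.normalized_radii == pytest.approx(1.0, abs=0.002)

    def test_marker_angle_recovered(self):
        spec = RenderSpec(cad=CadTarget(kind="circle"), seed=25, marker_angle=40.0, rotation=20.0)
        img, truth = render_structure(spec)
        m = analyze_circle(segment(binarize(img)), CadTarget(kind="circle"))
        got = m.start_marker_angle % 360.0
        assert min(abs(got - truth.marker_angle_deg), 360 - abs(got - truth.marker_angle_deg)) < 3.0

    def test_solid_disc_is_not_a_ring(self):
        mask = disc_mask((400, 400), (200, 200), 150)
        comps = segment(BinaryStructureImage(mask=mask, px_per_mm=52.0))
        with pytest.raises(ValueError, match="no ring detected"):
            analyze_circle(comps, CadTarget(kind="circle"))

    def test_fit_circle_exact_on_sampled_points(self):
        t = np.linspace(0, 1.4 * np.pi, 100)  # partial arc
        pts = np.column_stack([3.0 + 7.5 * np.cos(t), -2.0 + 7.5 * np.sin(t)])
        cx, cy, r = fit_circle(pts)
        assert (cx, cy, r) == pytest.approx((3.0, -2.0, 7.5), abs=1e-9)


class TestAngle:
    def test_ideal_print_scores_one(self, angle_components):
        m = analyze_angle(angle_components, CadTarget(kind="angle"))
        assert [v.designed for v in m.vertices] == [30.0, 45.0, 60.0]
        for v in m.vertices:
            assert v.normalized == pytest.approx(1.0, abs=0.03)
        assert m.normalized_width == pytest.approx(1.0, abs=0.05)
        assert len(m.widths) == 5

    def test_vertex_count_mismatch_raises(self, angle_components):
        cad = CadTarget(kind="angle", designed_angles=(30.0, 45.0, 60.0, 75.0))
        with pytest.raises(ValueError, match="structure/CAD mismatch"):
            analyze_angle(angle_components, cad)

    def test_normalization_combines_inner_and_outer(self, angle_components):
        # a_n = (a_i + a_o) / (2 a_model) for every vertex
        m = analyze_angle(angle_components, CadTarget(kind="angle"))
        for v in m.vertices:
            assert v.normalized == pytest.approx((v.inner + v.outer) / (2 * v.designed))


class TestInvariances:
    @pytest.mark.parametrize("kind", ["line", "angle"])
    def test_scale_invariance(self, kind):
        # halving/doubling the pixel pitch moves normalized scores < 1%
        cad = CadTarget(kind=kind, line_length=15.0)
        scores = {}
        for ppm in (52.0, 104.0):
            spec = RenderSpec(cad=cad, seed=26, px_per_mm=ppm, angle_arm_length=7.0)
            img, _ = render_structure(spec)
            rec = analyze_structure_image(img, cad)
            scores[ppm] = rec
        for key in ("w_n", "l_n", "a_n_30", "a_n_45", "a_n_60"):
            if key in scores[52.0]:
                assert scores[104.0][key] == pytest.approx(scores[52.0][key], abs=0.01)

    def test_scale_invariance_circle(self):
        cad = CadTarget(kind="circle")
        scores = {}
        for ppm in (26.0, 52.0):
            img, _ = render_structure(RenderSpec(cad=cad, seed=27, px_per_mm=ppm))
            scores[ppm] = analyze_structure_image(img, cad)
        assert scores[26.0]["r_n"] == pytest.approx(scores[52.0]["r_n"], abs=0.005)
        assert scores[26.0]["w_n"] == pytest.approx(scores[52.0]["w_n"], abs=0.02)

    @pytest.mark.parametrize("kind", ["line", "circle", "angle"])
    def test_rotation_invariance(self, kind):
        cad = CadTarget(kind=kind)
        recs = []
        for rot in (0.0, 28.0):
            img, _ = render_structure(RenderSpec(cad=cad, seed=28, rotation=rot))
            recs.append(analyze_structure_image(img, cad))
        for key in ("w_n", "l_n", "r_n", "a_n_30", "a_n_45", "a_n_60"):
            if key in recs[0]:
                assert recs[1][key] == pytest.approx(recs[0][key], abs=0.02)

    @pytest.mark.parametrize("stroke", [0.45, 0.8, 1.2])
    def test_width_recovery_across_strokes(self, stroke):
        # estimated width within 2 px equivalent (~0.04 mm at 52 px/mm)
        spec = RenderSpec(cad=CadTarget(kind="line"), seed=29, stroke_width=stroke)
        img, truth = render_structure(spec)
        m = analyze_line(segment(binarize(img)), CadTarget(kind="line"))
        assert abs(m.width - truth.stroke_width_mm) <= 2.0 / 52.0
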