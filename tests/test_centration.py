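"""Calibration, anatomic-frame conversion, distances, quadrants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iclcentration import (
    CentrationRecord,
    EllipseParams,
    InputError,
    RenderConfig,
    SegmentationResult,
    calibrate,
    classify_quadrant,
    compute_distances,
    process_eye,
    render_eye,
    to_anatomic_frame,
)

from conftest import make_eye


def ellipse_at(x, y, a=10.0, b=8.0):
    return EllipseParams(center_px=(x, y), semi_axes_px=(a, b), rotation_rad=0.0)


def seg_with_centers(limbus_xy, pupil_xy, hole_xy):
    return SegmentationResult(
        limbus=ellipse_at(*limbus_xy, a=107.0, b=101.0),
        pupil=ellipse_at(*pupil_xy, a=26.0, b=25.0),
        hole=ellipse_at(*hole_xy, a=3.75, b=3.75),
        flags={},
    )


class TestCalibration:
    def test_wtw_magnification(self):
        """WTW 10.28 mm over 214.23 px gives 0.04799 mm/px."""
        cal = calibrate(ellipse_at(0, 0, a=214.23 / 2, b=100.0), None, wtw_mm=10.28)
        assert cal.magnification_mm_per_px == pytest.approx(0.04799, abs=1e-5)

    def test_hole_norm_gives_360_um(self):
        limbus = ellipse_at(0, 0, a=214.23 / 2, b=100.0)
        hole = ellipse_at(0, 0, a=3.75, b=3.75)
        cal = calibrate(limbus, hole, wtw_mm=10.28)
        assert cal.hole_norm_px == pytest.approx(7.5)
        assert cal.px_to_mm(cal.hole_norm_px) == pytest.approx(0.360, abs=0.001)

    def test_identity_scale(self):
        cal = calibrate(ellipse_at(0, 0, a=5.0, b=4.0), None, wtw_mm=10.0)
        assert cal.magnification_mm_per_px == pytest.approx(1.0)

    @pytest.mark.parametrize("wtw", [8.0, 15.0])
    def test_wtw_out_of_range(self, wtw):
        with pytest.raises(InputError):
            calibrate(ellipse_at(0, 0), None, wtw_mm=wtw)


class TestAnatomicFrame:
    def test_coincident_centers_map_to_origin(self):
        seg = seg_with_centers((160, 160), (160, 160), (160, 160))
        cal = calibrate(seg.limbus, seg.hole, wtw_mm=10.28)
        rec = to_anatomic_frame(seg, cal, "OD")
        assert rec.x_hole_mm == 0 and rec.y_hole_mm == 0

    def test_os_mirror_rule(self):
        """An OS raster offset (+d, 0) maps to the negated OD x, same y."""
        seg = seg_with_centers((160, 160), (170, 150), (165, 155))
        cal = calibrate(seg.limbus, seg.hole, wtw_mm=10.28)
        od = to_anatomic_frame(seg, cal, "OD")
        os_ = to_anatomic_frame(seg, cal, "OS")
        assert os_.x_hole_mm == pytest.approx(-od.x_hole_mm)
        assert os_.y_hole_mm == pytest.approx(od.y_hole_mm)

    def test_raster_y_down_is_inferior(self):
        seg = seg_with_centers((160, 160), (160, 170), (160, 150))
        cal = calibrate(seg.limbus, seg.hole, wtw_mm=10.28)
        rec = to_anatomic_frame(seg, cal, "OD")
        assert rec.y_pupil_mm < 0  # raster below center = inferior
        assert rec.y_hole_mm > 0

    def test_end_to_end_ground_truth_recovery(self, clean_render_cfg):
        """A hole placed 0.10 mm nasal / 0.30 mm superior is recovered within 0.02 mm."""
        geom = make_eye(hole_center_mm=(0.10, 0.30))
        img, _ = render_eye(geom, clean_render_cfg)
        rec = process_eye(img, wtw_mm=geom.wtw_mm, laterality="OD")
        assert rec.x_hole_mm == pytest.approx(0.10, abs=0.02)
        assert rec.y_hole_mm == pytest.approx(0.30, abs=0.02)


class TestDistances:
    def test_coincident_all_zero(self):
        rec = compute_distances(CentrationRecord("e", "OD", 0, 0, 0, 0))
        assert rec.d_hc_mm == rec.d_pc_mm == rec.d_hp_mm == 0

    def test_three_four_five(self):
        rec = compute_distances(CentrationRecord("e", "OD", 0.3, 0.4, 0.0, 0.0))
        assert rec.d_hc_mm == pytest.approx(0.5)
        assert rec.d_hp_mm == pytest.approx(0.5)
        assert rec.d_pc_mm == 0

    def test_printed_component_distance(self):
        """Hole offset (0.16, 0.30) mm lies 0.3400 mm from the corneal center."""
        rec = compute_distances(CentrationRecord("e", "OD", 0.16, 0.30, 0.0, 0.0))
        assert rec.d_hc_mm == pytest.approx(math.hypot(0.16, 0.30), abs=1e-12)
        assert rec.d_hc_mm == pytest.approx(0.3400, abs=5e-5)

    @settings(max_examples=100, derandomize=True)
    @given(
        xh=st.floats(-1, 1), yh=st.floats(-1, 1),
        xp=st.floats(-1, 1), yp=st.floats(-1, 1),
    )
    def test_distance_identities(self, xh, yh, xp, yp):
        """D = sqrt(x^2+y^2) for every vector; magnitudes are |components|;
        the hole-pupil distance obeys the triangle inequality."""
        rec = compute_distances(CentrationRecord("e", "OD", xh, yh, xp, yp))
        assert rec.d_hc_mm == pytest.approx(math.hypot(xh, yh), abs=1e-12)
        assert rec.d_pc_mm == pytest.approx(math.hypot(xp, yp), abs=1e-12)
        assert rec.d_hp_mm == pytest.approx(math.hypot(xh - xp, yh - yp), abs=1e-12)
        assert rec.dhx_mm == abs(xh) and rec.dpy_mm == abs(yp)
        assert rec.d_hp_mm <= rec.d_hc_mm + rec.d_pc_mm + 1e-12

    def test_triangle_equality_iff_collinear(self):
        rec = compute_distances(CentrationRecord("e", "OD", 0.6, 0.0, -0.2, 0.0))
        assert rec.d_hp_mm == pytest.approx(rec.d_hc_mm + rec.d_pc_mm, abs=1e-12)

    def test_missing_coordinates_rejected(self):
        with pytest.raises(InputError):
            compute_distances(CentrationRecord("e", "OD", math.nan, 0, 0, 0))


class TestQuadrants:
    @pytest.mark.parametrize(
        "vec, label",
        [
            ((0.1, 0.2), "superior-nasal"),
            ((-0.1, 0.2), "superior-temporal"),
            ((0.1, -0.2), "inferior-nasal"),
            ((-0.1, -0.2), "inferior-temporal"),
        ],
    )
    def test_sign_reading(self, vec, label):
        got, boundary = classify_quadrant(vec)
        assert got == label and not boundary

    def test_zero_vector_is_flagged_boundary(self):
        label, boundary = classify_quadrant((0.0, 0.0))
        assert label == "superior-nasal" and boundary

    def test_axis_cases_flagged(self):
        assert classify_quadrant((0.0, -0.5)) == ("inferior-nasal", True)
        assert classify_quadrant((-0.5, 0.0)) == ("superior-temporal", True)


class TestPipelineInvariances:
    def test_mirror_invariance_full_pipeline(self, clean_render_cfg):
        """OS and OD renders of the same geometry yield the same record."""
        geom = make_eye(laterality="OD")
        img_od, _ = render_eye(geom, clean_render_cfg)
        img_os, _ = render_eye(dataclasses.replace(geom, laterality="OS"), clean_render_cfg)
        rod = process_eye(img_od, wtw_mm=geom.wtw_mm, laterality="OD")
        ros = process_eye(img_os, wtw_mm=geom.wtw_mm, laterality="OS")
        for attr in ("x_hole_mm", "y_hole_mm", "x_pupil_mm", "y_pupil_mm", "d_hc_mm"):
            assert getattr(ros, attr) == pytest.approx(getattr(rod, attr), abs=0.05)

    def test_scale_invariance_24_vs_48_um_per_px(self, sample_eye):
        """Rendering at double resolution changes no mm output by > 0.02 mm."""
        img48, _ = render_eye(sample_eye, RenderConfig(seed=0))
        img24, _ = render_eye(
            sample_eye, RenderConfig(scale_um_per_px=24.0, width=640, height=640, seed=0)
        )
        r48 = process_eye(img48, wtw_mm=sample_eye.wtw_mm, laterality=sample_eye.laterality)
        r24 = process_eye(img24, wtw_mm=sample_eye.wtw_mm, laterality=sample_eye.laterality)
        for attr in ("x_hole_mm", "y_hole_mm", "x_pupil_mm", "y_pupil_mm",
                     "d_hc_mm", "d_pc_mm", "d_hp_mm"):
            assert abs(getattr(r48, attr) - getattr(r24, attr)) <= 0.02, attr
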