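"""Geometric core: reference frame, depths, clipping, areas, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcindex.geometry import (
    AnteriorInsertionWarning,
    BScanAnnotation,
    DegenerateGeometryError,
    OutOfSpanError,
    Point2D,
    aggregate_eye,
    build_reference_frame,
    clip_polyline,
    compute_alid,
    compute_area_S,
    compute_scan_morphometry,
)

from conftest import annotation_from_profile, rigid_transform


class TestReferenceFrame:
    def test_axis_aligned(self):
        f = build_reference_frame([Point2D(0, 0), Point2D(1500, 0)])
        assert np.allclose(f.axis, [1, 0])
        assert np.allclose(f.normal, [0, 1])

    def test_tilted_axis_is_unit_and_orthogonal(self):
        f = build_reference_frame([Point2D(0, 0), Point2D(1500, 150)])
        assert np.allclose(f.axis, np.array([1500, 150]) / np.hypot(1500, 150))
        assert abs(f.axis @ f.normal) < 1e-12
        assert np.isclose(np.hypot(*f.normal), 1.0)
        assert f.normal[1] > 0  # posterior orientation

    def test_coincident_bmo_raises(self):
        with pytest.raises(DegenerateGeometryError):
            build_reference_frame([Point2D(0, 0), Point2D(0, 0)])


class TestDepthOfPoint:
    def test_point_on_line_has_zero_depth(self):
        from lcindex.geometry import depth_of_point

        f = build_reference_frame([Point2D(0, 0), Point2D(1500, 150)])
        _, d = depth_of_point(Point2D(750, 75), f)
        assert abs(d) < 1e-9

    def test_identity_rotation(self):
        from lcindex.geometry import depth_of_point

        f = build_reference_frame([Point2D(0, 0), Point2D(1500, 0)])
        assert depth_of_point(Point2D(500, 300), f) == pytest.approx((500, 300))

    def test_tilted_depth_matches_point_line_distance(self):
        # independent oracle: |cross((b-a), (p-a))| / |b-a|
        from lcindex.geometry import depth_of_point

        a, b, p = np.array([10.0, -5.0]), np.array([1400.0, 220.0]), np.array([600.0, 400.0])
        f = build_reference_frame([Point2D(*a), Point2D(*b)])
        _, d = depth_of_point(Point2D(*p), f)
        u, v = b - a, p - a
        oracle = abs(u[0] * v[1] - u[1] * v[0]) / np.linalg.norm(u)
        assert d == pytest.approx(oracle, abs=1e-9)


class TestAlid:
    def test_equal_depths(self):
        ann = annotation_from_profile([0, 1500], [300, 300])
        assert compute_alid(ann) == pytest.approx((300, 300, 300))

    def test_tilt_invariance_of_mean(self):
        ann = annotation_from_profile([0, 1500], [200, 400])
        tilted = rigid_transform(ann, 10.0, 0.0, 0.0)
        assert compute_alid(tilted)[2] == pytest.approx(300.0, abs=1e-9)

    def test_anterior_ali_warns_with_negative_depth(self):
        ann = annotation_from_profile([0, 1500], [-50, 300], ali_depths=(-50, 300))
        with pytest.warns(AnteriorInsertionWarning):
            d1, _, _ = compute_alid(ann)
        assert d1 == pytest.approx(-50.0)


class TestClipPolyline:
    def test_exact_span_unchanged(self):
        lc = np.column_stack([np.linspace(0, 1200, 5), np.full(5, 300.0)])
        out = clip_polyline(lc, 0.0, 1200.0)
        assert np.allclose(out, lc)

    def test_vertex_at_clip_abscissa_not_duplicated(self):
        lc = np.column_stack([np.array([0, 100, 600, 1300, 1500]), np.full(5, 300.0)])
        out = clip_polyline(lc, 100.0, 1300.0)
        assert np.allclose(out[:, 0], [100, 600, 1300])

    def test_span_gives_D(self):
        lc = np.column_stack([np.linspace(0, 1500, 50), np.full(50, 250.0)])
        out = clip_polyline(lc, 100.0, 1300.0)
        assert out[-1, 0] - out[0, 0] == pytest.approx(1200.0)

    def test_out_of_span_names_side(self):
        lc = np.column_stack([np.linspace(200, 1000, 5), np.full(5, 300.0)])
        with pytest.raises(OutOfSpanError, match="first"):
            clip_polyline(lc, 100.0, 900.0)


class TestAreaS:
    def test_rectangle(self):
        lc = np.column_stack([np.linspace(0, 1200, 7), np.full(7, 300.0)])
        assert compute_area_S(lc) == pytest.approx(360_000.0)

    def test_trapezoid(self):
        lc = np.column_stack([np.linspace(0, 1000, 100), np.linspace(200, 400, 100)])
        assert compute_area_S(lc) == pytest.approx(300_000.0)

    def test_parabola_against_dense_quadrature(self):
        D, h = 1500.0, 150.0
        t = np.linspace(0, D, 200)
        chord = 300.0
        depth = chord + h * (1 - (2 * t / D - 1) ** 2)
        S = compute_area_S(np.column_stack([t, depth]))
        tq = np.linspace(0, D, 100_001)
        oracle = np.trapezoid(chord + h * (1 - (2 * tq / D - 1) ** 2), tq)
        assert S == pytest.approx(oracle, rel=1e-4)


class TestScanMorphometry:
    def test_flat_slanted_chord_has_zero_index(self):
        t = np.linspace(0, 1400, 80)
        depth = np.linspace(180, 420, 80)  # flat LC exactly on the slanted chord
        m = compute_scan_morphometry(annotation_from_profile(t, depth))
        assert m.curvature_index == pytest.approx(0.0, abs=1e-9)

    def test_internal_identities(self, parabolic_annotation):
        m = compute_scan_morphometry(parabolic_annotation)
        assert m.mlcd == pytest.approx(m.S / m.D, abs=1e-9)
        assert m.curvature_index == pytest.approx(m.mlcd - m.mean_alid, abs=1e-9)
        assert m.D > 0

    def test_strict_vertical_equals_perpendicular_when_untilted(self, parabolic_annotation):
        a = compute_scan_morphometry(parabolic_annotation)
        b = compute_scan_morphometry(parabolic_annotation, strict_vertical=True)
        assert a.curvature_index == pytest.approx(b.curvature_index, abs=1e-9)

    def test_strict_vertical_differs_under_tilt(self, parabolic_annotation):
        tilted = rigid_transform(parabolic_annotation, 12.0, 0.0, 0.0)
        perp = compute_scan_morphometry(tilted)
        strict = compute_scan_morphometry(tilted, strict_vertical=True)
        assert perp.curvature_index != pytest.approx(strict.curvature_index, abs=0.1)

    def test_non_monotone_polyline_rejected(self):
        pts = [Point2D(0, 300), Point2D(800, 350), Point2D(400, 360), Point2D(1500, 300)]
        ann = BScanAnnotation(
            scan_id="bad",
            meridian="horizontal",
            bmo=(Point2D(0, 0), Point2D(1500, 0)),
            ali=(Point2D(0, 300), Point2D(1500, 300)),
            anterior_lc=tuple(pts),
        )
        with pytest.raises(DegenerateGeometryError, match="monotone"):
            compute_scan_morphometry(ann)


class TestAggregateEye:
    @staticmethod
    def _scan(index, meridian="horizontal", alid=300.0):
        from lcindex.geometry import ScanMorphometry

        return ScanMorphometry(
            scan_id="s",
            meridian=meridian,
            alid_side1=alid,
            alid_side2=alid,
            mean_alid=alid,
            D=1500.0,
            S=(alid + index) * 1500.0,
            mlcd=alid + index,
            curvature_index=index,
        )

    def test_identical_scans(self):
        eye = aggregate_eye("E", [self._scan(50.0)] * 3)
        assert eye.horizontal_index == pytest.approx(50.0)
        assert eye.n_scans_horizontal == 3

    def test_mean_of_three(self):
        eye = aggregate_eye("E", [self._scan(40.0), self._scan(50.0), self._scan(60.0)])
        assert eye.horizontal_index == pytest.approx(50.0)

    def test_overall_is_meridian_mean(self):
        scans = [self._scan(68.2, "horizontal"), self._scan(32.2, "vertical")]
        eye = aggregate_eye("E", scans)
        assert eye.overall_index == pytest.approx(50.2)

    def test_missing_meridian_leaves_overall_absent(self):
        eye = aggregate_eye("E", [self._scan(50.0, "horizontal")])
        assert eye.vertical_index is None
        assert eye.overall_index is None

    def test_empty_eye_raises(self):
        with pytest.raises(DegenerateGeometryError):
            aggregate_eye("E", [])


# ---------------------------------------------------------------------------
# invariance properties


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    angle=st.floats(-60, 60),
    dx=st.floats(-5000, 5000),
    dy=st.floats(-5000, 5000),
    seed=st.integers(0, 10_000),
)
def test_rigid_motion_invariance(angle, dx, dy, seed):
    """Translating/rotating the whole annotation changes no morphometry field."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1500, 60)
    depth = 300 + rng.normal(0, 40, size=60)
    ann = annotation_from_profile(t, depth)
    m0 = compute_scan_morphometry(ann)
    m1 = compute_scan_morphometry(rigid_transform(ann, angle, dx, dy))
    for f in ("alid_side1", "alid_side2", "mean_alid", "D", "mlcd", "curvature_index"):
        assert getattr(m1, f) == pytest.approx(getattr(m0, f), abs=1e-6)
    assert m1.S == pytest.approx(m0.S, abs=1e-3)  # μm² field scales with D


@settings(max_examples=30, deadline=None, derandomize=True)
@given(a=st.floats(-300, 300), b=st.floats(-0.3, 0.3), seed=st.integers(0, 10_000))
def test_chord_shift_invariance(a, b, seed):
    """A linear-in-t depth trend added to LC and ALI moves ALID and mLCD
    equally and leaves the curvature index unchanged."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1500, 60)
    depth = 300 + rng.normal(0, 40, size=60)
    ann0 = annotation_from_profile(t, depth)
    ann1 = annotation_from_profile(t, depth + a + b * t)
    m0, m1 = compute_scan_morphometry(ann0), compute_scan_morphometry(ann1)
    shift = m1.mean_alid - m0.mean_alid
    assert m1.mlcd - m0.mlcd == pytest.approx(shift, abs=1e-6)
    assert m1.curvature_index == pytest.approx(m0.curvature_index, abs=1e-6)


@pytest.mark.parametrize("c", [0.5, 2.0, 3.87])
def test_scale_equivariance(c, parabolic_annotation):
    """pixel_scale × c scales lengths by c and area by c²."""
    ann = parabolic_annotation
    scaled = BScanAnnotation(
        scan_id=ann.scan_id,
        meridian=ann.meridian,
        bmo=ann.bmo,
        ali=ann.ali,
        anterior_lc=ann.anterior_lc,
        pixel_scale=c,
    )
    m0, m1 = compute_scan_morphometry(ann), compute_scan_morphometry(scaled)
    assert m1.mean_alid == pytest.approx(c * m0.mean_alid)
    assert m1.mlcd == pytest.approx(c * m0.mlcd)
    assert m1.curvature_index == pytest.approx(c * m0.curvature_index)
    assert m1.S == pytest.approx(c**2 * m0.S)
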