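import numpy as np
import pytest

from lcindex.geometry import BScanAnnotation, Point2D


def annotation_from_profile(
    t, depth, ali_depths=None, meridian="horizontal", scan_id="fixture", pixel_scale=1.0
):
    """Annotation with an axis-aligned BMO line along y=0 and a polyline at
    the given frame coordinates; ALI points sit at the polyline's ends
    unless explicit depths are given."""
    t = np.asarray(t, float)
    depth = np.asarray(depth, float)
    if ali_depths is None:
        ali_depths = (depth[0], depth[-1])
    return BScanAnnotation(
        scan_id=scan_id,
        meridian=meridian,
        bmo=(Point2D(t[0], 0.0), Point2D(t[-1], 0.0)),
        ali=(Point2D(t[0], ali_depths[0]), Point2D(t[-1], ali_depths[1])),
        anterior_lc=tuple(Point2D(x, y) for x, y in zip(t, depth)),
        pixel_scale=pixel_scale,
    )


def rigid_transform(ann: BScanAnnotation, angle_deg: float, dx: float, dy: float):
    """Rotate about the origin then translate every annotated point."""
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    R = np.array([[c, -s], [s, c]])

    def f(p: Point2D) -> Point2D:
        x, y = R @ p.as_array()
        return Point2D(x + dx, y + dy)

    return BScanAnnotation(
        scan_id=ann.scan_id,
        meridian=ann.meridian,
        bmo=tuple(f(p) for p in ann.bmo),
        ali=tuple(f(p) for p in ann.ali),
        anterior_lc=tuple(f(p) for p in ann.anterior_lc),
        pixel_scale=ann.pixel_scale,
    )


@pytest.fixture
def parabolic_annotation():
    """U-shaped profile: chord at 300 μm, bowing amplitude 150 μm, D=1500."""
    t = np.linspace(0.0, 1500.0, 200)
    u = 2 * t / 1500.0 - 1.0
    depth = 300.0 + 150.0 * (1 - u * u)
    return annotation_from_profile(t, depth)
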