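"""Lamina cribrosa morphometry from annotated OCT B-scan geometry.

The measurements quantify posterior bowing of the lamina cribrosa (LC)
relative to the Bruch's membrane opening (BMO) reference plane on a single
optic-nerve-head B-scan:

* **ALID** — anterior laminar insertion depth: depth of each anterior
  laminar insertion (ALI) point below the BMO reference line; the per-scan
  ALID is the mean of the two sides.
* **D** — lateral span between the feet of the perpendiculars dropped from
  the two ALI points onto the BMO line.
* **S** — signed area enclosed by the anterior LC surface, the BMO
  reference line and the two bounding perpendiculars.
* **mLCD** — mean LC depth, ``S / D``.
* **LC curvature index** — ``mLCD − mean ALID``: the average posterior
  deviation of the LC surface from its own insertion level.  Because both
  terms are referenced to the same BMO line, the index is invariant to a
  uniform depth offset (choroidal/BMO position) and, by construction here,
  to rigid motion of the whole annotation.

All coordinates are micrometres with the axial (y) axis increasing
posteriorly.  Depths are signed: posterior to the BMO line is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Point2D",
    "BScanAnnotation",
    "ReferenceFrame",
    "ScanMorphometry",
    "EyeMorphometry",
    "DegenerateGeometryError",
    "OutOfSpanError",
    "AnteriorInsertionWarning",
    "build_reference_frame",
    "depth_of_point",
    "compute_alid",
    "clip_polyline",
    "compute_area_S",
    "compute_scan_morphometry",
    "aggregate_eye",
]

Meridian = Literal["horizontal", "vertical"]

#: absolute tolerance (μm) for geometric equality checks
TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when an annotation's geometry admits no measurement."""


class OutOfSpanError(ValueError):
    """Raised when an ALI projects outside the anterior-LC polyline span."""


class AnteriorInsertionWarning(UserWarning):
    """An ALI point lies anterior to the BMO reference line (negative depth)."""


@dataclass(frozen=True)
class Point2D:
    """A point in the B-scan plane (μm; y increases posteriorly)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_points(seq: Sequence[Point2D | Sequence[float]]) -> tuple[Point2D, ...]:
    out = []
    for p in seq:
        out.append(p if isinstance(p, Point2D) else Point2D(float(p[0]), float(p[1])))
    return tuple(out)


@dataclass(frozen=True)
class BScanAnnotation:
    """One B-scan's manual annotation.

    ``bmo`` and ``ali`` are ordered pairs with matching side order
    (temporal/nasal on horizontal scans, superior/inferior on vertical
    scans).  ``anterior_lc`` is the ordered anterior-LC-surface polyline.
    Coordinates may be pixels; ``pixel_scale`` (μm/pixel) converts them, and
    is 1.0 when coordinates are already micrometres.
    """

    scan_id: str
    meridian: Meridian
    bmo: tuple[Point2D, Point2D]
    ali: tuple[Point2D, Point2D]
    anterior_lc: tuple[Point2D, ...]
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bmo", _as_points(self.bmo))
        object.__setattr__(self, "ali", _as_points(self.ali))
        object.__setattr__(self, "anterior_lc", _as_points(self.anterior_lc))
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if len(self.bmo) != 2 or len(self.ali) != 2:
            raise ValueError("bmo and ali must each contain exactly two points")
        if len(self.anterior_lc) < 2:
            raise ValueError("anterior_lc polyline needs at least two points")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if np.allclose(self.bmo[0].as_array(), self.bmo[1].as_array()):
            raise DegenerateGeometryError("BMO points coincide")
        if np.allclose(self.ali[0].as_array(), self.ali[1].as_array()):
            raise DegenerateGeometryError("ALI points coincide")

    # -- μm views -----------------------------------------------------------
    def bmo_um(self) -> np.ndarray:
        return np.array([p.as_array() for p in self.bmo]) * self.pixel_scale

    def ali_um(self) -> np.ndarray:
        return np.array([p.as_array() for p in self.ali]) * self.pixel_scale

    def anterior_lc_um(self) -> np.ndarray:
        return np.array([p.as_array() for p in self.anterior_lc]) * self.pixel_scale


@dataclass(frozen=True)
class ReferenceFrame:
    """BMO reference frame: origin at the first BMO point, axis along the
    BMO line, normal perpendicular and oriented posteriorly."""

    origin: np.ndarray
    axis: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class ScanMorphometry:
    """Per-scan LC morphometry (all lengths μm, area μm²)."""

    scan_id: str
    meridian: Meridian
    alid_side1: float
    alid_side2: float
    mean_alid: float
    D: float
    S: float
    mlcd: float
    curvature_index: float


@dataclass(frozen=True)
class EyeMorphometry:
    """Per-eye morphometry: meridian means over gradable scans plus the
    overall LC curvature index (mean of the two meridian indices)."""

    eye_id: str
    horizontal_alid: float | None
    vertical_alid: float | None
    horizontal_mlcd: float | None
    vertical_mlcd: float | None
    horizontal_index: float | None
    vertical_index: float | None
    overall_index: float | None
    n_scans_horizontal: int
    n_scans_vertical: int


# ---------------------------------------------------------------------------
# frame construction and projection


def build_reference_frame(bmo: Sequence[Point2D | Sequence[float]]) -> ReferenceFrame:
    """Reference frame of the line connecting the two BMO points.

    The axis runs from the first to the second BMO point; the normal is
    the perpendicular oriented so that posterior points (larger y) have
    positive depth.
    """
    p0, p1 = (_as_points(bmo))
    a, b = p0.as_array(), p1.as_array()
    v = b - a
    norm = float(np.hypot(*v))
    if norm < TOL:
        raise DegenerateGeometryError("BMO points coincide; no reference line")
    axis = v / norm
    normal = np.array([-axis[1], axis[0]])
    if normal[1] < 0:  # orient toward increasing y (posterior)
        normal = -normal
    return ReferenceFrame(origin=a, axis=axis, normal=normal)


def depth_of_point(
    p: Point2D | Sequence[float], frame: ReferenceFrame
) -> tuple[float, float]:
    """Coordinates of ``p`` in the BMO frame: ``t`` μm along the axis from
    the frame origin, ``d`` μm signed depth (positive posterior)."""
    q = (p.as_array() if isinstance(p, Point2D) else np.asarray(p, float)) - frame.origin
    return float(q @ frame.axis), float(q @ frame.normal)


def _project(points: np.ndarray, frame: ReferenceFrame) -> np.ndarray:
    """Rotate an (n, 2) array of xy points into (t, d) frame coordinates."""
    q = points - frame.origin
    return np.column_stack([q @ frame.axis, q @ frame.normal])


def _strict_vertical_frame(bmo_um: np.ndarray) -> ReferenceFrame:
    """Frame for strict image-vertical depths: t is the raw image x
    coordinate and d the vertical (image-column) distance below the BMO
    line.  Shears rather than rotates, so depths follow image columns."""
    a, b = bmo_um
    if abs(b[0] - a[0]) < TOL:
        raise DegenerateGeometryError(
            "BMO line is image-vertical; strict-vertical depth undefined"
        )
    return ReferenceFrame(origin=a, axis=np.array([1.0, 0.0]), normal=np.array([0.0, 1.0]))


def _shear_project(points: np.ndarray, bmo_um: np.ndarray) -> np.ndarray:
    """(t, d) with t = x−x₀ and d = vertical distance to the BMO line."""
    a, b = bmo_um
    slope = (b[1] - a[1]) / (b[0] - a[0])
    t = points[:, 0] - a[0]
    d = points[:, 1] - (a[1] + slope * t)
    return np.column_stack([t, d])


# ---------------------------------------------------------------------------
# per-scan measurement


def _frame_coords(
    ann: BScanAnnotation, strict_vertical: bool
) -> tuple[np.ndarray, np.ndarray]:
    """ALI and polyline annotations in (t, d) frame coordinates."""
    bmo = ann.bmo_um()
    if strict_vertical:
        _strict_vertical_frame(bmo)  # validates geometry
        ali_td = _shear_project(ann.ali_um(), bmo)
        lc_td = _shear_project(ann.anterior_lc_um(), bmo)
    else:
        frame = build_reference_frame([Point2D(*bmo[0]), Point2D(*bmo[1])])
        ali_td = _project(ann.ali_um(), frame)
        lc_td = _project(ann.anterior_lc_um(), frame)

    # normalize polyline direction to ascending t; reject non-monotone input
    dt = np.diff(lc_td[:, 0])
    if np.all(dt < 0):
        lc_td = lc_td[::-1]
    elif not np.all(dt > 0):
        raise DegenerateGeometryError(
            f"scan {ann.scan_id}: anterior LC polyline is not strictly "
            "monotone along the BMO axis"
        )
    if ali_td[0, 0] > ali_td[1, 0]:
        ali_td = ali_td[::-1]
    return ali_td, lc_td


def compute_alid(
    ann: BScanAnnotation, strict_vertical: bool = False
) -> tuple[float, float, float]:
    """Per-side ALI depths and their mean (μm).

    Depth is measured perpendicular to the BMO reference line by default;
    with ``strict_vertical`` it is the image-column distance instead.  An
    ALI anterior to the BMO line yields a negative depth and a warning.
    """
    ali_td, _ = _frame_coords(ann, strict_vertical)
    d1, d2 = float(ali_td[0, 1]), float(ali_td[1, 1])
    if d1 < 0 or d2 < 0:
        warnings.warn(
            f"scan {ann.scan_id}: ALI anterior to the BMO reference line",
            AnteriorInsertionWarning,
            stacklevel=2,
        )
    return d1, d2, (d1 + d2) / 2.0


def clip_polyline(lc_td: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    """Restrict a frame-coordinate polyline to ``t ∈ [t_lo, t_hi]``.

    Endpoints are linearly interpolated at the exact clip abscissae; a
    vertex already at an abscissa is reused rather than duplicated.
    """
    if t_hi - t_lo <= TOL:
        raise DegenerateGeometryError("clip span D is zero")
    t = lc_td[:, 0]
    for side, tc in (("first", t_lo), ("second", t_hi)):
        if tc < t[0] - TOL or tc > t[-1] + TOL:
            raise OutOfSpanError(
                f"{side} ALI at t={tc:.3f} lies outside the anterior-LC "
                f"polyline span [{t[0]:.3f}, {t[-1]:.3f}]"
            )
    d_lo = float(np.interp(t_lo, t, lc_td[:, 1]))
    d_hi = float(np.interp(t_hi, t, lc_td[:, 1]))
    inside = (t > t_lo + TOL) & (t < t_hi - TOL)
    pts = [np.array([t_lo, d_lo])]
    pts.extend(lc_td[inside])
    pts.append(np.array([t_hi, d_hi]))
    return np.vstack(pts)


def compute_area_S(clipped: np.ndarray) -> float:
    """Signed area S (μm²) between the clipped anterior-LC polyline and the
    BMO reference line, by trapezoidal integration of depth over t.
    Posterior excursions count positively, anterior negatively."""
    t, d = clipped[:, 0], clipped[:, 1]
    if t[-1] - t[0] <= TOL:
        raise DegenerateGeometryError("clipped span D is zero")
    return float(np.trapezoid(d, t))


def compute_scan_morphometry(
    ann: BScanAnnotation, strict_vertical: bool = False
) -> ScanMorphometry:
    """Full per-scan morphometry: ALID, D, S, mLCD and curvature index."""
    ali_td, lc_td = _frame_coords(ann, strict_vertical)
    d1, d2, mean_alid = compute_alid(ann, strict_vertical)
    t_lo, t_hi = float(ali_td[0, 0]), float(ali_td[1, 0])
    clipped = clip_polyline(lc_td, t_lo, t_hi)
    S = compute_area_S(clipped)
    D = t_hi - t_lo
    mlcd = S / D
    return ScanMorphometry(
        scan_id=ann.scan_id,
        meridian=ann.meridian,
        alid_side1=d1,
        alid_side2=d2,
        mean_alid=mean_alid,
        D=D,
        S=S,
        mlcd=mlcd,
        curvature_index=mlcd - mean_alid,
    )


# ---------------------------------------------------------------------------
# per-eye aggregation


def _meridian_mean(scans: list[ScanMorphometry], attr: str) -> float | None:
    if not scans:
        return None
    return float(np.mean([getattr(s, attr) for s in scans]))


def aggregate_eye(eye_id: str, scans: Sequence[ScanMorphometry]) -> EyeMorphometry:
    """Aggregate gradable scans of one eye into per-meridian means.

    Each meridian's ALID, mLCD and index are the means over its gradable
    scans (nominally the central three of five); the overall index is the
    mean of the two meridian indices and is absent — not imputed — when a
    meridian has no gradable scan.
    """
    horiz = [s for s in scans if s.meridian == "horizontal"]
    vert = [s for s in scans if s.meridian == "vertical"]
    if not horiz and not vert:
        raise DegenerateGeometryError(f"eye {eye_id}: no gradable scans")
    h_idx = _meridian_mean(horiz, "curvature_index")
    v_idx = _meridian_mean(vert, "curvature_index")
    overall = (h_idx + v_idx) / 2.0 if (h_idx is not None and v_idx is not None) else None
    return EyeMorphometry(
        eye_id=eye_id,
        horizontal_alid=_meridian_mean(horiz, "mean_alid"),
        vertical_alid=_meridian_mean(vert, "mean_alid"),
        horizontal_mlcd=_meridian_mean(horiz, "mlcd"),
        vertical_mlcd=_meridian_mean(vert, "mlcd"),
        horizontal_index=h_idx,
        vertical_index=v_idx,
        overall_index=overall,
        n_scans_horizontal=len(horiz),
        n_scans_vertical=len(vert),
    )
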