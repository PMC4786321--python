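"""Synthetic annotation, cohort and rater-matrix generators.

Everything downstream of the geometry module is testable without any real
OCT data because each generator carries its own ground truth:

* :func:`generate_profile` builds a single annotated B-scan whose anterior
  LC follows a known analytic profile — a flat chord, a U-shaped parabolic
  bowl (horizontal-meridian morphology) or a W-shape with a central
  Gaussian ridge (vertical-meridian morphology, where the central ridge
  houses the retinal vessel trunk) — and returns the exact morphometry of
  the noiseless profile alongside the annotation.
* :func:`generate_cohort` draws per-eye morphometry and clinical
  covariates for POAG and healthy groups, parameterized by group means and
  SDs; the defaults reproduce the study-population statistics.
* :func:`generate_rater_matrix` draws subjects × raters × repeats
  measurements from an additive two-way model with specified variance
  components, for exercising the ICC machinery.

All generators are pure functions of their spec (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .geometry import (
    BScanAnnotation,
    Point2D,
    ScanMorphometry,
)
from .reliability import RaterMatrix

__all__ = [
    "ProfileSpec",
    "MeridianStats",
    "GroupSpec",
    "CohortSpec",
    "RaterSpec",
    "generate_profile",
    "generate_cohort",
    "generate_rater_matrix",
    "poag_group_spec",
    "healthy_group_spec",
    "default_cohort_spec",
    "severity_cohort_spec",
]

_QUAD_N = 100_001  # samples for the dense ground-truth quadrature


# ---------------------------------------------------------------------------
# single-profile generator


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters of one synthetic anterior-LC profile.

    The noiseless depth profile over the insertion span ``t ∈ [0, D]`` is::

        depth(t) = chord(t) + h·(1 − (2t/D − 1)²) − r·exp(−(t − D/2)²/(2w²))

    where ``chord`` interpolates the two insertion depths, ``h`` is the
    posterior bowing amplitude and the Gaussian ridge (W-shape only)
    models the central anterior hump.  Axial Gaussian jitter of SD
    ``noise_sd`` is added to the annotated vertices; the whole annotation
    is then rotated by ``tilt_deg`` about the first BMO point.
    """

    shape: Literal["flat", "U", "W"] = "U"
    D: float = 1500.0
    insertion_depths: tuple[float, float] = (350.0, 350.0)
    bowing_amplitude: float = 120.0
    ridge_height: float = 0.0
    ridge_width: float | None = None  # defaults to D/6
    tilt_deg: float = 0.0
    n_points: int = 200
    noise_sd: float = 0.0
    seed: int = 0
    scan_id: str = "synthetic"
    meridian: Literal["horizontal", "vertical"] = "horizontal"

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "U", "W"):
            raise ValueError(f"shape must be flat|U|W, got {self.shape!r}")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ridge_width is not None and self.ridge_width <= 0:
            raise ValueError("ridge_width must be positive")

    @property
    def h(self) -> float:
        return self.bowing_amplitude if self.shape in ("U", "W") else 0.0

    @property
    def r(self) -> float:
        return self.ridge_height if self.shape == "W" else 0.0

    @property
    def w(self) -> float:
        return self.ridge_width if self.ridge_width is not None else self.D / 6.0

    def depth(self, t: np.ndarray) -> np.ndarray:
        """Noiseless depth profile at abscissae ``t`` (μm below BMO line)."""
        d1, d2 = self.insertion_depths
        chord = d1 + (d2 - d1) * t / self.D
        u = 2.0 * t / self.D - 1.0
        prof = chord + self.h * (1.0 - u * u)
        if self.r != 0.0:
            prof = prof - self.r * np.exp(-((t - self.D / 2.0) ** 2) / (2.0 * self.w**2))
        return prof


def _rotation(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s], [s, c]])


def generate_profile(spec: ProfileSpec) -> tuple[BScanAnnotation, ScanMorphometry]:
    """Annotation realizing ``spec`` plus the noiseless ground truth.

    The ground-truth morphometry is evaluated on the analytic profile by
    dense trapezoidal quadrature, independently of the measurement
    pipeline, so pipeline output can be checked against it.
    """
    rng = np.random.default_rng(spec.seed)
    d1, d2 = spec.insertion_depths

    # ground truth on the noiseless profile
    tq = np.linspace(0.0, spec.D, _QUAD_N)
    S = float(np.trapezoid(spec.depth(tq), tq))
    mean_alid = (d1 + d2) / 2.0
    mlcd = S / spec.D
    truth = ScanMorphometry(
        scan_id=spec.scan_id,
        meridian=spec.meridian,
        alid_side1=d1,
        alid_side2=d2,
        mean_alid=mean_alid,
        D=spec.D,
        S=S,
        mlcd=mlcd,
        curvature_index=mlcd - mean_alid,
    )

    # annotated vertices with axial jitter, then rigid rotation
    t = np.linspace(0.0, spec.D, spec.n_points)
    depth = spec.depth(t) + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    ali_d = np.array([d1, d2]) + rng.normal(0.0, spec.noise_sd, size=2)
    R = _rotation(spec.tilt_deg)

    def rot(t_arr: np.ndarray, d_arr: np.ndarray) -> np.ndarray:
        return np.column_stack([t_arr, d_arr]) @ R.T

    bmo_xy = rot(np.array([0.0, spec.D]), np.zeros(2))
    ali_xy = rot(np.array([0.0, spec.D]), ali_d)
    lc_xy = rot(t, depth)
    ann = BScanAnnotation(
        scan_id=spec.scan_id,
        meridian=spec.meridian,
        bmo=tuple(Point2D(*p) for p in bmo_xy),
        ali=tuple(Point2D(*p) for p in ali_xy),
        anterior_lc=tuple(Point2D(*p) for p in lc_xy),
        pixel_scale=1.0,
    )
    return ann, truth


# ---------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class MeridianStats:
    """Group mean ± SD of ALID and of the curvature index on one meridian."""

    alid_mean: float
    alid_sd: float
    index_mean: float
    index_sd: float


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: sizes, morphometry statistics and covariates.

    ``covariates`` maps names to (mean, sd) of Gaussian draws; binary
    traits are given as fractions.  mLCD is not sampled directly: the
    curvature index is drawn independently of ALID and mLCD is formed as
    ``ALID + index``, which enforces the defining identity exactly while
    matching both printed marginals.
    """

    name: str
    n: int
    horizontal: MeridianStats | None = None
    vertical: MeridianStats | None = None
    overall_index: tuple[float, float] | None = None
    female_fraction: float = 0.5
    dm_fraction: float = 0.0
    htn_fraction: float = 0.0
    covariates: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size n must be positive")
        for m in (self.horizontal, self.vertical):
            if m is not None and (m.alid_sd < 0 or m.index_sd < 0):
                raise ValueError("SDs must be non-negative")
        if self.horizontal is None and self.vertical is None and self.overall_index is None:
            raise ValueError("group needs meridian stats or an overall index")


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: one or more groups and a seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0


#: covariates with a physical lower bound; violating draws are resampled
_POSITIVE_COVARIATES = ("cct", "rnfl", "untreated_iop", "iop_exam", "axl", "disc_area", "rim_area")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    x = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-eye table of morphometry, covariates and group label.

    Columns: ``eye_id, group, {horizontal,vertical}_{alid,mlcd,index},
    overall_index, mlcd`` plus one column per covariate, ``female/dm/htn``
    as 0/1, and ``severity`` (healthy / mild / moderate_advanced, from the
    −6 dB visual-field MD cut when an ``md`` covariate is present).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        cols: dict[str, np.ndarray] = {}
        n = g.n
        meridian_idx = {}
        for name, m in (("horizontal", g.horizontal), ("vertical", g.vertical)):
            if m is None:
                cols[f"{name}_alid"] = np.full(n, np.nan)
                cols[f"{name}_mlcd"] = np.full(n, np.nan)
                cols[f"{name}_index"] = np.full(n, np.nan)
                continue
            alid = rng.normal(m.alid_mean, m.alid_sd, size=n)
            index = rng.normal(m.index_mean, m.index_sd, size=n)
            cols[f"{name}_alid"] = alid
            cols[f"{name}_mlcd"] = alid + index
            cols[f"{name}_index"] = index
            meridian_idx[name] = index
        if len(meridian_idx) == 2:
            overall = (meridian_idx["horizontal"] + meridian_idx["vertical"]) / 2.0
        elif g.overall_index is not None:
            overall = rng.normal(g.overall_index[0], g.overall_index[1], size=n)
        else:
            (only,) = meridian_idx.values()
            overall = only.copy()
        cols["overall_index"] = overall
        mlcd_stack = np.column_stack([cols["horizontal_mlcd"], cols["vertical_mlcd"]])
        any_mlcd = ~np.all(np.isnan(mlcd_stack), axis=1)
        mlcd = np.full(n, np.nan)
        if any_mlcd.any():
            mlcd[any_mlcd] = np.nanmean(mlcd_stack[any_mlcd], axis=1)
        cols["mlcd"] = mlcd
        cols["female"] = (rng.random(n) < g.female_fraction).astype(int)
        cols["dm"] = (rng.random(n) < g.dm_fraction).astype(int)
        cols["htn"] = (rng.random(n) < g.htn_fraction).astype(int)
        for cov, (mu, sd) in g.covariates.items():
            if cov in _POSITIVE_COVARIATES:
                cols[cov] = _truncated_normal(rng, mu, sd, n)
            else:
                cols[cov] = rng.normal(mu, sd, size=n)
        df = pd.DataFrame(cols)
        df.insert(0, "group", g.name)
        df.insert(0, "eye_id", [f"{g.name}_{i:04d}" for i in range(n)])
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if "md" in table.columns:
        # MD = −6 dB exactly falls in moderate_advanced
        sev = np.where(table["md"] > -6.0, "mild", "moderate_advanced")
        sev = np.where(table["group"].str.lower() == "healthy", "healthy", sev)
        table["severity"] = sev
    return table


def poag_group_spec(n: int = 123) -> GroupSpec:
    """Primary open-angle glaucoma group at the study's published statistics."""
    return GroupSpec(
        name="POAG",
        n=n,
        horizontal=MeridianStats(374.2, 101.2, 85.8, 34.1),
        vertical=MeridianStats(426.2, 102.9, 49.8, 38.5),
        female_fraction=0.455,
        dm_fraction=0.107,
        htn_fraction=0.277,
        covariates={
            "age": (60.4, 10.6),
            "untreated_iop": (15.5, 3.7),
            "iop_exam": (12.3, 2.3),
            "se": (-1.08, 2.51),
            "axl": (24.13, 1.16),
            "cct": (529.3, 33.8),
            "disc_area": (2.03, 0.42),
            "rim_area": (0.86, 0.22),
            "vertical_cd": (0.74, 0.11),
            "rnfl": (73.8, 12.0),
            "md": (-4.59, 4.32),
        },
    )


def healthy_group_spec(n: int = 92) -> GroupSpec:
    """Healthy control group at the study's published statistics."""
    return GroupSpec(
        name="healthy",
        n=n,
        horizontal=MeridianStats(332.9, 97.4, 68.2, 32.3),
        vertical=MeridianStats(371.6, 109.1, 32.2, 31.1),
        female_fraction=0.598,
        dm_fraction=0.152,
        htn_fraction=0.326,
        covariates={
            "age": (62.1, 10.7),
            "untreated_iop": (13.7, 2.9),
            "iop_exam": (13.2, 2.8),
            "se": (-0.61, 2.67),
            "axl": (23.80, 1.28),
            "cct": (540.4, 30.7),
            "disc_area": (2.14, 0.36),
            "rim_area": (1.14, 0.24),
            "vertical_cd": (0.63, 0.11),
            "rnfl": (89.4, 9.7),
            "md": (-0.65, 1.98),
        },
    )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """POAG (n=123) vs healthy (n=92) cohort at the published statistics."""
    return CohortSpec(groups=(poag_group_spec(), healthy_group_spec()), seed=seed)


def severity_cohort_spec(seed: int = 0) -> CohortSpec:
    """Healthy / mild / moderate-to-advanced groups at the published
    overall-index statistics (50.2±26.6, 67.3±27.3, 69.2±29.0 μm)."""
    return CohortSpec(
        groups=(
            GroupSpec(name="healthy", n=92, overall_index=(50.2, 26.6)),
            GroupSpec(name="mild", n=92, overall_index=(67.3, 27.3)),
            GroupSpec(name="moderate_advanced", n=31, overall_index=(69.2, 29.0)),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rater-matrix generator


@dataclass(frozen=True)
class RaterSpec:
    """Additive two-way measurement model for reliability studies:
    ``y[s, r, k] = μ + subject_s + rater_r + ε`` with Gaussian components."""

    n_subjects: int = 20
    n_raters: int = 2
    n_repeats: int = 3
    var_subject: float = 900.0
    var_rater: float = 0.0
    var_error: float = 100.0
    grand_mean: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2 or self.n_repeats < 1:
            raise ValueError("need ≥2 subjects, ≥2 raters, ≥1 repeat")
        if min(self.var_subject, self.var_rater, self.var_error) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def population_icc(self) -> float:
        """ICC implied by the variance components:
        σ²_s / (σ²_s + σ²_r + σ²_e)."""
        tot = self.var_subject + self.var_rater + self.var_error
        return self.var_subject / tot if tot > 0 else float("nan")


def generate_rater_matrix(spec: RaterSpec) -> RaterMatrix:
    """Draw a complete subjects × raters × repeats measurement array."""
    rng = np.random.default_rng(spec.seed)
    s = rng.normal(0.0, np.sqrt(spec.var_subject), size=(spec.n_subjects, 1, 1))
    r = rng.normal(0.0, np.sqrt(spec.var_rater), size=(1, spec.n_raters, 1))
    e = rng.normal(
        0.0, np.sqrt(spec.var_error), size=(spec.n_subjects, spec.n_raters, spec.n_repeats)
    )
    values = spec.grand_mean + s + r + e
    return RaterMatrix(values=values)
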