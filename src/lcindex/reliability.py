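"""Intraclass correlation for absolute agreement (two-way model).

Implements the absolute-agreement ICC from a two-way ANOVA decomposition
(subjects crossed with raters), in the single-measure form ICC(A,1) and
the average-measure form ICC(A,k), with F-based 95% confidence intervals
following McGraw & Wong's formulation (the convention SPSS reports as the
"two-way mixed, absolute agreement" ICC).

Reliability designs here are complete: every subject is measured by every
rater the same number of times.  Repeats within a subject × rater cell are
averaged before the two-way decomposition when comparing raters
(inter-observer); the intra-observer ICC treats one rater's repeat series
as the second factor instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RaterMatrix",
    "MeanSquares",
    "ICCResult",
    "anova_decompose",
    "icc_absolute",
    "intra_observer_icc",
    "inter_observer_icc",
]

_DEGENERATE_TOL = 1e-12


class InsufficientDesignError(ValueError):
    """The design has too few subjects or raters for a two-way ICC."""


@dataclass(frozen=True)
class RaterMatrix:
    """Complete reliability design: subjects × raters × repeats values (μm)."""

    values: np.ndarray
    subject_labels: tuple[str, ...] | None = None
    rater_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError("values must be subjects × raters × repeats")
        if not np.all(np.isfinite(v)):
            raise ValueError("incomplete design: non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[2]

    def rater_means(self) -> np.ndarray:
        """Subjects × raters table of within-cell means over repeats."""
        return self.values.mean(axis=2)


@dataclass(frozen=True)
class MeanSquares:
    """Two-way ANOVA mean squares for an n × k subjects-by-raters table."""

    ms_subject: float
    ms_rater: float
    ms_error: float
    n: int
    k: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: Literal["single", "average"]
    ms: MeanSquares
    p_value: float
    undefined: bool = False


def anova_decompose(table: np.ndarray | RaterMatrix) -> MeanSquares:
    """Two-way mean squares of a subjects × raters table.

    A :class:`RaterMatrix` is collapsed over repeats by the within-cell
    mean first.  Sums of squares satisfy the exact decomposition
    SS_total = SS_subject + SS_rater + SS_error.
    """
    y = table.rater_means() if isinstance(table, RaterMatrix) else np.asarray(table, float)
    if y.ndim != 2:
        raise ValueError("expected a 2-D subjects × raters table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise InsufficientDesignError(f"need ≥2 subjects and ≥2 raters, got {n}×{k}")
    grand = y.mean()
    ss_subject = k * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_rater = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    ss_error = float((resid**2).sum())
    return MeanSquares(
        ms_subject=ss_subject / (n - 1),
        ms_rater=ss_rater / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def _single_ci(ms: MeanSquares, icc: float, alpha: float) -> tuple[float, float]:
    """F-based confidence bounds for ICC(A,1)."""
    n, k = ms.n, ms.k
    msr, msc, mse = ms.ms_subject, ms.ms_rater, ms.ms_error
    if 1.0 - icc < _DEGENERATE_TOL:
        return 1.0, 1.0
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else float(n - 1)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(lo), float(hi)


def _spearman_brown(r: float, k: int) -> float:
    den = 1.0 + (k - 1) * r
    return k * r / den if abs(den) > _DEGENERATE_TOL else 1.0


def icc_absolute(
    m: RaterMatrix | np.ndarray,
    form: Literal["single", "average"] = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Absolute-agreement ICC of a complete two-way design.

    ``single`` is ICC(A,1), the reliability of one rater's one
    measurement; ``average`` is ICC(A,k), the reliability of the mean over
    the k raters, obtained from the single form by the Spearman–Brown
    extension (equivalently the McGraw–Wong average-measure formula).

    A constant table has no subject variance to agree about; its ICC is
    undefined and flagged rather than reported as a number.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    ms = anova_decompose(m)
    n, k = ms.n, ms.k
    msr, msc, mse = ms.ms_subject, ms.ms_rater, ms.ms_error
    if max(msr, msc, mse) < _DEGENERATE_TOL:
        return ICCResult(
            icc=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            form=form,
            ms=ms,
            p_value=float("nan"),
            undefined=True,
        )
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom if abs(denom) > _DEGENERATE_TOL else 1.0
    lo1, hi1 = _single_ci(ms, icc1, alpha)
    # F test of the between-subject effect
    if mse < _DEGENERATE_TOL:
        p = 0.0
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    if form == "single":
        icc, lo, hi = icc1, lo1, hi1
    else:
        icc, lo, hi = (_spearman_brown(x, k) for x in (icc1, lo1, hi1))
    lo, hi = min(lo, icc), min(max(hi, icc), 1.0)
    return ICCResult(
        icc=float(icc), ci_low=float(lo), ci_high=float(hi), form=form, ms=ms, p_value=p
    )


def intra_observer_icc(
    m: RaterMatrix,
    rater: int,
    form: Literal["single", "average"] = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """One observer's repeatability: their repeat series act as the second
    factor of the two-way design (subjects × repeats)."""
    series = m.values[:, rater, :]
    if series.shape[1] < 2:
        raise InsufficientDesignError("intra-observer ICC needs ≥2 repeats")
    return icc_absolute(series, form=form, alpha=alpha)


def inter_observer_icc(
    m: RaterMatrix,
    form: Literal["average", "single"] = "average",
    alpha: float = 0.05,
) -> ICCResult:
    """Between-observer agreement: each observer is represented by their
    mean over repeats, and those means form the two-way design."""
    return icc_absolute(m.rater_means(), form=form, alpha=alpha)
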