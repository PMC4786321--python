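"""Cohort-level statistics for LC curvature-index analyses.

Reproduces the statistical pipeline applied to the measured cohorts:

* two-group comparisons — pooled-variance Student's t for continuous
  variables (Welch available behind a flag) and the Pearson chi-square
  test for categorical ones;
* one-way ANOVA across severity groups (healthy / mild / moderate-to-
  advanced glaucoma, split at visual-field MD = −6 dB) with Scheffé's
  post-hoc pairwise contrasts;
* a general-linear-model ladder for predictors of the overall LC
  curvature index: univariate screening of every covariate, then
  multivariate models containing the covariates that screened at
  P < 0.10, with the mutually collinear optic-disc descriptors (disc
  area, rim area, vertical C/D ratio, RNFL thickness, visual-field MD)
  partitioned across five separate models rather than entered jointly.

Model fitting is ordinary least squares via statsmodels; covariates are
reported on conventional clinical units (e.g. vertical C/D ratio per 0.1
increase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "AnovaResult",
    "GLMFit",
    "compare_groups",
    "severity_anova",
    "fit_univariate_ladder",
    "fit_multivariate_models",
    "DEFAULT_COVARIATES",
    "DEFAULT_PARTITION",
    "COLLINEAR_SET",
]

#: covariates screened in the univariate ladder, with the unit each β is
#: reported per (β is per one `scale` of the raw variable)
DEFAULT_COVARIATES: Mapping[str, float] = {
    "age": 1.0,
    "male": 1.0,
    "dm": 1.0,
    "htn": 1.0,
    "untreated_iop": 1.0,
    "iop_exam": 1.0,
    "se": 1.0,
    "axl": 1.0,
    "cct": 1.0,
    "disc_area": 1.0,
    "rim_area": 1.0,
    "vertical_cd": 0.1,  # per 0.1 increase
    "rnfl": 1.0,
    "md": 1.0,
    "mlcd": 1.0,
}

#: optic-disc descriptors too collinear to enter one joint model
COLLINEAR_SET = ("disc_area", "rim_area", "vertical_cd", "rnfl", "md")

#: how the collinear set is split across the five multivariate models
DEFAULT_PARTITION: Mapping[str, tuple[str, ...]] = {
    "model_1": ("disc_area", "rnfl"),
    "model_2": ("disc_area", "md"),
    "model_3": ("rim_area",),
    "model_4": ("vertical_cd", "rnfl"),
    "model_5": ("vertical_cd", "md"),
}


class RankDeficientDesignError(ValueError):
    """The regression design matrix contains aliased (collinear) columns."""


@dataclass(frozen=True)
class TestResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_n: tuple[int, ...]
    group_means: tuple[float, ...] | None = None


@dataclass(frozen=True)
class AnovaResult:
    variable: str
    f_statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    group_n: tuple[int, ...]
    group_means: tuple[float, ...]
    scheffe_p: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class GLMFit:
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    model_id: str
    n: int


# ---------------------------------------------------------------------------
# group comparisons


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    groups: Sequence[str] = ("POAG", "healthy"),
    group_col: str = "group",
    categorical: bool | None = None,
    welch: bool = False,
) -> TestResult:
    """Two-group comparison of one variable.

    Continuous variables use Student's t-test with pooled variance
    (``welch=True`` switches to the unequal-variance form); categorical
    variables use the Pearson chi-square test on the contingency table.
    ``categorical`` defaults to auto-detection (integer 0/1 columns are
    treated as categorical).
    """
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly two group labels")
    sub = [table.loc[table[group_col] == g, variable].dropna() for g in groups]
    for g, s in zip(groups, sub):
        if len(s) == 0:
            raise ValueError(f"group {g!r} is empty for variable {variable!r}")
    if categorical is None:
        categorical = set(np.unique(np.concatenate([s.to_numpy() for s in sub]))) <= {0, 1}
    if categorical:
        cont = np.array(
            [[int((s == v).sum()) for v in (0, 1)] for s in sub], dtype=float
        )
        if cont.min(axis=0).sum() == 0 or (cont.sum(axis=0) == 0).any():
            # a level absent from both groups collapses the table
            cont = cont[:, cont.sum(axis=0) > 0]
        chi2, p, _, _ = stats.chi2_contingency(cont, correction=False)
        return TestResult(
            variable=variable,
            test="chi-square",
            statistic=float(chi2),
            p_value=float(p),
            group_n=tuple(len(s) for s in sub),
        )
    if min(len(s) for s in sub) < 2:
        raise ValueError("continuous comparison needs ≥2 observations per group")
    t, p = stats.ttest_ind(sub[0], sub[1], equal_var=not welch)
    return TestResult(
        variable=variable,
        test="welch-t" if welch else "student-t",
        statistic=float(t),
        p_value=float(p),
        group_n=tuple(len(s) for s in sub),
        group_means=tuple(float(s.mean()) for s in sub),
    )


def severity_anova(
    table: pd.DataFrame,
    variable: str = "overall_index",
    group_col: str = "severity",
    groups: Sequence[str] = ("healthy", "mild", "moderate_advanced"),
) -> AnovaResult:
    """One-way ANOVA across the three severity groups with Scheffé
    post-hoc pairwise contrasts.

    Scheffé's criterion compares each pairwise mean difference against the
    F distribution scaled by (g−1), giving simultaneous protection over
    all contrasts.
    """
    samples = [table.loc[table[group_col] == g, variable].dropna().to_numpy() for g in groups]
    if len(groups) < 3 or any(len(s) == 0 for s in samples):
        raise ValueError("severity ANOVA needs three non-empty groups")
    f_stat, p = stats.f_oneway(*samples)
    g = len(samples)
    ns = np.array([len(s) for s in samples])
    N = int(ns.sum())
    means = np.array([s.mean() for s in samples])
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / (N - g)
    scheffe: dict[tuple[str, str], float] = {}
    for i in range(g):
        for j in range(i + 1, g):
            if mse <= 0:
                p_ij = 0.0 if means[i] != means[j] else 1.0
            else:
                f_ij = (means[i] - means[j]) ** 2 / (mse * (1 / ns[i] + 1 / ns[j]))
                p_ij = float(stats.f.sf(f_ij / (g - 1), g - 1, N - g))
            scheffe[(groups[i], groups[j])] = p_ij
    # identical groups: f_oneway returns nan (zero variance everywhere)
    if not np.isfinite(f_stat):
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        variable=variable,
        f_statistic=float(f_stat),
        p_value=float(p),
        group_labels=tuple(groups),
        group_n=tuple(int(n) for n in ns),
        group_means=tuple(float(m) for m in means),
        scheffe_p=scheffe,
    )


# ---------------------------------------------------------------------------
# general linear model ladder


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    if "male" not in t.columns and "female" in t.columns:
        t["male"] = 1 - t["female"]
    return t


def _design(t: pd.DataFrame, terms: Sequence[str], scales: Mapping[str, float]) -> pd.DataFrame:
    X = pd.DataFrame(index=t.index)
    for term in terms:
        X[term] = t[term] / scales.get(term, 1.0)
    return X


def _fit_ols(
    y: pd.Series, X: pd.DataFrame, model_id: str, alpha: float = 0.05
) -> list[GLMFit]:
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        aliased = _aliased_columns(Xc)
        raise RankDeficientDesignError(
            f"{model_id}: design is rank deficient; aliased columns: {aliased}"
        )
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=alpha)
    fits = []
    for term in X.columns:
        fits.append(
            GLMFit(
                term=term,
                beta=float(res.params[term]),
                ci_low=float(ci.loc[term, 0]),
                ci_high=float(ci.loc[term, 1]),
                p_value=float(res.pvalues[term]),
                model_id=model_id,
                n=int(res.nobs),
            )
        )
    return fits


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy, rightmost first)."""
    cols = list(X.columns)
    aliased = []
    for c in reversed(cols):
        if c == "const":
            continue
        rest = X[[k for k in cols if k != c and k not in aliased]]
        if np.linalg.matrix_rank(rest.to_numpy()) == np.linalg.matrix_rank(X.to_numpy()):
            aliased.append(c)
            if np.linalg.matrix_rank(rest.to_numpy()) == rest.shape[1]:
                break
    return aliased


def fit_univariate_ladder(
    table: pd.DataFrame,
    outcome: str = "overall_index",
    covariates: Mapping[str, float] | Sequence[str] | None = None,
) -> list[GLMFit]:
    """Simple linear model of the outcome on each covariate separately.

    ``covariates`` maps names to reporting scales (β per one scale unit);
    a plain sequence uses scale 1 for every name.  Constant covariates are
    skipped with a warning-level entry rather than an error.
    """
    t = _prepare(table)
    if covariates is None:
        covariates = {k: v for k, v in DEFAULT_COVARIATES.items() if k in t.columns}
    elif not isinstance(covariates, Mapping):
        covariates = {k: 1.0 for k in covariates}
    y = t[outcome]
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant")
    fits = []
    for cov, scale in covariates.items():
        if t[cov].nunique() < 2:
            import warnings

            warnings.warn(f"covariate {cov!r} is constant; skipped", stacklevel=2)
            continue
        X = _design(t, [cov], {cov: scale})
        fits.extend(_fit_ols(y, X, model_id="univariate"))
    return fits


def fit_multivariate_models(
    table: pd.DataFrame,
    ladder: Sequence[GLMFit],
    outcome: str = "overall_index",
    entry_p: float = 0.10,
    partition: Mapping[str, tuple[str, ...]] | None = None,
    collinear: Sequence[str] = COLLINEAR_SET,
    covariate_scales: Mapping[str, float] | None = None,
) -> dict[str, list[GLMFit]]:
    """Multivariate models from the univariate screen.

    Covariates with univariate p ≤ ``entry_p`` enter (boundary ties
    enter).  Entered members of the ``collinear`` set are distributed
    across the ``partition`` models; every other entered covariate appears
    in all models.  Models drop a partition member that did not pass the
    screen.
    """
    t = _prepare(table)
    scales = dict(DEFAULT_COVARIATES)
    if covariate_scales:
        scales.update(covariate_scales)
    entered = [f.term for f in ladder if f.p_value <= entry_p]
    common = [v for v in entered if v not in collinear]
    partition = dict(partition) if partition is not None else dict(DEFAULT_PARTITION)
    y = t[outcome]
    out: dict[str, list[GLMFit]] = {}
    for model_id, members in partition.items():
        terms = common + [m for m in members if m in entered]
        X = _design(t, terms, scales)
        out[model_id] = _fit_ols(y, X, model_id=model_id)
    return out
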