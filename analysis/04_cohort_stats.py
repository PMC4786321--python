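"""Cohort statistics on the simulated POAG/healthy and severity cohorts.

Reproduces the statistical pipeline on the tables from 01_simulate.py:
POAG-vs-healthy comparisons of ALID, mLCD and the curvature index on both
meridians (pooled t), the severity one-way ANOVA with Scheffé post-hoc,
and the univariate → five-model multivariate GLM ladder for predictors of
the overall curvature index.

Writes results/stats/ (comparison, ANOVA, univariate, multivariate CSVs).
"""

import dataclasses
from pathlib import Path

import pandas as pd

from lcindex.cohort_stats import (
    compare_groups,
    fit_multivariate_models,
    fit_univariate_ladder,
    severity_anova,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = ROOT / "simulated"
    if not (sim / "cohort.csv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(sim / "cohort.csv")
    severity = pd.read_csv(sim / "severity_cohort.csv")

    comparisons = []
    for var in ("horizontal_alid", "vertical_alid", "horizontal_mlcd",
                "vertical_mlcd", "horizontal_index", "vertical_index",
                "overall_index", "female", "untreated_iop", "rnfl"):
        comparisons.append(dataclasses.asdict(compare_groups(cohort, var)))
    comp = pd.DataFrame(comparisons)
    comp.to_csv(out / "group_comparisons.csv", index=False)
    idx = comp.set_index("variable")
    print("POAG vs healthy (simulated cohort):")
    for var in ("horizontal_index", "vertical_index"):
        r = idx.loc[var]
        print(f"  {var}: means {r.group_means[0]:.1f} vs {r.group_means[1]:.1f} μm, "
              f"t={r.statistic:.2f}, p={r.p_value:.2g}")

    anova = severity_anova(severity, group_col="group")
    pd.DataFrame(
        [{"contrast": "overall", "p": anova.p_value, "F": anova.f_statistic}]
        + [{"contrast": f"{a} vs {b}", "p": p} for (a, b), p in anova.scheffe_p.items()]
    ).to_csv(out / "severity_anova.csv", index=False)
    print(f"severity ANOVA F={anova.f_statistic:.2f} p={anova.p_value:.2g}; "
          f"mild vs moderate-advanced Scheffé p="
          f"{anova.scheffe_p[('mild', 'moderate_advanced')]:.2f}")

    ladder = fit_univariate_ladder(cohort)
    pd.DataFrame([dataclasses.asdict(f) for f in ladder]).to_csv(
        out / "univariate.csv", index=False
    )
    entered = sorted(f.term for f in ladder if f.p_value <= 0.10)
    print(f"univariate screen (p≤0.10): {', '.join(entered)}")
    models = fit_multivariate_models(cohort, ladder)
    pd.DataFrame(
        [dataclasses.asdict(f) for fits in models.values() for f in fits]
    ).to_csv(out / "multivariate.csv", index=False)
    for mid, fits in models.items():
        mlcd = [f for f in fits if f.term == "mlcd"]
        if mlcd:
            f = mlcd[0]
            print(f"  {mid}: mLCD β={f.beta:.3f} "
                  f"(95% CI {f.ci_low:.3f}-{f.ci_high:.3f}, p={f.p_value:.2g})")


if __name__ == "__main__":
    main()
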