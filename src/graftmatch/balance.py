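"""Covariate-balance diagnostics.

Balance between cohorts is quantified two ways, before and after matching:

* hypothesis tests — pooled-variance two-sample t-test for continuous and
  count covariates, Pearson chi-square (no continuity correction) on the
  level × group table for nominal covariates;
* standardized mean differences — |m₁−m₂| / √((s₁²+s₂²)/2) for numeric
  covariates, and for nominal covariates the maximum over levels of the
  two-proportion analogue |p₁−p₂| / √((p₁(1−p₁)+p₂(1−p₂))/2).

SMDs are reported as absolute values; 0 means perfect balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import Covariate, CovariateSpec, complete_case_filter, default_matching_spec
from .exceptions import AnalysisError
from .matching import MatchedCohort
from .registry import COHORT_TREATED

#: Conventional significance threshold: p < alpha significant,
#: alpha ≤ p < trend_alpha a trend.
DEFAULT_ALPHA = 0.05
DEFAULT_TREND_ALPHA = 0.10


def covariate_pvalue(
    treated: pd.Series | np.ndarray,
    control: pd.Series | np.ndarray,
    kind: str,
    welch: bool = False,
) -> float:
    """Two-sided p-value for a between-group difference on one covariate.

    Continuous/count → two-sample t-test (pooled variance by default;
    Welch via flag).  Nominal → Pearson chi-square without continuity
    correction.  Groups identical to machine precision give p = 1.
    """
    t = pd.Series(treated).dropna()
    c = pd.Series(control).dropna()
    if kind in ("continuous", "count"):
        if len(t) < 2 or len(c) < 2:
            raise AnalysisError("covariate_pvalue: need ≥2 observations per group")
        if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
            return 1.0 if t.mean() == c.mean() else 0.0
        res = stats.ttest_ind(t, c, equal_var=not welch)
        return float(res.pvalue)
    if kind == "nominal":
        levels = sorted(set(t.astype(str)) | set(c.astype(str)))
        if len(levels) < 2:
            return 1.0
        obs = np.array(
            [
                [(t.astype(str) == lv).sum() for lv in levels],
                [(c.astype(str) == lv).sum() for lv in levels],
            ]
        )
        if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
            raise AnalysisError("covariate_pvalue: degenerate contingency table")
        _, p, _, expected = stats.chi2_contingency(obs, correction=False)
        if (expected <= 0).any():
            raise AnalysisError("covariate_pvalue: zero expected cell count")
        return float(p)
    raise AnalysisError(f"covariate_pvalue: unknown kind {kind!r}")


def smd(
    treated: pd.Series | np.ndarray,
    control: pd.Series | np.ndarray,
    kind: str,
) -> float:
    """Absolute standardized mean difference.

    Returns ``inf`` when the pooled variance is zero but the means differ;
    identical degenerate groups give 0.
    """
    t = pd.Series(treated).dropna()
    c = pd.Series(control).dropna()
    if kind in ("continuous", "count"):
        denom = np.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2.0)
        diff = abs(t.mean() - c.mean())
        if denom == 0:
            return 0.0 if diff == 0 else float("inf")
        return float(diff / denom)
    if kind == "nominal":
        levels = sorted(set(t.astype(str)) | set(c.astype(str)))
        worst = 0.0
        for lv in levels:
            p1 = float((t.astype(str) == lv).mean())
            p2 = float((c.astype(str) == lv).mean())
            denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
            diff = abs(p1 - p2)
            if denom == 0:
                worst = max(worst, 0.0 if diff == 0 else float("inf"))
            else:
                worst = max(worst, diff / denom)
        return float(worst)
    raise AnalysisError(f"smd: unknown kind {kind!r}")


def _summary(values: pd.Series, cov: Covariate) -> str:
    v = values.dropna()
    if cov.is_numeric:
        return f"{v.mean():.2f}±{v.std(ddof=1):.2f}"
    counts = v.astype(str).value_counts().sort_index()
    return "; ".join(f"{lv}:{n}" for lv, n in counts.items())


@dataclass
class BalanceReport:
    """Per-covariate balance table for one stage (before or after matching).

    ``table`` columns: covariate, kind, test, p_value, smd,
    treated_summary, control_summary, stage.
    """

    table: pd.DataFrame
    stage: str

    @property
    def mean_smd(self) -> float:
        return float(self.table["smd"].mean())

    def n_balanced(self, alpha: float = DEFAULT_ALPHA) -> int:
        """Number of covariates whose test does not reject at ``alpha``."""
        return int((self.table["p_value"] > alpha).sum())

    def summary(self, alpha: float = DEFAULT_ALPHA) -> dict:
        return {
            "stage": self.stage,
            "mean_smd": self.mean_smd,
            "n_covariates": len(self.table),
            "n_balanced": self.n_balanced(alpha),
        }

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_love_plot_frame(self) -> pd.DataFrame:
        """Covariate / SMD export for a Love plot."""
        return self.table[["covariate", "smd", "stage"]].copy()


def _stage_report(
    treated: pd.DataFrame, control: pd.DataFrame, spec: CovariateSpec, stage: str, welch: bool
) -> BalanceReport:
    rows = []
    for cov in spec:
        tv = treated[cov.name]
        cv = control[cov.name]
        test = ("welch_t" if welch else "student_t") if cov.is_numeric else "chi_square"
        rows.append(
            {
                "covariate": cov.name,
                "kind": cov.kind,
                "test": test,
                "p_value": covariate_pvalue(tv, cv, cov.kind, welch=welch),
                "smd": smd(tv, cv, cov.kind),
                "treated_summary": _summary(tv, cov),
                "control_summary": _summary(cv, cov),
                "stage": stage,
            }
        )
    return BalanceReport(table=pd.DataFrame(rows), stage=stage)


def balance_table(
    records: pd.DataFrame,
    matched: MatchedCohort,
    spec: CovariateSpec | None = None,
    welch: bool = False,
) -> tuple[BalanceReport, BalanceReport]:
    """Balance before and after matching.

    "Before" is computed on all complete-case records; "after" on matched
    subjects only (pooled matched samples, not pairwise differences).
    """
    spec = spec or default_matching_spec()
    complete, _ = complete_case_filter(records, spec)
    is_treated = complete["cohort"] == COHORT_TREATED
    before = _stage_report(complete[is_treated], complete[~is_treated], spec, "before", welch)

    t_ids = [i for i in matched.treated_ids if i in complete.index]
    c_ids = [i for i in matched.control_ids if i in complete.index]
    after = _stage_report(complete.loc[t_ids], complete.loc[c_ids], spec, "after", welch)
    return before, after


def balance_grid(
    records: pd.DataFrame,
    cohorts: dict[str, MatchedCohort],
    spec: CovariateSpec | None = None,
) -> pd.DataFrame:
    """Cross-method comparison grid: one row per covariate, one column of
    after-matching p-values per matching method."""
    spec = spec or default_matching_spec()
    grid = {}
    for name, cohort in cohorts.items():
        _, after = balance_table(records, cohort, spec)
        grid[name] = after.table.set_index("covariate")["p_value"]
    out = pd.DataFrame(grid)
    out.index.name = "covariate"
    return out
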