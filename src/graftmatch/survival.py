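"""Post-matching outcome analysis.

Death-censored graft survival and patient survival are estimated with the
Kaplan–Meier product-limit estimator and compared by the two-group log-rank
test; "five-year survival" is the KM step value at 60 months.  Graft failure
means graft removal, return to dialysis or re-registration for transplant;
a death with a functioning graft censors the graft-failure analysis.

Failure-cause comparisons use crude 2×2 odds ratios with Woolf (log-normal)
95% confidence intervals and uncorrected Pearson chi-square p-values; a
multivariable Cox proportional-hazards model (Efron tie handling) quantifies
covariate effects on the graft-failure hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .exceptions import AnalysisError
from .matching import MatchedCohort
from .registry import COHORT_CONTROL, COHORT_TREATED

FIVE_YEARS_MONTHS = 60.0

#: Table-style age bins (years): [18,35), [35,50), [50,65), 65+.
AGE_BIN_EDGES = (18.0, 35.0, 50.0, 65.0, np.inf)
AGE_BIN_LABELS = ("18-34", "35-49", "50-64", ">65")


@dataclass
class SurvivalEstimate:
    """Kaplan–Meier product-limit estimate.

    ``timeline`` holds the observed event/censor times (ascending) with the
    KM survival probability, at-risk count and event count at each.
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """KM step value at time ``t`` (the value at the largest observed
        time ≤ t; S(0) = 1)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        """Greenwood variance of Ŝ(t)."""
        mask = (self.timeline <= t) & (self.events > 0)
        d = self.events[mask]
        n = self.at_risk[mask]
        s = self.survival_at(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.sum(d / (n * (n - d)))
        return float(s * s * g)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.timeline,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(
    durations: Sequence[float],
    events: Sequence[int],
    censored: Sequence[int] | None = None,
) -> SurvivalEstimate:
    """Product-limit estimator.

    ``events`` flags the endpoint of interest; ``censored`` (optional,
    mutually exclusive with ``events`` per subject) flags explicit censoring
    and is only accepted for interface symmetry — any subject without an
    event is censored at its duration.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise AnalysisError("km_estimate: empty input")
    if (durations <= 0).any():
        raise AnalysisError("km_estimate: durations must be positive")
    if censored is not None:
        censored = np.asarray(censored, dtype=int)
        if ((events == 1) & (censored == 1)).any():
            raise AnalysisError("km_estimate: event and censor flags are mutually exclusive")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    tbl = kmf.event_table.iloc[1:] if 0.0 not in durations else kmf.event_table
    timeline = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(timeline).to_numpy()
    return SurvivalEstimate(
        timeline=timeline,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(),
        events=tbl["observed"].to_numpy(),
        n_subjects=int(durations.size),
    )


def graft_survival_km(records: pd.DataFrame) -> SurvivalEstimate:
    """Death-censored graft survival: graft failure is the event, death with
    a functioning graft censors."""
    return km_estimate(records["followup_months"], records["graft_failure_event"])


def patient_survival_km(records: pd.DataFrame) -> SurvivalEstimate:
    """Patient survival: death is the event (graft failure does not end
    follow-up for survival, but in a single-follow-up registry the recorded
    time is used as-is)."""
    return km_estimate(records["followup_months"], records["death_event"])


def logrank(
    durations_a: Sequence[float],
    events_a: Sequence[int],
    durations_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic with 1 df,
    p-value).  If neither group has an event the test is undefined and
    (0.0, 1.0) is returned with a warning."""
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(np.asarray(durations_a)) == 0 or len(np.asarray(durations_b)) == 0:
        raise AnalysisError("logrank: both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        warnings.warn("logrank: no events in either group; p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(durations_a, durations_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _strata(records: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "age_group":
        return pd.cut(
            records["age"], bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False
        ).astype(str)
    return records[stratifier].astype(str)


def stratified_survival_table(
    records: pd.DataFrame,
    stratifiers: Sequence[str] = ("era", "dgf", "ethnicity", "dcd_donor", "age_group", "dialysis_at_listing"),
    at: float = FIVE_YEARS_MONTHS,
) -> pd.DataFrame:
    """Per-stratum five-year death-censored graft survival by cohort, with
    log-rank p-values.

    One row per stratifier level: survival at ``at`` months in each cohort
    and the two-group log-rank p.  Empty strata yield a row of NaNs with a
    warning.
    """
    rows = []
    overall = {"stratifier": "overall", "level": "all"}
    rows.append(overall | _stratum_stats(records, at))
    for strat in stratifiers:
        levels = _strata(records, strat)
        for lv in sorted(levels.dropna().unique()):
            sub = records[levels == lv]
            rows.append({"stratifier": strat, "level": lv} | _stratum_stats(sub, at))
    return pd.DataFrame(rows)


def _stratum_stats(sub: pd.DataFrame, at: float) -> dict:
    out = {
        "n_treated": int((sub["cohort"] == COHORT_TREATED).sum()),
        "n_control": int((sub["cohort"] == COHORT_CONTROL).sum()),
        "survival_treated": np.nan,
        "survival_control": np.nan,
        "logrank_p": np.nan,
    }
    t = sub[sub["cohort"] == COHORT_TREATED]
    c = sub[sub["cohort"] == COHORT_CONTROL]
    if t.empty or c.empty:
        warnings.warn("stratified_survival_table: empty stratum", stacklevel=2)
        return out
    out["survival_treated"] = graft_survival_km(t).survival_at(at)
    out["survival_control"] = graft_survival_km(c).survival_at(at)
    _, out["logrank_p"] = logrank(
        t["followup_months"], t["graft_failure_event"],
        c["followup_months"], c["graft_failure_event"],
    )
    return out


@dataclass
class EtiologyResult:
    """Crude 2×2 comparison of one failure cause between cohorts.

    ``a`` of ``n1`` treated failures and ``b`` of ``n2`` control failures
    have this cause.  OR is the cross-product ratio, the CI is Woolf's
    log-normal interval, and ``p`` the uncorrected Pearson chi-square.
    ``corrected`` flags the Haldane–Anscombe 0.5 adjustment for zero cells.
    """

    cause: str
    a: int
    n1: int
    b: int
    n2: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False

    @property
    def proportion_treated(self) -> float:
        return self.a / self.n1

    @property
    def proportion_control(self) -> float:
        return self.b / self.n2


def etiology_or(a: int, n1: int, b: int, n2: int, cause: str = "", alpha: float = 0.05) -> EtiologyResult:
    """Odds ratio for one failure cause.

    OR = (a/(n1−a)) / (b/(n2−b)); 95% Woolf CI
    exp(ln OR ± z·√(1/a + 1/(n1−a) + 1/b + 1/(n2−b))); p from the
    uncorrected Pearson chi-square on the 2×2 table.  A zero cell triggers
    the Haldane–Anscombe 0.5 correction for the OR and CI (flagged); the
    chi-square always uses the raw counts.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 == 0 or n2 == 0:
        raise AnalysisError("etiology_or: counts must satisfy 0 ≤ a ≤ n1, 0 ≤ b ≤ n2, n1, n2 > 0")
    cells = np.array([a, n1 - a, b, n2 - b], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    ca, cna, cb, cnb = cells
    orr = (ca / cna) / (cb / cnb)
    se = np.sqrt(1 / ca + 1 / cna + 1 / cb + 1 / cnb)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(orr) - z * se), np.exp(np.log(orr) + z * se)
    obs = np.array([[a, n1 - a], [b, n2 - b]])
    if (obs.sum(axis=0) == 0).any():
        p = 1.0
    else:
        _, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return EtiologyResult(
        cause=cause, a=a, n1=n1, b=b, n2=n2,
        odds_ratio=float(orr), ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), corrected=corrected,
    )


def etiology_or_exact(a: int, n1: int, b: int, n2: int, cause: str = "") -> EtiologyResult:
    """Fisher-based alternative: conditional-MLE odds ratio with exact CI and
    Fisher p-value."""
    obs = [[a, n1 - a], [b, n2 - b]]
    res = stats.contingency.odds_ratio(obs, kind="conditional")
    ci = res.confidence_interval(0.95)
    _, p = stats.fisher_exact(obs)
    return EtiologyResult(
        cause=cause, a=a, n1=n1, b=b, n2=n2,
        odds_ratio=float(res.statistic), ci_low=float(ci.low), ci_high=float(ci.high),
        p_value=float(p), corrected=False,
    )


def etiology_table(records: pd.DataFrame, causes: Sequence[str] | None = None) -> pd.DataFrame:
    """Failure-cause comparison table from a registry (or matched subset).

    One row per cause with counts, proportions of reported failures, OR,
    Woolf CI and chi-square p."""
    failed = records[records["graft_failure_event"].astype(bool)]
    t = failed[failed["cohort"] == COHORT_TREATED]
    c = failed[failed["cohort"] == COHORT_CONTROL]
    n1, n2 = len(t), len(c)
    if n1 == 0 or n2 == 0:
        raise AnalysisError("etiology_table: no graft failures in one of the cohorts")
    if causes is None:
        causes = sorted(set(failed["failure_cause"].dropna()))
    rows = []
    for cause in causes:
        res = etiology_or(
            int((t["failure_cause"] == cause).sum()), n1,
            int((c["failure_cause"] == cause).sum()), n2,
            cause=cause,
        )
        rows.append(
            {
                "cause": cause,
                "treated_count": res.a, "treated_failures": res.n1,
                "control_count": res.b, "control_failures": res.n2,
                "treated_pct": 100 * res.proportion_treated,
                "control_pct": 100 * res.proportion_control,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "corrected": res.corrected,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit on the graft-failure hazard.

    ``summary`` has one row per covariate: hazard_ratio, se_ln_hr, p_value.
    """

    summary: pd.DataFrame
    converged: bool
    n_events: int
    log_likelihood: float
    fitter: CoxPHFitter = field(repr=False, default=None)

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hazard_ratio"]


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "followup_months",
    event_col: str = "graft_failure_event",
) -> CoxFit:
    """Fit a Cox model by partial likelihood with Efron tie handling.

    Nominal covariates are expanded to dummies (first level reference).
    Raises :class:`AnalysisError` on constant covariates, absent events or
    non-convergence.
    """
    data = records[list(covariates) + [duration_col, event_col]].dropna()
    if int(data[event_col].sum()) == 0:
        raise AnalysisError("cox_fit: no events")
    X = pd.get_dummies(data, columns=[c for c in covariates if not pd.api.types.is_numeric_dtype(data[c])],
                       drop_first=True, dtype=float)
    for col in X.columns.drop([duration_col, event_col]):
        if X[col].nunique() < 2:
            raise AnalysisError(f"cox_fit: covariate {col!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col=duration_col, event_col=event_col)
    except Exception as exc:
        raise AnalysisError(f"cox_fit: fit failed: {exc}") from exc
    summ = pd.DataFrame(
        {
            "hazard_ratio": np.exp(cph.params_),
            "se_ln_hr": cph.standard_errors_,
            "p_value": cph.summary["p"],
        }
    )
    return CoxFit(
        summary=summ,
        converged=True,
        n_events=int(data[event_col].sum()),
        log_likelihood=float(cph.log_likelihood_),
        fitter=cph,
    )
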