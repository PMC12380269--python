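"""Survival machinery: KM, log-rank, strata, odds ratios, Cox."""

import numpy as np
import pandas as pd
import pytest

from graftmatch import (
    cox_fit,
    default_config,
    etiology_or,
    etiology_table,
    generate_registry,
    km_estimate,
    logrank,
    stratified_survival_table,
)
from graftmatch.exceptions import AnalysisError
from graftmatch.survival import etiology_or_exact, graft_survival_km


class TestKmEstimate:
    def test_no_events_survival_stays_one(self):
        est = km_estimate([3, 8, 12], [0, 0, 0])
        assert est.survival_at(100) == 1.0

    def test_three_subject_fixture_by_hand(self):
        # events at 5 and 15, censor at 10: S(5)=2/3, S(15)=(2/3)·(1-1/1)=0
        est = km_estimate([5, 10, 15], [1, 0, 1])
        assert est.survival_at(5) == pytest.approx(2 / 3)
        assert est.survival_at(12) == pytest.approx(2 / 3)
        assert est.survival_at(15) == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(50, size=200)
        est = km_estimate(t, np.ones(200, dtype=int))
        for q in (10.0, 40.0, 80.0):
            assert est.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_exponential_simulation_recovers_closed_form(self, rng):
        lam, n, q = 0.011, 5000, 60.0
        t = rng.exponential(1 / lam, size=n)
        cens = np.minimum(t, 120.0)
        events = (t <= 120.0).astype(int)
        est = km_estimate(cens, events)
        target = np.exp(-lam * q)
        se = np.sqrt(est.variance_at(q))
        assert abs(est.survival_at(q) - target) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            km_estimate([], [])

    def test_event_censor_exclusivity_enforced(self):
        with pytest.raises(AnalysisError):
            km_estimate([5.0], [1], censored=[1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        stat, p = logrank([3, 5, 9], [1, 0, 1], [3, 5, 9], [1, 0, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(40, 80), rng.exponential(70, 90)
        ea, eb = np.ones(80, int), np.ones(90, int)
        s1, p1 = logrank(ta, ea, tb, eb)
        s2, p2 = logrank(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_hazard_ratio_three_is_detected(self, rng):
        a = rng.exponential(20, 1000)
        b = rng.exponential(60, 1000)
        _, p = logrank(a, np.ones(1000, int), b, np.ones(1000, int))
        assert p < 0.001

    def test_no_events_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            stat, p = logrank([5, 6], [0, 0], [7, 8], [0, 0])
        assert (stat, p) == (0.0, 1.0)


class TestStratifiedTable:
    def test_single_level_stratifier_equals_overall(self, medium_registry):
        reg = medium_registry.copy()
        reg["era"] = "2011-2020"
        tbl = stratified_survival_table(reg, stratifiers=("era",)).set_index("level")
        assert tbl.loc["2011-2020", "survival_treated"] == tbl.loc["all", "survival_treated"]
        assert tbl.loc["2011-2020", "logrank_p"] == tbl.loc["all", "logrank_p"]

    def test_dgf_stratum_has_lower_survival_in_both_cohorts(self):
        cfg = default_config(n_treated=2500, n_control=2500, rng_seed=31)
        assert cfg.dgf_hazard_ratio > 1
        reg = generate_registry(cfg)
        tbl = stratified_survival_table(reg, stratifiers=("dgf",)).set_index("level")
        for col in ("survival_treated", "survival_control"):
            assert tbl.loc["1", col] < tbl.loc["0", col]

    def test_stratum_without_events_reports_survival_one(self, small_registry):
        reg = small_registry.copy()
        reg["graft_failure_event"] = 0
        reg["failure_cause"] = pd.NA
        tbl = stratified_survival_table(reg, stratifiers=())
        assert tbl.loc[0, "survival_treated"] == 1.0

    def test_empty_stratum_emits_nan_row_with_warning(self, small_registry):
        reg = small_registry.copy()
        levels = reg["era"].copy()
        levels[reg["cohort"] == "treated"] = "2000-2010"
        reg["era"] = levels
        with pytest.warns(UserWarning):
            tbl = stratified_survival_table(reg, stratifiers=("era",))
        row = tbl.set_index("level").loc["2011-2020"]
        assert np.isnan(row["survival_treated"])

    def test_age_bins_partition_all_subjects(self, medium_registry):
        tbl = stratified_survival_table(medium_registry, stratifiers=("age_group",))
        sub = tbl[tbl["stratifier"] == "age_group"]
        assert sub["n_treated"].sum() == (medium_registry["cohort"] == "treated").sum()


class TestEtiologyOr:
    def test_equal_proportions_give_unit_odds_ratio(self):
        res = etiology_or(10, 20, 10, 20)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_antisymmetric_under_group_swap(self):
        a = etiology_or(94, 332, 445, 1487)
        b = etiology_or(445, 1487, 94, 332)
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)
        assert a.ci_low == pytest.approx(1 / b.ci_high)
        assert a.ci_high == pytest.approx(1 / b.ci_low)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_cell_triggers_flagged_haldane_correction(self):
        res = etiology_or(0, 10, 5, 20)
        assert res.corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(AnalysisError):
            etiology_or(11, 10, 1, 20)

    def test_exact_variant_agrees_in_direction(self):
        woolf = etiology_or(94, 332, 445, 1487)
        exact = etiology_or_exact(94, 332, 445, 1487)
        assert (woolf.odds_ratio < 1) == (exact.odds_ratio < 1)
        assert exact.ci_low <= exact.odds_ratio <= exact.ci_high

    def test_table_from_registry_counts_consistent(self, medium_registry):
        tbl = etiology_table(medium_registry)
        failed = medium_registry[medium_registry["graft_failure_event"] == 1]
        assert tbl["treated_count"].sum() == (failed["cohort"] == "treated").sum()
        assert (tbl["ci_low"] <= tbl["odds_ratio"]).all()
        assert (tbl["odds_ratio"] <= tbl["ci_high"]).all()


class TestCoxFit:
    @staticmethod
    def _simulate(rng, n, hr):
        x = rng.integers(0, 2, size=n)
        lam = 0.01 * hr**x
        t = rng.exponential(1 / lam)
        obs = np.minimum(t, 100.0)
        return pd.DataFrame(
            {
                "x": x.astype(float),
                "followup_months": obs,
                "graft_failure_event": (t <= 100.0).astype(int),
            }
        )

    def test_null_covariate_hazard_ratio_near_one(self, rng):
        df = self._simulate(rng, 3000, 1.0)
        fit = cox_fit(df, ["x"])
        ln_hr = np.log(fit.hazard_ratios["x"])
        assert abs(ln_hr) < 3 * fit.summary.loc["x", "se_ln_hr"]

    def test_recovers_simulated_hazard_ratio(self, rng):
        df = self._simulate(rng, 3000, 2.0)
        fit = cox_fit(df, ["x"])
        ln_hr = np.log(fit.hazard_ratios["x"])
        assert abs(ln_hr - np.log(2.0)) < 3 * fit.summary.loc["x", "se_ln_hr"]

    def test_duplicated_dataset_nearly_same_point_estimates(self, rng):
        # exact identity holds for Breslow ties; Efron's correction sees the
        # duplication-induced ties, so allow a small perturbation
        df = self._simulate(rng, 400, 1.5)
        fit1 = cox_fit(df, ["x"])
        fit2 = cox_fit(pd.concat([df, df], ignore_index=True), ["x"])
        assert fit1.hazard_ratios["x"] == pytest.approx(fit2.hazard_ratios["x"], rel=1e-2)

    def test_constant_covariate_rejected(self, rng):
        df = self._simulate(rng, 100, 1.0)
        df["x"] = 1.0
        with pytest.raises(AnalysisError):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self, rng):
        df = self._simulate(rng, 50, 1.0)
        df["graft_failure_event"] = 0
        with pytest.raises(AnalysisError):
            cox_fit(df, ["x"])


def test_death_censored_graft_km_treats_death_as_censoring(small_registry):
    """Flipping death events to censoring must not change graft-failure KM."""
    est = graft_survival_km(small_registry)
    no_death = small_registry.copy()
    no_death["death_event"] = 0
    est2 = graft_survival_km(no_death)
    np.testing.assert_array_equal(est.survival, est2.survival)
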