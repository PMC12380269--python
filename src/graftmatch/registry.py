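"""Registry table schema and CSV I/O.

A registry is a plain :class:`pandas.DataFrame` with one row per transplant,
indexed by ``subject_id``.  The column set below is the package's native
dialect; user-supplied extracts with different headers are adapted through a
column map at read time.

Columns
-------
cohort
    ``"treated"`` (high-risk-index arm) or ``"control"``.
age, bmi, cold_ischemia
    Recipient age (years), body-mass index (kg/m²) and cold ischemia time
    (hours).
hla_mismatch
    HLA mismatch count, integer 0–6.
ethnicity, sex
    Nominal recipient covariates.
dialysis_at_listing, dgf, dcd_donor
    0/1 stratifier flags: maintenance dialysis before transplant, delayed
    graft function, donation-after-circulatory-death donor.
era
    Transplant-year era, ``"2000-2010"`` or ``"2011-2020"``.
primary_diagnosis
    Primary renal diagnosis category.
followup_months
    Observed follow-up (months); always > 1 month because subjects who die
    within 30 days of transplant are excluded from the study population.
graft_failure_event, death_event
    0/1 event indicators.  Graft failure means graft removal, return to
    dialysis or re-registration for transplant; survival analyses of graft
    failure are death-censored (death with a functioning graft censors).
failure_cause
    Failure-cause category; present iff ``graft_failure_event == 1``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

COHORT_TREATED = "treated"
COHORT_CONTROL = "control"

ETHNICITY_LEVELS = ("Asian", "Black", "Hispanic", "Other", "White")
SEX_LEVELS = ("female", "male")
ERA_LEVELS = ("2000-2010", "2011-2020")
DIAGNOSIS_LEVELS = ("FSGS", "PKD", "hypertensive_nephrosclerosis", "T2DM", "other")
FAILURE_CAUSES = (
    "infection",
    "primary graft failure",
    "recurrent disease",
    "acute rejection",
    "chronic rejection",
    "vascular thrombosis",
    "BK virus",
    "other",
)

#: Minimum follow-up implied by the 30-day early-death exclusion (months).
MIN_FOLLOWUP_MONTHS = 1.0

COVARIATE_COLUMNS = ("age", "bmi", "cold_ischemia", "hla_mismatch", "ethnicity", "sex")
STRATIFIER_COLUMNS = ("dialysis_at_listing", "dgf", "dcd_donor", "era", "primary_diagnosis")
OUTCOME_COLUMNS = ("followup_months", "graft_failure_event", "death_event", "failure_cause")
REGISTRY_COLUMNS = ("cohort",) + COVARIATE_COLUMNS + STRATIFIER_COLUMNS + OUTCOME_COLUMNS


def validate_registry(records: pd.DataFrame) -> None:
    """Check registry invariants, raising :class:`ConfigurationError` on the
    first violation.

    Invariants: unique subject ids; known cohort labels; age ≥ 18;
    HLA mismatch in {0..6} where present; follow-up beyond the 30-day
    exclusion window; failure cause present iff a graft-failure event is
    recorded.  Covariate cells may be missing (NaN); outcome cells may not.
    """
    missing_cols = [c for c in REGISTRY_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ConfigurationError(f"registry is missing columns: {missing_cols}")
    if records.index.has_duplicates:
        raise ConfigurationError("subject_id: duplicate identifiers in registry")
    bad_cohort = set(records["cohort"].unique()) - {COHORT_TREATED, COHORT_CONTROL}
    if bad_cohort:
        raise ConfigurationError(f"cohort: unknown labels {sorted(bad_cohort)}")
    age = records["age"].dropna()
    if (age < 18).any():
        raise ConfigurationError("age: recipients under 18 are excluded from the study population")
    hla = records["hla_mismatch"].dropna()
    if ((hla < 0) | (hla > 6)).any():
        raise ConfigurationError("hla_mismatch: values must lie in 0..6")
    fup = records["followup_months"]
    if fup.isna().any() or (fup <= MIN_FOLLOWUP_MONTHS).any():
        raise ConfigurationError(
            "followup_months: follow-up must exceed the 30-day early-death exclusion window"
        )
    gf = records["graft_failure_event"].astype(bool)
    has_cause = records["failure_cause"].notna() & (records["failure_cause"] != "")
    if (gf != has_cause).any():
        raise ConfigurationError(
            "failure_cause: must be present exactly for records with a graft-failure event"
        )


def read_registry(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a registry CSV.

    Parameters
    ----------
    path
        CSV file with a ``subject_id`` column (or one mapped to it).
    column_map
        Optional mapping from the file's column names to the native names,
        e.g. ``{"REC_AGE": "age"}``.  Unmapped native-named columns pass
        through.
    """
    df = pd.read_csv(path, dtype={"failure_cause": "string"})
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "subject_id" not in df.columns:
        raise ConfigurationError("subject_id: column not found in registry CSV")
    df = df.set_index("subject_id")
    validate_registry(df)
    return df


def write_registry(records: pd.DataFrame, path: str | Path) -> None:
    """Write a registry to CSV (missing covariate cells become empty fields)."""
    out = records.copy()
    out.index.name = "subject_id"
    out.to_csv(path, na_rep="")


def split_cohorts(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the (treated, control) partition of a registry."""
    return (
        records[records["cohort"] == COHORT_TREATED],
        records[records["cohort"] == COHORT_CONTROL],
    )


def treatment_indicator(records: pd.DataFrame) -> np.ndarray:
    """1 for treated rows, 0 for controls."""
    return (records["cohort"] == COHORT_TREATED).to_numpy(dtype=int)


def as_treated_mask(y) -> np.ndarray:
    """Boolean treated mask from cohort labels (strings or 0/1 indicators)."""
    y = np.asarray(y)
    if y.dtype.kind in "biuf":
        return y.astype(bool)
    return (y == COHORT_TREATED) | (y == "1") | (y == "True")
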