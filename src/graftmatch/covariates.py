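"""Matching-covariate specification, complete-case filtering and encoding.

The matcher compares subjects in a numeric feature space.  Continuous and
count covariates are z-scored on the pooled (treated + control) complete-case
sample so that no single covariate dominates a Manhattan sum merely through
its units; nominal covariates are one-hot encoded, so a full mismatch on one
nominal covariate contributes 2 to a Manhattan distance.  Column order is
deterministic: covariates in spec order, one-hot levels lexicographic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EncodingError

KINDS = ("continuous", "count", "nominal")


@dataclass(frozen=True)
class Covariate:
    """One matching covariate: a registry column and its statistical kind."""

    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"{self.name}: unknown covariate kind {self.kind!r}")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("continuous", "count")


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered list of matching covariates.

    The default spec (:func:`default_matching_spec`) carries the six
    recipient covariates used to match the cohorts: BMI, age, cold ischemia
    time, HLA mismatch, ethnicity and sex.  HLA mismatch is treated as an
    ordinal count (z-scored scalar) rather than one-hot.
    """

    covariates: tuple[Covariate, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("covariate names must be unique")
        if not names:
            raise ConfigurationError("covariate spec must not be empty")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def __iter__(self):
        return iter(self.covariates)

    def __len__(self) -> int:
        return len(self.covariates)


def default_matching_spec() -> CovariateSpec:
    """The six matching covariates of the study design."""
    return CovariateSpec(
        (
            Covariate("age", "continuous"),
            Covariate("bmi", "continuous"),
            Covariate("cold_ischemia", "continuous"),
            Covariate("hla_mismatch", "count"),
            Covariate("ethnicity", "nominal"),
            Covariate("sex", "nominal"),
        )
    )


def complete_case_filter(
    records: pd.DataFrame, spec: CovariateSpec | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop records with any missing matching covariate.

    Returns ``(kept, dropped_count)``; outcome columns are never consulted.
    """
    spec = spec or default_matching_spec()
    missing = [c for c in spec.names if c not in records.columns]
    if missing:
        raise ConfigurationError(f"records are missing matching covariates: {missing}")
    cells = records[spec.names]
    blank = cells.isna()
    for c in spec:
        if not pd.api.types.is_numeric_dtype(cells[c.name]):
            blank[c.name] |= (cells[c.name].astype("string") == "").fillna(False)
    keep = ~blank.any(axis=1)
    kept = records[keep]
    return kept, int((~keep).sum())


@dataclass
class EncodedMatrix:
    """Numeric feature matrix used by distance and propensity computations.

    Attributes
    ----------
    values
        ``(n_subjects, n_features)`` float array with no missing entries.
    index
        Subject ids, aligned with the rows of ``values``.
    columns
        Encoded feature names, ``"<covariate>"`` for numeric covariates and
        ``"<covariate>=<level>"`` for one-hot columns.
    sources
        Source covariate per encoded column.
    """

    values: np.ndarray
    index: pd.Index
    columns: list[str]
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise EncodingError("encoded matrix contains missing entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.columns)

    def subset(self, ids: Iterable) -> "EncodedMatrix":
        frame = self.to_frame().loc[list(ids)]
        return EncodedMatrix(frame.to_numpy(), frame.index, list(self.columns), list(self.sources))


def encode(records: pd.DataFrame, spec: CovariateSpec | None = None) -> EncodedMatrix:
    """Encode complete-case records into the matching feature space.

    Continuous/count covariates are z-scored with the mean and SD of the
    *pooled* sample passed in (treated and control together); nominal
    covariates become one-hot blocks with lexicographically ordered levels.

    Raises
    ------
    EncodingError
        If a numeric covariate has zero variance (its z-score is undefined)
        or any matching cell is missing (records must be complete-case).
    """
    spec = spec or default_matching_spec()
    blocks: list[np.ndarray] = []
    columns: list[str] = []
    sources: list[str] = []
    for cov in spec:
        col = records[cov.name]
        if col.isna().any():
            raise EncodingError(f"{cov.name}: missing values; apply complete_case_filter first")
        if cov.is_numeric:
            x = col.to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0.0:
                raise EncodingError(f"{cov.name}: zero variance in pooled sample")
            blocks.append(((x - x.mean()) / sd)[:, None])
            columns.append(cov.name)
            sources.append(cov.name)
        else:
            levels = sorted(col.astype(str).unique())
            onehot = np.stack([(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels], axis=1)
            blocks.append(onehot)
            columns.extend(f"{cov.name}={lv}" for lv in levels)
            sources.extend(cov.name for _ in levels)
    values = np.concatenate(blocks, axis=1)
    return EncodedMatrix(values, records.index.copy(), columns, sources)


def covariate_values(
    records: pd.DataFrame, cov: Covariate, subjects: Sequence | None = None
) -> pd.Series:
    """Raw values of one covariate, optionally restricted to given subjects."""
    col = records[cov.name]
    if subjects is not None:
        col = col.loc[list(subjects)]
    return col
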