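"""Nearest-centroid clustering matcher.

The matcher treats every treated subject as the centroid of its own cluster,
assigns each control to the cluster whose centroid is nearest in the encoded
covariate space (Manhattan distance by default; cosine available), discards
clusters that attracted fewer than ``min_size`` controls, and keeps the ``k``
nearest controls of each surviving cluster.  Because assignment maps each
control to exactly one centroid, the resulting 1:k matched cohort is without
replacement by construction.

All tie-breaks are by subject-id order, so the output is invariant to input
row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .covariates import CovariateSpec, EncodedMatrix, complete_case_filter, default_matching_spec, encode
from .exceptions import ConfigurationError, MatchingError
from .registry import COHORT_CONTROL, COHORT_TREATED, as_treated_mask

logger = logging.getLogger(__name__)

METRICS = ("manhattan", "cosine")
_SCIPY_METRIC = {"manhattan": "cityblock", "cosine": "cosine"}


def distance(u: np.ndarray, v: np.ndarray, metric: str = "manhattan") -> float:
    """Distance between two encoded rows.

    ``manhattan`` is Σ|uᵢ−vᵢ|; ``cosine`` is 1 − u·v/(‖u‖‖v‖) ∈ [0, 2]
    and is undefined (raises) for a zero vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise MatchingError("distance: vectors must have equal dimension")
    if metric == "manhattan":
        return float(np.abs(u - v).sum())
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise MatchingError("cosine distance is undefined for a zero vector")
        return float(1.0 - (u @ v) / (nu * nv))
    raise ConfigurationError(f"metric: unknown metric {metric!r}")


def pairwise_distances(a: EncodedMatrix, b: EncodedMatrix, metric: str) -> np.ndarray:
    if metric not in METRICS:
        raise ConfigurationError(f"metric: unknown metric {metric!r}")
    if metric == "cosine":
        for mat, name in ((a, "first"), (b, "second")):
            if (np.linalg.norm(mat.values, axis=1) == 0).any():
                raise MatchingError(f"cosine distance undefined: zero row in {name} matrix")
    return cdist(a.values, b.values, metric=_SCIPY_METRIC[metric])


@dataclass
class ClusterAssignment:
    """Map from each control to its nearest treated centroid.

    ``table`` has one row per control: ``control_id``, ``treated_id``,
    ``distance``.  Every complete-case control appears exactly once, so the
    assignment partitions the control pool across clusters.
    """

    table: pd.DataFrame
    metric: str
    n_clusters: int  # = number of treated centroids initialised

    def cluster_sizes(self) -> pd.Series:
        return self.table.groupby("treated_id").size()


@dataclass
class MatchedCohort:
    """A 1:k matched cohort.

    ``table`` has one row per matched control: ``matched_set_id`` (the
    treated subject anchoring the set), ``treated_id``, ``control_id``,
    ``distance`` and ``rank`` (1 = closest).  Within a set, distances are
    nondecreasing in rank.  Unless ``with_replacement`` is set, no control
    appears in more than one set.
    """

    table: pd.DataFrame
    method: str
    metric: str
    k: int
    min_size: int | None = None
    with_replacement: bool = False
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def treated_ids(self) -> list:
        return sorted(self.table["treated_id"].unique())

    @property
    def control_ids(self) -> list:
        return list(self.table["control_id"])

    @property
    def subject_ids(self) -> list:
        return self.treated_ids + self.control_ids

    @property
    def n_sets(self) -> int:
        return len(self.treated_ids)

    def validate(self) -> None:
        t = self.table
        if t.empty:
            return
        sizes = t.groupby("matched_set_id").size()
        if (sizes != self.k).any():
            raise MatchingError(f"matched sets must contain exactly k={self.k} controls")
        if not self.with_replacement and t["control_id"].duplicated().any():
            raise MatchingError("control reused across matched sets in without-replacement matching")
        if t.groupby("matched_set_id")["control_id"].nunique().lt(self.k).any():
            raise MatchingError("control reused within a matched set")
        for _, grp in t.groupby("matched_set_id"):
            d = grp.sort_values("rank")["distance"].to_numpy()
            if (np.diff(d) < -1e-12).any():
                raise MatchingError("distances within a matched set must be nondecreasing in rank")
        if (t["distance"] < 0).any():
            raise MatchingError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per matched subject with its role."""
        rows = []
        for set_id, grp in self.table.groupby("matched_set_id", sort=True):
            rows.append(
                {
                    "matched_set_id": set_id, "role": "treated",
                    "subject_id": grp["treated_id"].iloc[0], "distance": 0.0, "rank": 0,
                }
            )
            for _, r in grp.sort_values("rank").iterrows():
                rows.append(
                    {
                        "matched_set_id": set_id, "role": "control",
                        "subject_id": r["control_id"], "distance": r["distance"],
                        "rank": int(r["rank"]),
                    }
                )
        return pd.DataFrame(rows, columns=["matched_set_id", "role", "subject_id", "distance", "rank"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "method": self.method,
            "metric": self.metric,
            "k": self.k,
            "min_size": self.min_size,
            "with_replacement": self.with_replacement,
            "n_matched_sets": self.n_sets,
            "n_matched_controls": len(self.table),
            "stage_counts": dict(self.stage_counts),
        }


def assign_to_centroids(
    treated: EncodedMatrix, controls: EncodedMatrix, metric: str = "manhattan"
) -> ClusterAssignment:
    """Assign every control to the nearest treated centroid.

    One cluster is initialised per treated row.  Ties go to the smallest
    treated subject id.
    """
    if treated.shape[0] == 0:
        raise MatchingError("assign_to_centroids: empty treated set")
    order = np.argsort(treated.index)  # so argmin's first-hit tie-break is the smallest id
    t_sorted = EncodedMatrix(
        treated.values[order], treated.index[order], list(treated.columns), list(treated.sources)
    )
    d = pairwise_distances(t_sorted, controls, metric)
    nearest = np.argmin(d, axis=0)
    table = pd.DataFrame(
        {
            "control_id": controls.index,
            "treated_id": t_sorted.index[nearest],
            "distance": d[nearest, np.arange(d.shape[1])],
        }
    )
    return ClusterAssignment(table=table, metric=metric, n_clusters=treated.shape[0])


def filter_and_select(
    assignment: ClusterAssignment, k: int = 5, min_size: int = 5
) -> MatchedCohort:
    """Drop clusters with fewer than ``min_size`` controls, then keep each
    surviving cluster's ``k`` nearest controls (ties by smallest control id)."""
    if k > min_size:
        raise ConfigurationError("k: selection size k must not exceed min_size")
    if k < 1:
        raise ConfigurationError("k: must be at least 1")
    t = assignment.table
    sizes = t.groupby("treated_id").size()
    surviving = sizes[sizes >= min_size].index
    kept = t[t["treated_id"].isin(surviving)].copy()
    kept = kept.sort_values(["treated_id", "distance", "control_id"], kind="mergesort")
    kept["rank"] = kept.groupby("treated_id").cumcount() + 1
    kept = kept[kept["rank"] <= k]
    kept["matched_set_id"] = kept["treated_id"]
    table = kept[["matched_set_id", "treated_id", "control_id", "distance", "rank"]].reset_index(
        drop=True
    )
    return MatchedCohort(
        table=table,
        method=f"cluster_{assignment.metric}",
        metric=assignment.metric,
        k=k,
        min_size=min_size,
        stage_counts={
            "clusters_initialised": assignment.n_clusters,
            "clusters_surviving": len(surviving),
        },
    )


class CentroidMatcher(BaseEstimator):
    """Nearest-centroid clustering matcher with a scikit-learn interface.

    Parameters
    ----------
    spec : CovariateSpec, optional
        Matching covariates; defaults to the six-covariate study spec.
    metric : {"manhattan", "cosine"}
        Distance used both for centroid assignment and within-cluster
        ranking.
    k : int
        Controls retained per surviving cluster (1:k matching).
    min_size : int
        Minimum cluster size to survive the filter; must be ≥ k.

    After ``fit(X, y)`` — ``X`` a covariate DataFrame indexed by subject id,
    ``y`` cohort labels (``"treated"``/``"control"`` or 1/0) — the fitted
    attributes are ``matched_cohort_``, ``assignment_``, ``n_clusters_``
    and ``stage_counts_``.
    """

    def __init__(
        self,
        spec: CovariateSpec | None = None,
        metric: str = "manhattan",
        k: int = 5,
        min_size: int = 5,
    ):
        self.spec = spec
        self.metric = metric
        self.k = k
        self.min_size = min_size

    def fit(self, X: pd.DataFrame, y=None) -> "CentroidMatcher":
        if y is None:
            raise ValueError("y (cohort labels) is required")
        spec = self.spec or default_matching_spec()
        if self.metric not in METRICS:
            raise ConfigurationError(f"metric: unknown metric {self.metric!r}")
        treated_mask = as_treated_mask(y)
        records = X.copy()

        kept, dropped = complete_case_filter(records, spec)
        kept_mask = records.index.isin(kept.index)
        logger.info("complete-case filter: kept %d, dropped %d", len(kept), dropped)

        encoded = encode(kept, spec)
        treated_ids = records.index[treated_mask & kept_mask]
        control_ids = records.index[~treated_mask & kept_mask]
        logger.info(
            "encoded %d treated and %d controls into %d features",
            len(treated_ids), len(control_ids), encoded.shape[1],
        )

        assignment = assign_to_centroids(
            encoded.subset(treated_ids), encoded.subset(control_ids), self.metric
        )
        logger.info("initialised %d clusters; assigned %d controls", assignment.n_clusters, len(control_ids))

        cohort = filter_and_select(assignment, self.k, self.min_size)
        cohort.stage_counts.update(
            {
                "input_records": len(records),
                "complete_case_kept": len(kept),
                "complete_case_dropped": dropped,
                "n_treated": len(treated_ids),
                "n_controls": len(control_ids),
            }
        )
        logger.info(
            "selected %d matched sets (%d controls)", cohort.n_sets, len(cohort.table)
        )

        self.spec_ = spec
        self.encoded_ = encoded
        self.assignment_ = assignment
        self.n_clusters_ = assignment.n_clusters
        self.matched_cohort_ = cohort
        self.stage_counts_ = cohort.stage_counts
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a record table to the matched subjects."""
        return X.loc[X.index.isin(self.matched_cohort_.subject_ids)]


def cluster_match(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    spec: CovariateSpec | None = None,
    metric: str = "manhattan",
    k: int = 5,
    min_size: int = 5,
) -> MatchedCohort:
    """Functional wrapper over :class:`CentroidMatcher`.

    Runs complete-case filtering, pooled encoding, centroid assignment and
    cluster filtering/selection on the two record tables and returns the
    matched cohort.
    """
    X = pd.concat([treated, control])
    y = np.array([COHORT_TREATED] * len(treated) + [COHORT_CONTROL] * len(control))
    return CentroidMatcher(spec=spec, metric=metric, k=k, min_size=min_size).fit(X, y).matched_cohort_
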