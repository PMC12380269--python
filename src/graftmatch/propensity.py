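"""Propensity-score matching baseline.

A logistic model of treatment membership on the encoded matching covariates
is fit by unpenalised maximum likelihood; greedy 1:k nearest-neighbour
matching on the score then proceeds over treated subjects in a seeded random
order (greedy matching is order-dependent, so the order must be recorded to
be reproducible).  Matching without replacement removes used controls from
the pool and drops treated subjects that cannot obtain k controls; matching
with replacement lets a control serve several matched sets (never twice
within one set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from sklearn.base import BaseEstimator

from .covariates import CovariateSpec, complete_case_filter, default_matching_spec, encode
from .exceptions import FittingError, MatchingError
from .matching import MatchedCohort
from .registry import COHORT_CONTROL, COHORT_TREATED, as_treated_mask

logger = logging.getLogger(__name__)


@dataclass
class PropensityModel:
    """Fitted logistic propensity model.

    ``params`` holds the intercept (``const``) and one coefficient per
    encoded feature; ``scores`` are fitted treatment probabilities per
    subject, strictly inside (0, 1) on non-separable data.
    """

    params: pd.Series
    scores: pd.Series  # indexed by subject_id
    treated_ids: pd.Index
    control_ids: pd.Index

    def __post_init__(self) -> None:
        s = self.scores
        if ((s <= 0) | (s >= 1)).any():
            raise FittingError("propensity scores must lie strictly in (0, 1)")


def fit_propensity(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    spec: CovariateSpec | None = None,
) -> PropensityModel:
    """Fit the propensity model by maximum likelihood on complete cases.

    Raises
    ------
    FittingError
        On perfect separation or non-convergence, with the solver diagnostic.
    """
    spec = spec or default_matching_spec()
    if treated.empty or control.empty:
        raise FittingError("fit_propensity: both groups must be non-empty")
    X = pd.concat([treated, control])
    y = np.concatenate([np.ones(len(treated)), np.zeros(len(control))])
    kept, dropped = complete_case_filter(X, spec)
    if dropped:
        logger.info("fit_propensity: dropped %d incomplete records", dropped)
    y = pd.Series(y, index=X.index)[X.index.isin(kept.index)]
    # canonical row order: the fit (and its floating-point accumulation) is
    # then invariant to the caller's record order
    kept = kept.sort_index()
    y = y.loc[kept.index].to_numpy()
    encoded = encode(kept, spec)
    design = sm.add_constant(encoded.to_frame(), has_constant="add")
    # Drop one reference level per one-hot block: with the intercept the full
    # block is collinear (columns are lexicographic, so the first level of
    # each nominal covariate is the reference).
    drop = []
    seen = set()
    for col, src in zip(encoded.columns, encoded.sources):
        if "=" in col:
            if src in seen:
                continue
            seen.add(src)
            drop.append(col)
    design = design.drop(columns=drop)
    res = None
    errors = []
    for method in ("newton", "bfgs"):  # newton can hit a singular Hessian under quasi-separation
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                candidate = sm.Logit(y, design).fit(disp=0, maxiter=500, method=method)
            if candidate.mle_retvals.get("converged", True):
                res = candidate
                break
            errors.append(f"{method}: did not converge")
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            errors.append(f"{method}: {exc}")
    if res is None:
        raise FittingError(f"propensity fit failed: {'; '.join(errors)}")
    scores = pd.Series(np.asarray(res.predict(design)), index=kept.index, name="propensity")
    if ((scores <= 0) | (scores >= 1)).any():
        raise FittingError("propensity fit produced degenerate scores (perfect separation?)")
    t_scores, c_scores = scores[y == 1], scores[y == 0]
    if t_scores.min() > c_scores.max() or t_scores.max() < c_scores.min():
        raise FittingError(
            "perfect separation: the covariates completely separate treated from "
            "control (disjoint propensity-score ranges); matching on such scores is meaningless"
        )
    return PropensityModel(
        params=res.params,
        scores=scores,
        treated_ids=kept.index[y == 1],
        control_ids=kept.index[y == 0],
    )


def psm_match(
    model: PropensityModel,
    k: int = 5,
    with_replacement: bool = False,
    rng_seed: int = 0,
    caliper: float | None = None,
) -> MatchedCohort:
    """Greedy 1:k nearest-neighbour matching on |score difference|.

    Treated subjects are processed in a seeded random order.  ``caliper``,
    if given, is a maximum score gap in units of the score SD.  Without
    replacement, treated subjects that cannot obtain k (in-caliper) controls
    are dropped — exhausting the pool is an outcome, not an error.
    """
    if k < 1:
        raise MatchingError("k: must be at least 1")
    rng = np.random.default_rng(rng_seed)
    treated_ids = np.sort(np.asarray(model.treated_ids))
    order = rng.permutation(len(treated_ids))
    scores = model.scores
    max_gap = np.inf
    if caliper is not None:
        max_gap = caliper * float(scores.std(ddof=1))

    pool_ids = np.sort(np.asarray(model.control_ids))
    pool_scores = scores.loc[pool_ids].to_numpy()
    available = np.ones(len(pool_ids), dtype=bool)

    rows = []
    n_dropped = 0
    for idx in order:
        tid = treated_ids[idx]
        ts = scores.loc[tid]
        gaps = np.abs(pool_scores - ts)
        cand = available & (gaps <= max_gap) if not with_replacement else (gaps <= max_gap)
        n_cand = int(cand.sum())
        if n_cand < k:
            n_dropped += 1
            continue
        cand_idx = np.flatnonzero(cand)
        # k smallest gaps, ties broken by smallest control id (pool is sorted)
        sel = cand_idx[np.lexsort((pool_ids[cand_idx], gaps[cand_idx]))[:k]]
        sel = sel[np.argsort(gaps[sel], kind="mergesort")]
        for rank, j in enumerate(sel, start=1):
            rows.append(
                {
                    "matched_set_id": tid,
                    "treated_id": tid,
                    "control_id": pool_ids[j],
                    "distance": float(gaps[j]),
                    "rank": rank,
                }
            )
        if not with_replacement:
            available[sel] = False

    method = "psm_with_replacement" if with_replacement else "psm_without_replacement"
    table = pd.DataFrame(
        rows, columns=["matched_set_id", "treated_id", "control_id", "distance", "rank"]
    )
    logger.info("%s: %d matched sets, %d treated dropped", method, len(rows) // k if rows else 0, n_dropped)
    return MatchedCohort(
        table=table,
        method=method,
        metric="propensity_score",
        k=k,
        with_replacement=with_replacement,
        stage_counts={
            "n_treated": len(treated_ids),
            "n_controls": len(pool_ids),
            "treated_dropped": n_dropped,
            "rng_seed": rng_seed,
        },
    )


class PropensityMatcher(BaseEstimator):
    """Propensity-score matcher with a scikit-learn interface.

    ``fit(X, y)`` fits the logistic model on the covariate DataFrame ``X``
    (indexed by subject id) with cohort labels ``y``, then performs greedy
    1:k matching.  Fitted attributes: ``model_``, ``scores_``,
    ``matched_cohort_``.
    """

    def __init__(
        self,
        spec: CovariateSpec | None = None,
        k: int = 5,
        with_replacement: bool = False,
        caliper: float | None = None,
        random_state: int = 0,
    ):
        self.spec = spec
        self.k = k
        self.with_replacement = with_replacement
        self.caliper = caliper
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "PropensityMatcher":
        if y is None:
            raise ValueError("y (cohort labels) is required")
        treated_mask = as_treated_mask(y)
        self.model_ = fit_propensity(X[treated_mask], X[~treated_mask], self.spec)
        self.scores_ = self.model_.scores
        self.matched_cohort_ = psm_match(
            self.model_,
            k=self.k,
            with_replacement=self.with_replacement,
            rng_seed=self.random_state,
            caliper=self.caliper,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a record table to the matched subjects."""
        return X.loc[X.index.isin(self.matched_cohort_.subject_ids)]
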