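"""Nearest-centroid matcher: unit examples, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from graftmatch import (
    CentroidMatcher,
    ConfigurationError,
    MatchingError,
    assign_to_centroids,
    cluster_match,
    distance,
    filter_and_select,
    split_cohorts,
)
from graftmatch.covariates import EncodedMatrix


def _encoded(values: np.ndarray, prefix: str) -> EncodedMatrix:
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"{prefix}{i:04d}" for i in range(len(values))])
    cols = [f"f{j}" for j in range(values.shape[1])]
    return EncodedMatrix(values, idx, cols, cols)


class TestDistance:
    def test_identity_is_zero_under_both_metrics(self):
        u = np.array([1.3, -2.0, 0.5])
        assert distance(u, u, "manhattan") == 0.0
        assert distance(u, u, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_manhattan_hand_sum(self):
        assert distance([0, 0], [3, 4], "manhattan") == 7.0

    def test_cosine_orthogonal_vectors(self):
        assert distance([1, 0], [0, 1], "cosine") == pytest.approx(1.0)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(MatchingError):
            distance([0, 0], [1, 1], "cosine")

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(MatchingError):
            distance([1], [1, 2], "manhattan")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        arrays(float, 4, elements=st.floats(-50, 50)),
        arrays(float, 4, elements=st.floats(-50, 50)),
        arrays(float, 4, elements=st.floats(-50, 50)),
    )
    def test_manhattan_metric_axioms(self, u, v, w):
        duv = distance(u, v, "manhattan")
        assert duv >= 0
        assert duv == pytest.approx(distance(v, u, "manhattan"))
        assert duv <= distance(u, w, "manhattan") + distance(w, v, "manhattan") + 1e-9


class TestAssignToCentroids:
    def test_single_centroid_attracts_all(self):
        treated = _encoded([[0.0, 0.0]], "T")
        controls = _encoded(np.arange(10).reshape(5, 2), "C")
        asg = assign_to_centroids(treated, controls)
        assert (asg.table["treated_id"] == "T0000").all()
        assert asg.n_clusters == 1

    def test_tie_goes_to_smaller_treated_id(self):
        treated = _encoded([[1.0], [-1.0]], "T")  # control at 0 is equidistant
        controls = _encoded([[0.0]], "C")
        asg = assign_to_centroids(treated, controls)
        assert asg.table["treated_id"].iloc[0] == "T0000"

    def test_empty_treated_rejected(self):
        with pytest.raises(MatchingError):
            assign_to_centroids(_encoded(np.empty((0, 2)), "T"), _encoded([[1.0, 2.0]], "C"))

    @pytest.mark.parametrize("metric", ["manhattan", "cosine"])
    def test_matches_exhaustive_nearest_neighbour(self, rng, metric):
        treated = _encoded(rng.normal(size=(50, 6)) + 0.5, "T")
        controls = _encoded(rng.normal(size=(400, 6)) + 0.5, "C")
        asg = assign_to_centroids(treated, controls, metric)
        # independent O(T×C) search using the scalar distance function
        for cid, row in zip(controls.index, controls.values):
            dists = [distance(row, t, metric) for t in treated.values]
            best = int(np.argmin(dists))
            got = asg.table.set_index("control_id").loc[cid]
            assert got["treated_id"] == treated.index[best]
            assert got["distance"] == pytest.approx(dists[best], abs=1e-9)

    def test_partition_property(self, rng):
        treated = _encoded(rng.normal(size=(20, 3)), "T")
        controls = _encoded(rng.normal(size=(150, 3)), "C")
        asg = assign_to_centroids(treated, controls)
        assert sorted(asg.table["control_id"]) == sorted(controls.index)
        assert not asg.table["control_id"].duplicated().any()


class TestFilterAndSelect:
    def _assignment(self, rng, n_t=30, n_c=300):
        treated = _encoded(rng.normal(size=(n_t, 4)), "T")
        controls = _encoded(rng.normal(size=(n_c, 4)), "C")
        return assign_to_centroids(treated, controls)

    def test_k_above_min_size_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            filter_and_select(self._assignment(rng), k=6, min_size=5)

    def test_exactly_k_member_clusters_all_retained(self):
        # 2 centroids at ±10, k controls hugging each: all survive
        treated = _encoded([[-10.0], [10.0]], "T")
        controls = _encoded([[-10.5], [-9.5], [-10.1], [9.5], [10.5], [10.1]], "C")
        cohort = filter_and_select(assign_to_centroids(treated, controls), k=3, min_size=3)
        assert cohort.n_sets == 2
        assert sorted(cohort.control_ids) == sorted(controls.index)

    def test_undersized_cluster_excluded(self):
        treated = _encoded([[-10.0], [10.0]], "T")
        # second centroid attracts only 1 control
        controls = _encoded([[-10.5], [-9.5], [10.0]], "C")
        cohort = filter_and_select(assign_to_centroids(treated, controls), k=2, min_size=2)
        assert cohort.treated_ids == ["T0000"]
        assert "C0002" not in cohort.control_ids

    def test_matches_sort_and_take_k_oracle(self, rng):
        asg = self._assignment(rng)
        cohort = filter_and_select(asg, k=5, min_size=5)
        # brute force: per cluster, sort members by (distance, id), take 5
        expected = {}
        for tid, grp in asg.table.groupby("treated_id"):
            if len(grp) >= 5:
                members = sorted(zip(grp["distance"], grp["control_id"]))[:5]
                expected[tid] = [cid for _, cid in members]
        got = {
            tid: list(grp.sort_values("rank")["control_id"])
            for tid, grp in cohort.table.groupby("treated_id")
        }
        assert got == expected

    def test_min_size_monotonicity(self, rng):
        asg = self._assignment(rng)
        n_sets = [
            filter_and_select(asg, k=3, min_size=m).n_sets for m in (3, 5, 8, 12)
        ]
        assert n_sets == sorted(n_sets, reverse=True)


class TestClusterMatch:
    def test_identical_controls_give_zero_distances(self, small_registry):
        treated, _ = split_cohorts(small_registry)
        clones = pd.concat([treated] * 5)
        clones.index = [f"C{i:06d}" for i in range(len(clones))]
        clones = clones.assign(cohort="control")
        cohort = cluster_match(treated, clones, k=5, min_size=5)
        assert cohort.n_sets > 0
        assert cohort.table["distance"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_ratio_invariant_and_no_duplicates(self, medium_registry):
        treated, control = split_cohorts(medium_registry)
        for metric in ("manhattan", "cosine"):
            cohort = cluster_match(treated, control, metric=metric)
            assert len(cohort.table) == 5 * cohort.n_sets
            assert not cohort.table["control_id"].duplicated().any()

    def test_permutation_invariance(self, small_registry, rng):
        treated, control = split_cohorts(small_registry)
        a = cluster_match(treated, control)
        shuffled_t = treated.sample(frac=1, random_state=4)
        shuffled_c = control.sample(frac=1, random_state=5)
        b = cluster_match(shuffled_t, shuffled_c)
        pa = a.table.sort_values(["matched_set_id", "rank"]).reset_index(drop=True)
        pb = b.table.sort_values(["matched_set_id", "rank"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(pa, pb)

    def test_estimator_interface_round_trip(self, small_registry):
        est = CentroidMatcher(k=3, min_size=4)
        assert est.get_params()["k"] == 3
        est.set_params(k=4)
        y = (small_registry["cohort"] == "treated").astype(int).to_numpy()
        est.fit(small_registry, y)
        assert est.n_clusters_ == int(y.sum())
        matched = est.transform(small_registry)
        assert set(matched.index) == set(est.matched_cohort_.subject_ids)
        sizes = est.matched_cohort_.table.groupby("matched_set_id").size()
        assert (sizes == 4).all()
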