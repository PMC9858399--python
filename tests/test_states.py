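import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from dfnc.states import (
    L1KMeans,
    StatePartition,
    compute_state_metrics,
    kmeans_l1,
    select_k_elbow,
    subject_state_fnc,
)
from dfnc.windows import WindowedFNCSeries, matrix_from_vector


class TestL1KMeans:
    def test_two_cluster_line_example_exact(self):
        """Exhaustively-verifiable optimum: {0,1} vs {10,11} with medians at
        0.5 and 10.5 and total dispersion 2.0."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        est = L1KMeans(2, n_replicates=5, random_state=0).fit(X)
        assert sorted(est.cluster_centers_.ravel()) == [0.5, 10.5]
        assert est.inertia_ == pytest.approx(2.0)

    def test_identical_points_single_cluster_zero_dispersion(self):
        X = np.tile([[1.0, 2.0]], (10, 1))
        est = L1KMeans(1, n_replicates=2, random_state=0).fit(X)
        assert est.inertia_ == 0.0

    def test_converged_centroids_are_member_medians(self, rng):
        X = rng.standard_normal((300, 5))
        est = L1KMeans(3, n_replicates=3, random_state=1).fit(X)
        for j in range(3):
            members = X[est.labels_ == j]
            assert np.allclose(est.cluster_centers_[j], np.median(members, axis=0))

    def test_more_clusters_than_distinct_points_fails(self):
        X = np.tile([[1.0]], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            L1KMeans(2).fit(X)

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((100, 4))
        a = L1KMeans(3, random_state=5).fit(X)
        b = L1KMeans(3, random_state=5).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.cluster_centers_, b.cluster_centers_)

    def test_best_of_replicates_dispersion_non_increasing_in_k(self, rng):
        X = np.vstack([rng.normal(c, 0.3, size=(60, 3)) for c in (0, 3, 6, 9)])
        prev = np.inf
        for k in range(2, 7):
            est = L1KMeans(k, n_replicates=10, random_state=2).fit(X)
            assert est.inertia_ <= prev + 1e-9
            prev = est.inertia_

    def test_predict_matches_training_labels(self, rng):
        X = rng.standard_normal((80, 3))
        est = L1KMeans(4, random_state=3).fit(X)
        assert np.array_equal(est.predict(X), est.labels_)


class TestElbow:
    def test_two_well_separated_blobs_select_two_in_majority(self):
        """Two tight 1-D blobs: splitting a Gaussian blob halves its
        within-cluster spread while only diluting the between-centroid mean,
        so the cluster-index curve has no sharp endpoint elbow and selection
        is a majority property, not a certainty."""
        picks = []
        for s in range(20):
            r = np.random.default_rng(s)
            X = np.concatenate([r.normal(0, 0.5, 200), r.normal(30, 0.5, 200)])[:, None]
            picks.append(select_k_elbow(X, 2, 6, replicates=3, seed=s).chosen_k)
        assert picks.count(2) > len(picks) / 2

    def test_four_separated_blobs_select_four(self, rng):
        X = np.vstack([rng.normal(c, 0.4, size=(80, 4)) for c in (0, 5, 10, 15)])
        res = select_k_elbow(X, 2, 8, replicates=5, seed=1)
        assert res.chosen_k == 4

    def test_curve_recorded_for_every_k(self, rng):
        X = rng.standard_normal((120, 3))
        res = select_k_elbow(X, 2, 5, replicates=2, seed=2)
        assert res.ks == (2, 3, 4, 5)
        assert len(res.cluster_index) == 4

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k_elbow(rng.standard_normal((20, 2)), 4, 4)


class TestStateMetrics:
    def _partition(self, seqs, k):
        return StatePartition(
            k=k, centroids=np.zeros((k, 2)),
            assignments={f"s{i}": np.asarray(q) for i, q in enumerate(seqs)},
            dispersion=0.0,
        )

    def test_hand_counted_example(self):
        m = compute_state_metrics(self._partition([[1, 1, 2, 2, 2, 1]], 2))
        row = m.iloc[0]
        assert row["n_transitions"] == 2
        assert row["state1_ft"] == pytest.approx(0.5)
        assert row["state2_ft"] == pytest.approx(0.5)
        assert row["state1_mdt"] == pytest.approx(1.5)
        assert row["state2_mdt"] == pytest.approx(3.0)

    def test_constant_sequence(self):
        m = compute_state_metrics(self._partition([[1] * 40], 2))
        row = m.iloc[0]
        assert row["n_transitions"] == 0
        assert row["state1_ft"] == 1.0 and row["state1_mdt"] == 40
        assert row["state2_ft"] == 0.0 and row["state2_mdt"] == 0.0

    def test_strict_alternation_over_160_windows(self):
        seq = [1, 2] * 80
        m = compute_state_metrics(self._partition([seq], 2))
        assert m.iloc[0]["n_transitions"] == 159

    def test_seconds_conversion(self):
        m = compute_state_metrics(
            self._partition([[1, 1, 1, 1]], 1), tr_seconds=2.4, step=1, units="seconds"
        )
        assert m.iloc[0]["state1_mdt"] == pytest.approx(4 * 2.4)

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=60))
    def test_conservation_invariants(self, seq):
        """FT sums to one; runs x MDT recover the window count; NT bounds."""
        part = self._partition([seq], 4)
        m = compute_state_metrics(part).iloc[0]
        w = len(seq)
        ft = [m[f"state{k}_ft"] for k in range(1, 5)]
        assert sum(ft) == pytest.approx(1.0, abs=1e-12)
        seq_arr = np.asarray(seq)
        total = 0.0
        for k in range(1, 5):
            changes = np.flatnonzero(np.diff(seq_arr) != 0)
            starts = np.concatenate([[0], changes + 1])
            n_runs = int((seq_arr[starts] == k).sum())
            total += n_runs * m[f"state{k}_mdt"]
        assert total == pytest.approx(w)
        assert m["n_transitions"] <= w - 1
        entered = sum(f > 0 for f in ft)
        assert (m["n_transitions"] == 0) == (entered == 1)


class TestSubjectStateFNC:
    def _series(self, sid, vectors):
        vectors = np.asarray(vectors, dtype=float)
        mats = np.stack([matrix_from_vector(v, 3) for v in vectors])
        return WindowedFNCSeries(sid, np.arange(len(vectors)), mats)

    def test_identical_windows_return_that_vector(self):
        v = np.array([[0.1, 0.2, 0.3]] * 4)
        series = self._series("a", v)
        part = StatePartition(1, np.zeros((1, 3)), {"a": np.ones(4, dtype=int)}, 0.0)
        out = subject_state_fnc(part, [series])
        assert np.allclose(out[1].loc["a"].to_numpy(), [0.1, 0.2, 0.3])

    def test_absent_subject_excluded_from_state_table(self):
        s1 = self._series("a", [[0.1, 0.1, 0.1]] * 3)
        s2 = self._series("b", [[0.5, 0.5, 0.5]] * 3)
        part = StatePartition(
            2, np.zeros((2, 3)),
            {"a": np.array([1, 1, 1]), "b": np.array([2, 2, 2])}, 0.0,
        )
        out = subject_state_fnc(part, [s1, s2])
        assert list(out[1].index) == ["a"]
        assert list(out[2].index) == ["b"]

    def test_median_over_windows(self):
        v = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.9, 0, 0]])
        series = self._series("a", v)
        part = StatePartition(1, np.zeros((1, 3)), {"a": np.ones(3, dtype=int)}, 0.0)
        out = subject_state_fnc(part, [series])
        assert out[1].loc["a"].iloc[0] == pytest.approx(0.2)


class TestAssignmentAccuracy:
    def test_well_separated_states_recovered_above_95_percent(self, rng):
        """With centroid separation > 4x within-state spread, pooled windows
        are reassigned to their generating state almost perfectly."""
        k, p, per = 4, 15, 400
        centroids = rng.uniform(-0.8, 0.8, size=(k, p))
        # enforce L1 separation > 4x expected within-cluster L1 spread
        spread = 0.05
        while True:
            d = cdist(centroids, centroids, "cityblock")
            np.fill_diagonal(d, np.inf)
            if d.min() > 4 * spread * p:
                break
            centroids = rng.uniform(-0.9, 0.9, size=(k, p))
        truth = np.repeat(np.arange(k), per)
        X = centroids[truth] + rng.normal(0, spread, size=(k * per, p))
        est = L1KMeans(k, n_replicates=5, random_state=0).fit(X)
        cm = np.zeros((k, k))
        for t, l in zip(truth, est.labels_):
            cm[t, l] += 1
        r, c = linear_sum_assignment(-cm)
        assert cm[r, c].sum() / len(truth) >= 0.95


def test_kmeans_l1_wrapper_reports_one_based_labels(rng):
    X = rng.standard_normal((50, 3))
    part = kmeans_l1(X, k=3, replicates=3, seed=0)
    labels = part.assignments["pooled"]
    assert labels.min() >= 1 and labels.max() <= 3
    d = cdist(X, part.centroids, "cityblock")
    assert part.dispersion == pytest.approx(d[np.arange(50), labels - 1].sum())
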