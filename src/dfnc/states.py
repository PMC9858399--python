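"""Recurring connectivity states: L1 k-means, elbow selection, state metrics.

Windowed connectivity vectors from all subjects are pooled and clustered
with k-means under the Manhattan (L1) distance; the centroid update is the
componentwise median (the L1 minimizer), so this is k-medians. The number
of states is chosen over k = 2..8 by the elbow criterion applied to the
cluster index I(k) = (mean within-cluster distance to centroid) / (mean
pairwise distance between centroids): the selected k maximizes the
perpendicular distance from (k, I(k)) to the chord joining the curve's
endpoints. Per-subject state metrics follow: fraction time (FT), mean
dwell time (MDT, in windows), and the number of transitions (NT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, ClusterMixin

from .windows import WindowedFNCSeries

__all__ = [
    "L1KMeans",
    "StatePartition",
    "kmeans_l1",
    "cluster_windows",
    "select_k_elbow",
    "ElbowResult",
    "compute_state_metrics",
    "subject_state_fnc",
]


class L1KMeans(ClusterMixin, BaseEstimator):
    """K-means clustering under the Manhattan distance (k-medians).

    Lloyd-style alternation: points are assigned to the nearest centroid by
    L1 distance (ties to the lowest centroid index), centroids are updated
    to the componentwise median of their members, and an emptied cluster is
    re-seeded from the point currently farthest from its assigned centroid.
    The best of ``n_replicates`` independently initialized runs (lowest
    total within-cluster L1 distance) is kept.

    Parameters
    ----------
    n_clusters : int
        Number of states k.
    n_replicates : int, default 10
        Independent restarts ("cycles") per fit.
    max_iter : int, default 200
        Maximum Lloyd iterations per replicate.
    random_state : int or None
        Seed for the replicate initializations.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, P)
    labels_ : ndarray of shape (n_samples,), 0-based
    inertia_ : float
        Total within-cluster L1 distance (dispersion).
    replicate_seeds_ : list of int
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_replicates: int = 10,
        max_iter: int = 200,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def _run_once(self, X: np.ndarray, rng: np.random.Generator):
        n, k = X.shape[0], self.n_clusters
        idx = rng.choice(n, size=k, replace=False)
        # Re-draw while initial centroids collide on duplicate rows.
        for _ in range(100):
            if len(np.unique(X[idx], axis=0)) == k:
                break
            idx = rng.choice(n, size=k, replace=False)
        centroids = X[idx].copy()
        labels = None
        for _ in range(self.max_iter):
            dist = cdist(X, centroids, metric="cityblock")
            new_labels = dist.argmin(axis=1)
            point_dist = dist[np.arange(n), new_labels]
            counts = np.bincount(new_labels, minlength=k)
            for empty in np.flatnonzero(counts == 0):
                far = point_dist.argmax()
                centroids[empty] = X[far]
                new_labels[far] = empty
                point_dist[far] = 0.0
                counts = np.bincount(new_labels, minlength=k)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                centroids[j] = np.median(X[labels == j], axis=0)
        dist = cdist(X, centroids, metric="cityblock")
        labels = dist.argmin(axis=1)
        inertia = float(dist[np.arange(n), labels].sum())
        return centroids, labels, inertia

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (windows, pairs) matrix")
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise ValueError("fewer distinct points than clusters")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        master = np.random.default_rng(self.random_state)
        seeds = master.integers(0, 2**31 - 1, size=self.n_replicates)
        best = None
        for s in seeds:
            result = self._run_once(X, np.random.default_rng(int(s)))
            if best is None or result[2] < best[2]:
                best = result
        self.cluster_centers_, self.labels_, self.inertia_ = best
        self.replicate_seeds_ = [int(s) for s in seeds]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return cdist(X, self.cluster_centers_, metric="cityblock").argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass(frozen=True)
class StatePartition:
    """Clustering outcome: centroids plus per-subject 1-based state labels."""

    k: int
    centroids: np.ndarray
    assignments: dict[str, np.ndarray]
    dispersion: float
    replicate_seeds: tuple[int, ...] = ()

    @property
    def subject_ids(self) -> list[str]:
        return list(self.assignments)

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.assignments[s] for s in self.assignments])


def kmeans_l1(
    vectors: np.ndarray,
    k: int,
    replicates: int = 10,
    max_iter: int = 200,
    seed: int | None = None,
) -> StatePartition:
    """Cluster pooled window vectors; labels reported 1-based."""
    est = L1KMeans(n_clusters=k, n_replicates=replicates, max_iter=max_iter,
                   random_state=seed).fit(vectors)
    return StatePartition(
        k=k,
        centroids=est.cluster_centers_,
        assignments={"pooled": est.labels_ + 1},
        dispersion=est.inertia_,
        replicate_seeds=tuple(est.replicate_seeds_),
    )


def cluster_windows(
    series_list: list[WindowedFNCSeries],
    k: int,
    replicates: int = 10,
    max_iter: int = 200,
    seed: int | None = None,
) -> StatePartition:
    """Pool all subjects' windows, cluster, and split labels back per subject."""
    vectors = np.vstack([s.vectors for s in series_list])
    est = L1KMeans(n_clusters=k, n_replicates=replicates, max_iter=max_iter,
                   random_state=seed).fit(vectors)
    assignments = {}
    offset = 0
    for s in series_list:
        w = s.n_windows
        assignments[s.subject_id] = est.labels_[offset:offset + w] + 1
        offset += w
    return StatePartition(
        k=k,
        centroids=est.cluster_centers_,
        assignments=assignments,
        dispersion=est.inertia_,
        replicate_seeds=tuple(est.replicate_seeds_),
    )


@dataclass(frozen=True)
class ElbowResult:
    """Model-selection record: chosen k and the cluster-index curve."""

    chosen_k: int
    ks: tuple[int, ...]
    cluster_index: tuple[float, ...]
    dispersions: tuple[float, ...]


def _cluster_index(X: np.ndarray, centroids: np.ndarray, inertia: float) -> float:
    within = inertia / X.shape[0]
    between = pdist(centroids, metric="cityblock").mean()
    return within / between


def select_k_elbow(
    vectors: np.ndarray,
    k_min: int = 2,
    k_max: int = 8,
    replicates: int = 10,
    max_iter: int = 200,
    seed: int | None = None,
) -> ElbowResult:
    """Choose k in [k_min, k_max] by the elbow of the cluster-index curve.

    The elbow is the k whose point (k, I(k)) lies farthest below the chord
    joining the curve's endpoints (signed distance, so a point above the
    chord never wins); ties resolve to the smaller k. For the usual
    decreasing convex curve this is the point of maximum perpendicular
    distance from the chord.
    """
    if k_max <= k_min:
        raise ValueError("k_max must exceed k_min")
    X = np.asarray(vectors, dtype=float)
    ks = tuple(range(k_min, k_max + 1))
    index, dispersions = [], []
    for i, k in enumerate(ks):
        sub_seed = None if seed is None else int(seed) + i
        est = L1KMeans(n_clusters=k, n_replicates=replicates, max_iter=max_iter,
                       random_state=sub_seed).fit(X)
        index.append(_cluster_index(X, est.cluster_centers_, est.inertia_))
        dispersions.append(est.inertia_)
    # Vertical gap below the chord is proportional to the perpendicular
    # distance (fixed chord angle), so the argmax is identical.
    slope = (index[-1] - index[0]) / (ks[-1] - ks[0])
    gaps = [index[0] + slope * (k - ks[0]) - i_k for k, i_k in zip(ks, index)]
    chosen = ks[int(np.argmax(gaps))]
    return ElbowResult(chosen_k=chosen, ks=ks, cluster_index=tuple(index),
                       dispersions=tuple(dispersions))


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, lengths) of the maximal constant runs of seq."""
    seq = np.asarray(seq)
    changes = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], changes + 1])
    lengths = np.diff(np.concatenate([starts, [len(seq)]]))
    return seq[starts], lengths


def compute_state_metrics(
    partition: StatePartition,
    tr_seconds: float = 2.4,
    step: int = 1,
    units: str = "windows",
) -> pd.DataFrame:
    """Per-subject FT, MDT and NT from the state assignments.

    FT_k is the fraction of windows assigned to state k; MDT_k the mean
    length of maximal runs of k, in windows (or seconds via
    ``units='seconds'``, i.e. windows * step * TR); NT counts adjacent
    label changes. States never entered get FT = MDT = 0.
    """
    if units not in ("windows", "seconds"):
        raise ValueError("units must be 'windows' or 'seconds'")
    scale = 1.0 if units == "windows" else step * tr_seconds
    rows = []
    for sid, seq in partition.assignments.items():
        seq = np.asarray(seq)
        if seq.size == 0:
            raise ValueError(f"subject {sid}: empty assignment sequence")
        w = len(seq)
        run_labels, run_lengths = _run_lengths(seq)
        row: dict[str, float] = {"subject_id": sid}
        for k in range(1, partition.k + 1):
            row[f"state{k}_ft"] = float((seq == k).sum()) / w
            lens = run_lengths[run_labels == k]
            row[f"state{k}_mdt"] = float(lens.mean()) * scale if lens.size else 0.0
        row["n_transitions"] = int((np.diff(seq) != 0).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def subject_state_fnc(
    partition: StatePartition,
    series_list: list[WindowedFNCSeries],
) -> dict[int, pd.DataFrame]:
    """Per-state connectivity summaries for the subjects who entered the state.

    For each state k, returns a DataFrame (rows = subjects who entered k,
    columns = pair names) holding the elementwise median of that subject's
    windowed vectors assigned to k. Subjects never entering a state are
    absent from its table.
    """
    by_id = {s.subject_id: s for s in series_list}
    out: dict[int, pd.DataFrame] = {}
    for k in range(1, partition.k + 1):
        rows, ids = [], []
        for sid, seq in partition.assignments.items():
            mask = np.asarray(seq) == k
            if not mask.any():
                continue
            vecs = by_id[sid].vectors[mask]
            rows.append(np.median(vecs, axis=0))
            ids.append(sid)
        columns = series_list[0].pair_names if series_list else None
        out[k] = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                              columns=columns)
    return out
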