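"""Meta-state dynamism: independent connectivity patterns and their indices.

Instead of assigning each window to a single state, the meta-state view
models every windowed connectivity vector as a weighted sum of m maximally
independent connectivity patterns (fixed-point ICA on the pooled window
vectors). The per-window pattern weights are discretized into signed
quartiles — sign(weight) x quartile of |weight|, codes in
{-4..-1, 1..4} — and each window's code vector is its meta-state. Four
indices summarize a subject's trajectory through this discrete space:
the number of distinct meta-states occupied, the number of changes between
successive meta-states, the span (largest L1 distance between two occupied
meta-states), and the total L1 distance traveled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA

__all__ = [
    "MetaStateDecomposition",
    "MetaStatePatterns",
    "fit_connectivity_patterns",
    "discretize_weights",
    "metastate_metrics",
    "METASTATE_INDICES",
]

METASTATE_INDICES = ("meta_number", "meta_changes", "meta_span", "meta_distance")


class MetaStateDecomposition(TransformerMixin, BaseEstimator):
    """ICA of pooled windowed-connectivity vectors into m patterns.

    ``fit`` runs fixed-point ICA (with PCA whitening to m components) on a
    (W_total, P) matrix; ``transform`` returns the (n, m) pattern weights.
    A fixed orientation convention makes the decomposition comparable
    across runs: each pattern's largest-magnitude element is positive, and
    patterns are ordered by explained variance (descending).

    Attributes
    ----------
    components_ : ndarray of shape (m, P)
        The independent connectivity patterns.
    explained_energy_ : ndarray of shape (m,)
        Variance contributed by each pattern, used for the ordering.
    """

    def __init__(self, n_patterns: int = 4, random_state: int | None = None,
                 max_iter: int = 1000, tol: float = 1e-6):
        self.n_patterns = n_patterns
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (windows, pairs) matrix")
        n, p = X.shape
        if self.n_patterns > p:
            raise ValueError(f"cannot extract {self.n_patterns} patterns from {p} pairs")
        if n <= self.n_patterns:
            raise ValueError("need more windows than patterns")
        if self.n_patterns < 2:
            raise ValueError("need at least 2 patterns")
        ica = FastICA(
            n_components=self.n_patterns,
            random_state=self.random_state,
            whiten="unit-variance",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        weights = ica.fit_transform(X)          # (n, m) independent weights
        patterns = ica.mixing_.T.copy()         # (m, P)
        # Orientation: largest-|.| element of each pattern positive.
        flips = np.ones(self.n_patterns)
        for i in range(self.n_patterns):
            if patterns[i, np.abs(patterns[i]).argmax()] < 0:
                flips[i] = -1.0
        patterns *= flips[:, None]
        weights = weights * flips[None, :]
        # Order by contributed variance, descending.
        energy = weights.var(axis=0) * (patterns**2).sum(axis=1)
        order = np.argsort(energy)[::-1]
        self.components_ = patterns[order]
        self.explained_energy_ = energy[order]
        self.mean_ = ica.mean_
        self._ica = ica
        self._order = order
        self._flips = flips
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        """Pattern weights for each window, in the fitted orientation/order."""
        X = np.asarray(X, dtype=float)
        # FastICA.transform yields the unflipped sources; reapply orientation.
        w = self._ica.transform(X) * self._flips[None, :]
        return w[:, self._order]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class MetaStatePatterns:
    """Fitted patterns plus each subject's window-by-pattern weights."""

    patterns: np.ndarray                 # (m, P)
    weights: dict[str, np.ndarray]       # subject -> (W, m)
    seed: int | None = None

    @property
    def m(self) -> int:
        return self.patterns.shape[0]

    def pooled_weights(self) -> np.ndarray:
        return np.vstack(list(self.weights.values()))


def fit_connectivity_patterns(
    series_vectors: dict[str, np.ndarray],
    m: int = 4,
    seed: int | None = None,
) -> MetaStatePatterns:
    """Fit m independent patterns to pooled vectors; split weights per subject.

    ``series_vectors`` maps subject id to that subject's (W, P) windowed
    connectivity vectors.
    """
    pooled = np.vstack(list(series_vectors.values()))
    est = MetaStateDecomposition(n_patterns=m, random_state=seed).fit(pooled)
    all_weights = est.transform(pooled)
    weights = {}
    offset = 0
    for sid, vecs in series_vectors.items():
        weights[sid] = all_weights[offset:offset + len(vecs)]
        offset += len(vecs)
    return MetaStatePatterns(patterns=est.components_, weights=weights, seed=seed)


def discretize_weights(patterns: MetaStatePatterns) -> dict[str, np.ndarray]:
    """Signed-quartile meta-state codes per subject.

    Quartile boundaries (25/50/75th percentiles of |weight|) are pooled over
    all subjects and windows per pattern, so meta-state vectors are
    comparable across subjects. Each weight maps to
    sign(weight) x q with q in {1..4} the quartile of |weight| (values on a
    boundary take the lower quartile); an exactly zero weight codes as +1.
    """
    pooled = patterns.pooled_weights()
    absw = np.abs(pooled)
    boundaries = np.percentile(absw, [25, 50, 75], axis=0)  # (3, m)
    out = {}
    for sid, w in patterns.weights.items():
        a = np.abs(w)
        q = 1 + (a[:, None, :] > boundaries[None, :, :]).sum(axis=1)
        sign = np.where(w < 0, -1, 1)
        out[sid] = (sign * q).astype(np.int64)
    return out


def metastate_metrics(trajectories: dict[str, np.ndarray]) -> pd.DataFrame:
    """The four dynamism indices per subject.

    meta_number: distinct meta-states occupied; meta_changes: successive
    windows whose meta-state differs; meta_span: largest L1 distance between
    two occupied meta-states (0 when only one); meta_distance: total L1
    distance traveled along the trajectory.
    """
    rows = []
    for sid, traj in trajectories.items():
        traj = np.asarray(traj)
        if traj.ndim != 2 or traj.shape[0] == 0:
            raise ValueError(f"subject {sid}: trajectory must be a non-empty (W, m) array")
        distinct = np.unique(traj, axis=0)
        diffs = np.abs(np.diff(traj, axis=0)).sum(axis=1)
        span = float(pdist(distinct, metric="cityblock").max()) if len(distinct) > 1 else 0.0
        rows.append({
            "subject_id": sid,
            "meta_number": int(len(distinct)),
            "meta_changes": int((diffs > 0).sum()),
            "meta_span": span,
            "meta_distance": float(diffs.sum()),
        })
    return pd.DataFrame(rows).set_index("subject_id")
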