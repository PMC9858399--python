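"""Tapered sliding-window functional network connectivity.

A rectangular window (default 15 TRs, i.e. 36 s at TR = 2.4 s) is convolved
with a Gaussian (sigma 3 TRs, truncated at +/-8 TRs) to produce a soft taper
of total support L = 31 TRs. The taper slides in steps of 1 TR; within each
window a taper-weighted Pearson correlation matrix is computed across the C
components, or, optionally, an L1-penalized (graphical LASSO) precision is
fit to the weighted covariance to stabilize estimation on short windows.
With the defaults, 190 timepoints yield 160 windows per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .preprocess import SubjectTimecourse

__all__ = [
    "TaperWindow",
    "WindowedFNCSeries",
    "SlidingWindowFNC",
    "build_taper",
    "extract_windows",
    "windowed_fnc",
    "select_glasso_lambda",
    "glasso_windowed_fnc",
    "vectorize_fnc",
    "matrix_from_vector",
    "pair_names",
]


@dataclass(frozen=True)
class TaperWindow:
    """Soft window: rectangle of ``width`` TRs convolved with a Gaussian."""

    weights: np.ndarray
    width: int
    sigma: float
    half_support: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.width + 2 * self.half_support:
            raise ValueError("taper length must be width + 2 * half_support")
        if (w <= 0).any():
            raise ValueError("taper weights must be strictly positive")
        if np.abs(w - w[::-1]).max() > 1e-12:
            raise ValueError("taper must be symmetric about its center")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def width_seconds(self, tr_seconds: float) -> float:
        """Physical duration of the rectangular core."""
        return self.width * tr_seconds


def build_taper(width: int = 15, sigma: float = 3.0, half_support: int = 8) -> TaperWindow:
    """Convolve a width-TR rectangle with a truncated Gaussian, peak at 1."""
    if width < 1 or half_support < 1 or sigma <= 0:
        raise ValueError("require width >= 1, half_support >= 1, sigma > 0")
    offsets = np.arange(-half_support, half_support + 1, dtype=float)
    gauss = np.exp(-(offsets**2) / (2.0 * sigma**2))
    w = np.convolve(np.ones(width), gauss, mode="full")
    w = w / w.max()
    w = (w + w[::-1]) / 2.0  # enforce exact symmetry against fp round-off
    return TaperWindow(w, width=width, sigma=sigma, half_support=half_support)


def extract_windows(T: int, taper: TaperWindow, step: int = 1) -> np.ndarray:
    """0-based inclusive start indices of every window that fits in T points."""
    L = len(taper)
    if step < 1:
        raise ValueError("step must be >= 1")
    if T < L:
        raise ValueError(
            f"time course has {T} points but the taper needs {L}"
        )
    return np.arange(0, T - L + 1, step)


def pair_names(component_names) -> list[str]:
    names = list(component_names)
    c = len(names)
    iu = np.triu_indices(c, k=1)
    return [f"{names[i]}~{names[j]}" for i, j in zip(*iu)]


def vectorize_fnc(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (diagonal excluded, row-major) of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if np.abs(m - m.T).max() > 1e-8:
        raise ValueError("connectivity matrix is not symmetric")
    return m[np.triu_indices(m.shape[0], k=1)]


def matrix_from_vector(vector: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_fnc`; unit diagonal restored."""
    v = np.asarray(vector, dtype=float)
    if n_components is None:
        # P = C (C - 1) / 2
        n_components = int(round((1 + np.sqrt(1 + 8 * len(v))) / 2))
    m = np.eye(n_components)
    iu = np.triu_indices(n_components, k=1)
    if len(v) != len(iu[0]):
        raise ValueError("vector length does not match a triangular count")
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


@dataclass(frozen=True)
class WindowedFNCSeries:
    """Per-subject windowed connectivity: W matrices plus their P-vectors."""

    subject_id: str
    starts: np.ndarray
    matrices: np.ndarray  # (W, C, C)
    estimator: str = "sample"
    lam: float | None = None
    component_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must have shape (W, C, C)")
        object.__setattr__(self, "matrices", m)
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=int))
        if len(self.starts) != m.shape[0]:
            raise ValueError("one start index per window required")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrices.shape[1]

    @property
    def vectors(self) -> np.ndarray:
        """(W, P) matrix of upper-triangle pair values."""
        iu = np.triu_indices(self.n_components, k=1)
        return self.matrices[:, iu[0], iu[1]]

    @property
    def pair_names(self) -> list[str]:
        names = self.component_names or tuple(f"IC{i + 1}" for i in range(self.n_components))
        return pair_names(names)


def _windowed_weighted_cov(x: np.ndarray, taper: TaperWindow, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Taper-weighted covariance for every window: (starts, (W, C, C))."""
    starts = extract_windows(x.shape[0], taper, step)
    L = len(taper)
    p = taper.weights / taper.weights.sum()
    views = sliding_window_view(x, L, axis=0)[starts]  # (W, C, L)
    views = np.swapaxes(views, 1, 2)  # (W, L, C)
    means = np.einsum("wlc,l->wc", views, p)
    centered = views - means[:, None, :]
    cov = np.einsum("wlc,wld,l->wcd", centered, centered, p)
    return starts, cov


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    """Correlation from covariance; zero-variance pairs map to r = 0."""
    var = np.diagonal(cov, axis1=-2, axis2=-1)
    bad = var <= 0
    if bad.any():
        warnings.warn("zero weighted variance in a window; affected pairs set to 0")
    sd = np.sqrt(np.where(bad, 1.0, var))
    corr = cov / (sd[..., :, None] * sd[..., None, :])
    if bad.any():
        mask = bad[..., :, None] | bad[..., None, :]
        corr = np.where(mask, 0.0, corr)
    eye = np.eye(cov.shape[-1], dtype=bool)
    corr[..., eye] = 1.0
    return np.clip(corr, -1.0, 1.0)


def windowed_fnc(
    tc: SubjectTimecourse,
    taper: TaperWindow | None = None,
    step: int = 1,
) -> WindowedFNCSeries:
    """Taper-weighted Pearson correlation matrix for every sliding window."""
    taper = taper or build_taper()
    starts, cov = _windowed_weighted_cov(tc.values, taper, step)
    corr = _cov_to_corr(cov)
    return WindowedFNCSeries(
        subject_id=tc.subject_id, starts=starts, matrices=corr,
        estimator="sample", component_names=tc.component_names,
    )


def _fit_precision(cov: np.ndarray, lam: float):
    """Penalized precision (and covariance) at penalty lam; lam = 0 is the MLE."""
    if lam == 0:
        prec = np.linalg.inv(cov)
        return cov, prec
    with warnings.catch_warnings():
        # near-converged solutions (tiny residual dual gap) are fine here;
        # genuine failures raise and are handled by the callers
        warnings.simplefilter("ignore", ConvergenceWarning)
        cov_est, prec = graphical_lasso(cov, alpha=lam, max_iter=200)
    return cov_est, prec


def glasso_windowed_fnc(
    tc: SubjectTimecourse,
    taper: TaperWindow | None = None,
    step: int = 1,
    lam: float = 0.1,
) -> WindowedFNCSeries:
    """Per-window graphical-LASSO correlation estimates.

    Each window's taper-weighted covariance is replaced by the L1-penalized
    maximum-likelihood covariance before conversion to correlation. At
    lam = 0 this reduces exactly to the sample estimator; windows where the
    solver fails fall back to the sample correlation with a warning.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    taper = taper or build_taper()
    if lam == 0:
        series = windowed_fnc(tc, taper, step)
        return WindowedFNCSeries(
            subject_id=series.subject_id, starts=series.starts,
            matrices=series.matrices, estimator="glasso", lam=0.0,
            component_names=series.component_names,
        )
    starts, covs = _windowed_weighted_cov(tc.values, taper, step)
    out = np.empty_like(covs)
    for w in range(covs.shape[0]):
        try:
            cov_est, _ = _fit_precision(covs[w], lam)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            warnings.warn(f"graphical lasso failed in window {w}; using sample estimate")
            cov_est = covs[w]
        out[w] = cov_est
    corr = _cov_to_corr(out)
    return WindowedFNCSeries(
        subject_id=tc.subject_id, starts=starts, matrices=corr,
        estimator="glasso", lam=lam, component_names=tc.component_names,
    )


def default_lambda_grid() -> np.ndarray:
    """10 logarithmically spaced penalties spanning [1e-3, 1]."""
    return np.logspace(-3, 0, 10)


def select_glasso_lambda(
    tc: SubjectTimecourse,
    taper: TaperWindow | None = None,
    grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    step: int = 1,
) -> float:
    """Pick the penalty maximizing held-out Gaussian log-likelihood.

    Windows are split into ``folds`` contiguous blocks (contiguity respects
    the temporal ordering of overlapping windows). For each candidate
    penalty the precision is fit on the pooled (averaged) training-window
    covariance and scored as ``logdet(Theta) - tr(S_test @ Theta)`` on each
    held-out window covariance. Ties resolve to the smallest penalty; a
    penalty whose fit fails in any fold is excluded.
    """
    taper = taper or build_taper()
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or (grid < 0).any():
        raise ValueError("grid must be non-empty with all penalties >= 0")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    _, covs = _windowed_weighted_cov(tc.values, taper, step)
    n_windows = covs.shape[0]
    if folds > n_windows:
        raise ValueError(f"{folds} folds but only {n_windows} windows")
    blocks = np.array_split(np.arange(n_windows), folds)

    best_lam, best_score = None, -np.inf
    for lam in np.sort(grid):
        scores = []
        ok = True
        for test_idx in blocks:
            train_mask = np.ones(n_windows, dtype=bool)
            train_mask[test_idx] = False
            s_train = covs[train_mask].mean(axis=0)
            try:
                _, prec = _fit_precision(s_train, float(lam))
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                ok = False
                break
            sign, logdet = np.linalg.slogdet(prec)
            if sign <= 0:
                ok = False
                break
            ll = logdet - np.einsum("wij,ji->w", covs[test_idx], prec)
            scores.append(ll.mean())
        if not ok:
            continue
        score = float(np.mean(scores))
        if score > best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise RuntimeError("graphical lasso failed to converge for every penalty")
    return best_lam


class SlidingWindowFNC(TransformerMixin, BaseEstimator):
    """Transformer: (T, C) time course -> (W, P) windowed connectivity vectors.

    Parameters
    ----------
    width, sigma, half_support : taper geometry in TRs (defaults 15, 3, 8,
        total support 31 TRs).
    step : slide step in TRs.
    estimator : "sample" for taper-weighted Pearson correlation, "glasso"
        for the L1-penalized precision route.
    alpha : graphical LASSO penalty (ignored for the sample estimator).
    """

    def __init__(
        self,
        width: int = 15,
        sigma: float = 3.0,
        half_support: int = 8,
        step: int = 1,
        estimator: str = "sample",
        alpha: float = 0.1,
        tr_seconds: float = 2.4,
    ):
        self.width = width
        self.sigma = sigma
        self.half_support = half_support
        self.step = step
        self.estimator = estimator
        self.alpha = alpha
        self.tr_seconds = tr_seconds

    def fit(self, X, y=None):
        if self.estimator not in ("sample", "glasso"):
            raise ValueError("estimator must be 'sample' or 'glasso'")
        X = np.asarray(X, dtype=float)
        self.taper_ = build_taper(self.width, self.sigma, self.half_support)
        if X.ndim != 2 or X.shape[0] < len(self.taper_):
            raise ValueError(
                f"X must be (T, C) with T >= taper support {len(self.taper_)}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def series(self, X, subject_id: str = "subject") -> WindowedFNCSeries:
        tc = X if isinstance(X, SubjectTimecourse) else SubjectTimecourse(
            np.asarray(X, dtype=float), tr_seconds=self.tr_seconds, subject_id=subject_id
        )
        taper = getattr(self, "taper_", None) or build_taper(
            self.width, self.sigma, self.half_support
        )
        if self.estimator == "glasso":
            return glasso_windowed_fnc(tc, taper, self.step, self.alpha)
        return windowed_fnc(tc, taper, self.step)

    def transform(self, X) -> np.ndarray:
        return self.series(X).vectors

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
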