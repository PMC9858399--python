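"""Conditioning of network component time courses before connectivity estimation.

Component time courses coming out of a group decomposition carry slow
scanner drift and occasional motion spikes. Before any correlation is
computed they are conditioned in a fixed order: linear detrend, robust
despiking, and a zero-phase low-pass Butterworth filter (default 0.15 Hz,
order 5). Nuisance regression against, e.g., motion parameters is available
but off by default, since group-level covariate adjustment is usually done
at the statistics stage instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SubjectTimecourse",
    "NuisanceSet",
    "TimecourseConditioner",
    "detrend_linear",
    "despike_mad",
    "butterworth_lowpass",
    "regress_columns",
    "condition_timecourse",
]


@dataclass(frozen=True)
class SubjectTimecourse:
    """One subject's T x C matrix of component signals.

    Parameters
    ----------
    values : ndarray of shape (T, C)
        Signal matrix, rows are timepoints.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    subject_id : str
        Subject identifier.
    component_names : tuple of str
        One label per column.
    """

    values: np.ndarray
    tr_seconds: float = 2.4
    subject_id: str = "subject"
    component_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("timecourse values must be a 2-D (T, C) matrix")
        object.__setattr__(self, "values", values)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        names = tuple(self.component_names)
        if not names:
            names = tuple(f"IC{i + 1}" for i in range(values.shape[1]))
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} component names for {values.shape[1]} columns"
            )
        object.__setattr__(self, "component_names", names)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SubjectTimecourse":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class NuisanceSet:
    """T x R matrix of nuisance regressors (e.g., motion parameters)."""

    regressors: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        object.__setattr__(self, "regressors", regressors)
        names = tuple(self.names)
        if not names:
            names = tuple(f"reg{i + 1}" for i in range(regressors.shape[1]))
        if len(names) != regressors.shape[1]:
            raise ValueError("one name per regressor column required")
        object.__setattr__(self, "names", names)


def _as_matrix(tc: SubjectTimecourse | np.ndarray) -> np.ndarray:
    if isinstance(tc, SubjectTimecourse):
        return tc.values
    return np.asarray(tc, dtype=float)


def _wrap_like(tc: SubjectTimecourse | np.ndarray, values: np.ndarray):
    if isinstance(tc, SubjectTimecourse):
        return tc.with_values(values)
    return values


def detrend_linear(tc: SubjectTimecourse | np.ndarray):
    """Remove the least-squares line (intercept + slope) from each column."""
    x = _as_matrix(tc)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to detrend")
    return _wrap_like(tc, signal.detrend(x, axis=0, type="linear"))


def despike_mad(
    tc: SubjectTimecourse | np.ndarray,
    threshold: float = 3.0,
    window: int = 7,
):
    """Replace outliers with the running median, per column.

    A point is a spike when its deviation from the running median exceeds
    ``threshold`` times the robust sigma 1.4826 * MAD of the column's
    residuals about its median. The running-median residuals themselves are
    unusable as a scale (an odd-window running median reproduces the center
    sample exactly on any locally monotone stretch, so their MAD collapses
    to zero on smooth signals). A truly constant column is returned
    unchanged; when the MAD is zero but isolated nonzero deviations remain
    (a flat trace with a lone spike), those points are still treated as
    spikes.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = _as_matrix(tc).copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        running = ndimage.median_filter(col, size=window, mode="nearest")
        resid = col - running
        mad = np.median(np.abs(col - np.median(col)))
        sigma = 1.4826 * mad
        if sigma > 0:
            spikes = np.abs(resid) > threshold * sigma
        else:
            spikes = np.abs(resid) > 0
        col[spikes] = running[spikes]
    return _wrap_like(tc, x)


def butterworth_lowpass(
    tc: SubjectTimecourse,
    cutoff_hz: float = 0.15,
    order: int = 5,
    tr_seconds: float | None = None,
):
    """Zero-phase (forward-backward) digital Butterworth low-pass filter."""
    if isinstance(tc, SubjectTimecourse):
        tr = tc.tr_seconds if tr_seconds is None else tr_seconds
    elif tr_seconds is None:
        raise ValueError("tr_seconds required for a bare array")
    else:
        tr = tr_seconds
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist:.6g} Hz for TR = {tr} s"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / tr)
    x = _as_matrix(tc)
    return _wrap_like(tc, signal.filtfilt(b, a, x, axis=0))


def regress_columns(
    tc: SubjectTimecourse | np.ndarray,
    nuisance: NuisanceSet | np.ndarray | None,
):
    """Replace each column by its OLS residual against [intercept | regressors].

    An empty regressor set therefore mean-centers the columns.
    """
    x = _as_matrix(tc)
    t = x.shape[0]
    if nuisance is None:
        design = np.ones((t, 1))
    else:
        reg = nuisance.regressors if isinstance(nuisance, NuisanceSet) else np.asarray(nuisance, float)
        reg = reg.reshape(t, -1) if reg.size else np.empty((t, 0))
        if reg.shape[0] != t:
            raise ValueError(
                f"nuisance rows ({reg.shape[0]}) must match timepoints ({t})"
            )
        design = np.column_stack([np.ones(t), reg])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("nuisance design matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return _wrap_like(tc, x - design @ beta)


@dataclass
class ConditioningSettings:
    """Stage toggles and parameters for :func:`condition_timecourse`."""

    detrend: bool = True
    despike: bool = True
    despike_threshold: float = 3.0
    despike_window: int = 7
    lowpass: bool = True
    cutoff_hz: float = 0.15
    order: int = 5
    nuisance: NuisanceSet | None = None


def condition_timecourse(
    tc: SubjectTimecourse,
    settings: ConditioningSettings | None = None,
) -> SubjectTimecourse:
    """Apply detrend -> despike -> low-pass (-> optional nuisance regression)."""
    s = settings or ConditioningSettings()
    out = tc
    if s.detrend:
        out = detrend_linear(out)
    if s.despike:
        out = despike_mad(out, threshold=s.despike_threshold, window=s.despike_window)
    if s.lowpass:
        out = butterworth_lowpass(out, cutoff_hz=s.cutoff_hz, order=s.order)
    if s.nuisance is not None:
        out = regress_columns(out, s.nuisance)
    if not np.all(np.isfinite(out.values)):
        raise ValueError("conditioning produced non-finite values")
    return out


class TimecourseConditioner(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the conditioning chain.

    Operates on a (T, C) array; stateless (``fit`` only validates input),
    so it composes with pipelines applied per subject.

    Parameters
    ----------
    detrend, despike, lowpass : bool
        Stage toggles, applied in that fixed order.
    despike_threshold : float
        Spike threshold in multiples of the robust sigma.
    despike_window : int
        Odd running-median window length.
    cutoff_hz : float
        Low-pass cutoff in Hz; must be below Nyquist for ``tr_seconds``.
    order : int
        Butterworth order.
    tr_seconds : float
        Sampling interval used by the filter design.
    """

    def __init__(
        self,
        detrend: bool = True,
        despike: bool = True,
        lowpass: bool = True,
        despike_threshold: float = 3.0,
        despike_window: int = 7,
        cutoff_hz: float = 0.15,
        order: int = 5,
        tr_seconds: float = 2.4,
    ):
        self.detrend = detrend
        self.despike = despike
        self.lowpass = lowpass
        self.despike_threshold = despike_threshold
        self.despike_window = despike_window
        self.cutoff_hz = cutoff_hz
        self.order = order
        self.tr_seconds = tr_seconds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a (T, C) matrix with T >= 2")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        tc = SubjectTimecourse(np.asarray(X, dtype=float), tr_seconds=self.tr_seconds)
        settings = ConditioningSettings(
            detrend=self.detrend,
            despike=self.despike,
            despike_threshold=self.despike_threshold,
            despike_window=self.despike_window,
            lowpass=self.lowpass,
            cutoff_hz=self.cutoff_hz,
            order=self.order,
        )
        return condition_timecourse(tc, settings).values

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
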