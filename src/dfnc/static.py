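"""Static (time-averaged) functional network connectivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SubjectTimecourse
from .windows import pair_names, vectorize_fnc

__all__ = ["StaticFNCResult", "static_fnc_matrix", "fisher_z"]


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r), elementwise."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StaticFNCResult:
    """One subject's full-scan correlation matrix and its Fisher-z pairs."""

    subject_id: str
    matrix: np.ndarray
    component_names: tuple[str, ...] = ()

    @property
    def zvector(self) -> np.ndarray:
        r = np.clip(vectorize_fnc(self.matrix), -0.999999, 0.999999)
        return fisher_z(r)

    @property
    def pair_names(self) -> list[str]:
        names = self.component_names or tuple(
            f"IC{i + 1}" for i in range(self.matrix.shape[0])
        )
        return pair_names(names)


def static_fnc_matrix(tc: SubjectTimecourse) -> StaticFNCResult:
    """Pearson correlation matrix over the entire conditioned scan."""
    x = tc.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [tc.component_names[i] for i in dead]
        raise ValueError(f"zero-variance component(s): {', '.join(names)}")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return StaticFNCResult(tc.subject_id, corr, tc.component_names)
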