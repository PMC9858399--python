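"""Behavioral correlation screens with false-discovery-rate control.

Connectivity features (static Fisher-z pairs, per-state Fisher-z pairs,
state metrics, meta-state indices) are correlated against the six
behavioral measures with Pearson's r (two-sided t-test p-values, n - 2 df)
and Benjamini-Hochberg FDR correction across a declared family. The family
size may exceed the number of tests actually computed — useful when the
declared correction family counts tests over subjects who never entered a
state — so the step-up is implemented with an explicit family-size m:
adjusted p_(i) = min_{j >= i} m * p_(j) / j, capped at 1 (equivalent to the
usual correction when m equals the number of tests).

Per-state connectivity screens include only subjects who entered the state.
A covariate list switches the screen to partial correlations (both sides
residualized on the covariates, t-test on n - 2 - n_cov df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson_r_p",
    "bh_fdr",
    "correlate_features_behavior",
    "motion_state_qc",
]


@dataclass(frozen=True)
class CorrelationResult:
    """One feature-behavior correlation within a correction family."""

    feature: str
    behavior: str
    n: int
    r: float
    p: float
    q: float = np.nan
    significant: bool = False
    family: str = ""
    family_size: int = 0


def pearson_r_p(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from the t distribution (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def bh_fdr(
    pvalues,
    q: float = 0.05,
    family_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask).

    ``family_size`` defaults to len(pvalues); a larger value treats the
    missing tests of the declared family as unobserved (never-rejected)
    members, which only makes the correction more conservative.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size cannot be smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out, out <= q


def _residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(values)), covariates])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _corr_with_optional_covariates(x, y, cov: np.ndarray | None):
    if cov is None:
        return pearson_r_p(x, y)
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[mask], y[mask], cov[mask]
    n = len(x)
    k = cov.shape[1]
    if n < 3 + k:
        raise ValueError("too few observations for partial correlation")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p, n


def correlate_features_behavior(
    features: pd.DataFrame,
    behavior: pd.DataFrame,
    family: str = "screen",
    q: float = 0.05,
    family_size: int | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate every feature column with every behavioral measure.

    Rows are aligned on subject id (inner join); per-test NaNs drop that
    subject from that test only, which is how per-state features restrict
    to subjects who entered the state. Returns a tidy DataFrame with
    columns feature, behavior, n, r, p, q, significant, family,
    family_size, FDR-corrected across the declared family.
    """
    measure_cols = [c for c in behavior.columns if covariates is None or c not in covariates]
    common = features.index.intersection(behavior.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between features and behavior")
    f = features.loc[common]
    b = behavior.loc[common]
    cov = None
    if covariates:
        missing = [c for c in covariates if c not in behavior.columns]
        if missing:
            raise ValueError(f"covariates not in behavior table: {missing}")
        cov = b[covariates].to_numpy(dtype=float)
        measure_cols = [c for c in b.columns if c not in covariates]
    rows = []
    for feat in f.columns:
        for measure in measure_cols:
            try:
                r, p, n = _corr_with_optional_covariates(
                    f[feat].to_numpy(dtype=float),
                    b[measure].to_numpy(dtype=float),
                    cov,
                )
            except ValueError as err:
                # degenerate test (too few complete pairs, or a constant
                # side); skip it rather than abort the whole screen
                warnings.warn(f"skipping {feat} ~ {measure}: {err}")
                continue
            rows.append({"feature": feat, "behavior": measure, "n": n, "r": r, "p": p})
    if not rows:
        raise ValueError("no computable feature-behavior tests")
    out = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(out)
    adj, reject = bh_fdr(out["p"].to_numpy(), q=q, family_size=m)
    out["q"] = adj
    out["significant"] = reject
    out["family"] = family
    out["family_size"] = m
    return out


def motion_state_qc(
    occupancy: pd.DataFrame,
    mean_fd: pd.Series,
) -> pd.DataFrame:
    """Raw Pearson screen of state occupancy (FT) against mean framewise
    displacement; reported uncorrected, flagged when p < 0.05."""
    common = occupancy.index.intersection(mean_fd.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between occupancy and motion tables")
    occ = occupancy.loc[common]
    fd = mean_fd.loc[common].to_numpy(dtype=float)
    rows = []
    for col in occ.columns:
        r, p, n = pearson_r_p(occ[col].to_numpy(dtype=float), fd)
        rows.append({"state": col, "n": n, "r": r, "p": p, "flagged": p < 0.05})
    return pd.DataFrame(rows)
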