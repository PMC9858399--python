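"""Synthetic resting-state cohorts with Markov-switching connectivity states.

The generator emulates the study design the pipeline targets: a cohort of
adolescents (default 80) each contributing 190 retained BOLD timepoints
(TR = 2.4 s) across the six triple-network components (dorsal/posterior
default mode, right/left executive control, salience). Latent brain states
follow a first-order Markov chain; given the state, timepoints are i.i.d.
zero-mean Gaussian draws with that state's correlation matrix. Behavioral
scores are drawn around published cohort means/SDs, with configurable
correlations planted against ground-truth dynamic features so that the
downstream statistical screens have known effects to recover.

Emissions are deliberately i.i.d. within state (no temporal
autocorrelation): windowed correlations then estimate the state matrix
without bias, which keeps every downstream stage testable against the
generating truth.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import SubjectTimecourse

__all__ = [
    "StateCovarianceSet",
    "MarkovModel",
    "PlantedEffect",
    "CohortConfig",
    "SyntheticCohort",
    "BEHAVIOR_MEASURES",
    "DEFAULT_BEHAVIOR_MOMENTS",
    "DEFAULT_EFFECTS",
    "DEFAULT_COMPONENTS",
    "make_default_states",
    "simulate_state_sequence",
    "simulate_subject_timecourse",
    "simulate_behavior_table",
    "generate_cohort",
    "true_state_features",
]

DEFAULT_COMPONENTS = ("dDMN", "pdDMN", "pvDMN", "rECN", "lECN", "SN")

#: The six behavioral measures the screens correlate against.
BEHAVIOR_MEASURES = (
    "YSR Attention Problems",
    "YSR ADHD",
    "UPPS Urgency",
    "UPPS Lack of Premeditation",
    "UPPS Lack of Perseverance",
    "UPPS Sensation Seeking",
)

#: Cohort means and standard deviations for each measure (T-scores for the
#: YSR scales, 1-4 Likert means for the UPPS facets).
DEFAULT_BEHAVIOR_MOMENTS: dict[str, tuple[float, float]] = {
    "YSR Attention Problems": (57.19, 6.85),
    "YSR ADHD": (57.00, 6.67),
    "UPPS Urgency": (2.46, 0.66),
    "UPPS Lack of Premeditation": (2.21, 0.63),
    "UPPS Lack of Perseverance": (2.04, 0.64),
    "UPPS Sensation Seeking": (2.82, 0.64),
}

_EDGE_FEATURE_RE = re.compile(r"^state(\d+)_edge_(.+)~(.+)$")


@dataclass(frozen=True)
class StateCovarianceSet:
    """K symmetric positive-definite correlation matrices, one per latent state."""

    covariances: tuple[np.ndarray, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mats = tuple(np.asarray(m, dtype=float) for m in self.covariances)
        for i, m in enumerate(mats):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"state {i + 1}: covariance must be square")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"state {i + 1}: covariance must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ValueError(f"state {i + 1}: diagonal entries must be 1")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"state {i + 1}: covariance is not positive definite")
            off = m[~np.eye(m.shape[0], dtype=bool)]
            if off.size and np.abs(off).max() >= 1.0:
                raise ValueError(f"state {i + 1}: off-diagonal entries must be in (-1, 1)")
        object.__setattr__(self, "covariances", mats)
        labels = tuple(self.labels) or tuple(f"state{i + 1}" for i in range(len(mats)))
        if len(labels) != len(mats):
            raise ValueError("one label per state required")
        object.__setattr__(self, "labels", labels)

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_components(self) -> int:
        return self.covariances[0].shape[0]


@dataclass(frozen=True)
class MarkovModel:
    """Row-stochastic transition matrix plus initial distribution."""

    transition: np.ndarray
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if (t < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "transition", t)
        init = self.initial
        if init is None:
            init = np.full(t.shape[0], 1.0 / t.shape[0])
        init = np.asarray(init, dtype=float)
        if init.shape != (t.shape[0],) or (init < 0).any() or not np.isclose(init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must be a probability vector of length K")
        object.__setattr__(self, "initial", init)

    @classmethod
    def uniform_sticky(cls, n_states: int, self_transition: float = 0.90) -> "MarkovModel":
        """Chain with a common self-transition and uniform off-diagonal mass."""
        if not 0.0 <= self_transition <= 1.0:
            raise ValueError("self_transition must be in [0, 1]")
        if n_states == 1:
            return cls(np.ones((1, 1)))
        off = (1.0 - self_transition) / (n_states - 1)
        t = np.full((n_states, n_states), off)
        np.fill_diagonal(t, self_transition)
        return cls(t)


@dataclass(frozen=True)
class PlantedEffect:
    """A target Pearson correlation between a dynamic feature and a measure."""

    feature: str
    behavior: str
    rho: float

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1.0:
            raise ValueError("|rho| must be < 1")
        if self.behavior not in BEHAVIOR_MEASURES:
            raise ValueError(f"unknown behavioral measure {self.behavior!r}")


#: Default planted effects: State-1 lECN~SN edge strength against both
#: attention measures, State-3 dwell time against ADHD and perseverance,
#: and overall switching (transition count) against ADHD.
DEFAULT_EFFECTS: tuple[PlantedEffect, ...] = (
    PlantedEffect("state1_edge_lECN~SN", "YSR Attention Problems", -0.39),
    PlantedEffect("state1_edge_lECN~SN", "YSR ADHD", -0.38),
    PlantedEffect("state3_mdt", "YSR ADHD", 0.30),
    PlantedEffect("state3_mdt", "UPPS Lack of Perseverance", 0.33),
    PlantedEffect("n_transitions", "YSR ADHD", 0.35),
)


def _project_to_correlation(m: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-ish valid correlation matrix: clip eigenvalues, rescale diagonal."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() < eig_floor:
        m = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def _curated_patterns(c: int) -> list[np.ndarray]:
    """Base off-diagonal patterns for the four canonical six-component states.

    Entries are unit-scale; the actual off-diagonal magnitude is
    ``separation`` times these values. Indices follow DEFAULT_COMPONENTS:
    0 dDMN, 1 pdDMN, 2 pvDMN, 3 rECN, 4 lECN, 5 SN.
    """
    patterns = []
    # State 1: posterior DMN / ECN weakly coupled, strong pdDMN-pvDMN and
    # pdDMN-rECN, salience row silent.
    b = np.zeros((c, c))
    core = [0, 1, 2, 3, 4]
    for i in core:
        for j in core:
            if i != j:
                b[i, j] = 0.4
    b[1, 2] = b[2, 1] = 1.0
    b[1, 3] = b[3, 1] = 1.0
    patterns.append(b)
    # State 2: DMN and ECN internally coherent, anticorrelated with each
    # other; DMN moderately coupled to SN.
    b = np.zeros((c, c))
    dmn, ecn, sn = [0, 1, 2], [3, 4], 5
    for grp in (dmn, ecn):
        for i in grp:
            for j in grp:
                if i != j:
                    b[i, j] = 1.0
    for i in dmn:
        for j in ecn:
            b[i, j] = b[j, i] = -0.7
        b[i, sn] = b[sn, i] = 0.5
    patterns.append(b)
    # State 3: globally hyperconnected.
    b = np.full((c, c), 0.8)
    np.fill_diagonal(b, 0.0)
    patterns.append(b)
    # State 4: isolated strong pvDMN-SN dyad, the pair uncorrelated-to-
    # anticorrelated with a coherent remainder.
    b = np.zeros((c, c))
    rest = [0, 1, 3, 4]
    for i in rest:
        for j in rest:
            if i != j:
                b[i, j] = 0.6
        for j in (2, 5):
            b[i, j] = b[j, i] = -0.4
    b[2, 5] = b[5, 2] = 1.0
    patterns.append(b)
    return patterns


def _procedural_pattern(c: int, k: int) -> np.ndarray:
    """Deterministic block-ish pattern for state index k at arbitrary C."""
    i = np.arange(c)
    u = np.cos(np.pi * (k + 1) * (i + 0.5) / c)
    b = np.outer(u, u)
    np.fill_diagonal(b, 0.0)
    peak = np.abs(b).max()
    return b / peak if peak > 0 else b


def make_default_states(
    C: int = 6,
    K: int = 4,
    separation: float = 0.6,
    labels: tuple[str, ...] = (),
) -> StateCovarianceSet:
    """Build K template state correlation matrices with C components.

    For the canonical six-component configuration the four templates
    qualitatively reproduce the recurring resting-state patterns: (1) a
    posterior-DMN/ECN ensemble with a silent salience row, (2) DMN vs ECN
    antagonism with moderate DMN-SN coupling, (3) global hyperconnectivity
    (every off-diagonal positive), and (4) an isolated pvDMN-SN dyad.
    ``separation`` scales all off-diagonal magnitudes; zero gives identity
    matrices. Any template that is not positive definite after scaling is
    repaired by eigenvalue clipping and diagonal rescaling.
    """
    if C < 2 or K < 1:
        raise ValueError("need C >= 2 components and K >= 1 states")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if C == 6 and K <= 4:
        bases = _curated_patterns(C)[:K]
    else:
        bases = [_procedural_pattern(C, k) for k in range(K)]
    mats = []
    for k, b in enumerate(bases):
        m = np.eye(C) + separation * b
        m = np.clip(m, -0.97, 0.97)
        np.fill_diagonal(m, 1.0)
        m = _project_to_correlation(m)
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError(f"state {k + 1}: not positive definite after projection")
        mats.append(m)
    return StateCovarianceSet(tuple(mats), labels)


def simulate_state_sequence(
    model: MarkovModel,
    T: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw a length-T latent state sequence (0-based labels) from the chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = model.transition.shape[0]
    # Inverse-CDF sampling from one uniform per step keeps this reproducible
    # and cheap for the short sequences involved.
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=1)
    u = rng.random(T)
    seq = np.empty(T, dtype=np.int64)
    seq[0] = np.searchsorted(cum_init, u[0], side="right").clip(0, k - 1)
    for t in range(1, T):
        seq[t] = np.searchsorted(cum_trans[seq[t - 1]], u[t], side="right").clip(0, k - 1)
    return seq


def simulate_subject_timecourse(
    states: StateCovarianceSet,
    sequence: np.ndarray,
    seed: int | np.random.Generator,
    tr_seconds: float = 2.4,
    subject_id: str = "subject",
    component_names: tuple[str, ...] = (),
) -> SubjectTimecourse:
    """Emit one Gaussian draw per timepoint with the active state's covariance."""
    sequence = np.asarray(sequence, dtype=int)
    if sequence.min(initial=0) < 0 or sequence.max(initial=0) >= states.n_states:
        raise ValueError("sequence labels must index into the state set")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = states.n_components
    z = rng.standard_normal((len(sequence), c))
    chols = [np.linalg.cholesky(m) for m in states.covariances]
    x = np.empty_like(z)
    for k in range(states.n_states):
        mask = sequence == k
        if mask.any():
            x[mask] = z[mask] @ chols[k].T
    names = component_names or (DEFAULT_COMPONENTS if c == 6 else ())
    return SubjectTimecourse(x, tr_seconds=tr_seconds, subject_id=subject_id,
                             component_names=names)


def simulate_behavior_table(
    features: pd.DataFrame,
    effects: tuple[PlantedEffect, ...] = DEFAULT_EFFECTS,
    means_sds: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw the six behavioral measures with planted feature correlations.

    Each measure b with planted effects (f_i, rho_i) is generated as

        b = mean_b + sd_b * (sum_i rho_i * z(f_i) + sqrt(1 - sum_i rho_i^2) * eps)

    with eps standard normal and z() the within-cohort z-score, so the
    population correlation of b with each planted feature is rho_i (up to
    correlations among the features themselves). Measures with no planted
    effect are pure noise around their mean.
    """
    moments = dict(DEFAULT_BEHAVIOR_MOMENTS)
    if means_sds:
        moments.update(means_sds)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seen: set[tuple[str, str]] = set()
    for e in effects:
        if e.feature not in features.columns:
            raise ValueError(f"planted feature {e.feature!r} not in feature table")
        key = (e.feature, e.behavior)
        if key in seen:
            raise ValueError(f"duplicate planted effect for {key}")
        seen.add(key)
    n = len(features)
    out = {}
    for measure in BEHAVIOR_MEASURES:
        mean, sd = moments[measure]
        mine = [e for e in effects if e.behavior == measure]
        rho_sq = sum(e.rho**2 for e in mine)
        if rho_sq >= 1.0:
            raise ValueError(f"planted effects for {measure!r} have sum rho^2 >= 1")
        signal = np.zeros(n)
        for e in mine:
            f = features[e.feature].to_numpy(dtype=float)
            std = f.std()
            if std == 0:
                # Degenerate cohort (e.g. a single subject): no variance to
                # correlate against, so the effect contributes nothing.
                warnings.warn(
                    f"feature {e.feature!r} has zero variance; planted effect inert"
                )
                continue
            signal += e.rho * (f - f.mean()) / std
        eps = rng.standard_normal(n)
        out[measure] = mean + sd * (signal + np.sqrt(1.0 - rho_sq) * eps)
    return pd.DataFrame(out, index=features.index)


def true_state_features(sequences: list[np.ndarray], n_states: int) -> pd.DataFrame:
    """Ground-truth dynamic features from the latent state sequences.

    Columns: state{k}_ft, state{k}_mdt (fraction of timepoints and mean run
    length in timepoints, 0 when never entered), and n_transitions.
    """
    rows = []
    for seq in sequences:
        seq = np.asarray(seq)
        t = len(seq)
        row: dict[str, float] = {}
        changes = np.flatnonzero(np.diff(seq) != 0)
        run_starts = np.concatenate([[0], changes + 1])
        run_labels = seq[run_starts]
        run_lengths = np.diff(np.concatenate([run_starts, [t]]))
        for k in range(n_states):
            row[f"state{k + 1}_ft"] = float((seq == k).sum()) / t
            lens = run_lengths[run_labels == k]
            row[f"state{k + 1}_mdt"] = float(lens.mean()) if lens.size else 0.0
        row["n_transitions"] = float(len(changes))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition settings for :func:`generate_cohort`."""

    n_subjects: int = 80
    n_timepoints: int = 190
    n_components: int = 6
    n_states: int = 4
    tr_seconds: float = 2.4
    separation: float = 0.6
    self_transition: float = 0.90
    component_names: tuple[str, ...] = DEFAULT_COMPONENTS
    effects: tuple[PlantedEffect, ...] = DEFAULT_EFFECTS
    behavior_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_MOMENTS)
    )
    edge_effect_sd: float = 0.15
    include_motion: bool = True
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort with its ground truth retained."""

    subjects: tuple[SubjectTimecourse, ...]
    true_state_sequences: tuple[np.ndarray, ...]
    behavior: pd.DataFrame
    features: pd.DataFrame
    states: StateCovarianceSet
    config: CohortConfig
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _edge_features_from_effects(
    effects: tuple[PlantedEffect, ...],
    component_names: tuple[str, ...],
    n_states: int,
) -> list[tuple[str, int, int, int]]:
    """Resolve edge-feature names to (name, state index, i, j) triples."""
    out = []
    for e in effects:
        m = _EDGE_FEATURE_RE.match(e.feature)
        if m is None:
            continue
        k = int(m.group(1)) - 1
        a, b = m.group(2), m.group(3)
        if k < 0 or k >= n_states:
            raise ValueError(f"{e.feature!r}: state index out of range")
        try:
            i, j = component_names.index(a), component_names.index(b)
        except ValueError as err:
            raise ValueError(f"{e.feature!r}: unknown component in pair") from err
        if (e.feature, k, i, j) not in out:
            out.append((e.feature, k, i, j))
    return out


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort: time courses, truth, behavior.

    Per-subject edge effects are planted by perturbing the named state's
    correlation entry with a subject-specific Gaussian offset (clipped so
    the entry stays inside (-0.95, 0.95), then re-projected to a valid
    correlation matrix); the realized offset is the ground-truth feature
    the behavioral score is correlated against.
    """
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_components == 6 and len(cfg.component_names) != 6:
        raise ValueError("component_names must match n_components")
    names = tuple(cfg.component_names[: cfg.n_components]) if cfg.component_names else ()
    base_states = make_default_states(cfg.n_components, cfg.n_states, cfg.separation)
    chain = MarkovModel.uniform_sticky(cfg.n_states, cfg.self_transition)
    edge_specs = _edge_features_from_effects(cfg.effects, names, cfg.n_states)

    subjects = []
    sequences = []
    edge_values: dict[str, list[float]] = {name: [] for name, *_ in edge_specs}
    width = max(3, len(str(cfg.n_subjects)))
    for s in range(cfg.n_subjects):
        sid = f"sub-{s + 1:0{width}d}"
        seq = simulate_state_sequence(chain, cfg.n_timepoints, rng)
        # Subject-specific state matrices carry the planted edge offsets.
        mats = [m.copy() for m in base_states.covariances]
        for name, k, i, j in edge_specs:
            offset = rng.normal(0.0, cfg.edge_effect_sd)
            target = np.clip(mats[k][i, j] + offset, -0.95, 0.95)
            realized = target - base_states.covariances[k][i, j]
            mats[k][i, j] = mats[k][j, i] = target
            mats[k] = _project_to_correlation(mats[k])
            edge_values[name].append(realized)
        subject_states = StateCovarianceSet(tuple(mats)) if edge_specs else base_states
        tc = simulate_subject_timecourse(
            subject_states, seq, rng, tr_seconds=cfg.tr_seconds,
            subject_id=sid, component_names=names,
        )
        subjects.append(tc)
        sequences.append(seq)

    features = true_state_features(sequences, cfg.n_states)
    features.index = pd.Index([s.subject_id for s in subjects], name="subject_id")
    for name, vals in edge_values.items():
        features[name] = vals

    behavior = simulate_behavior_table(features, cfg.effects, cfg.behavior_moments, rng)
    if cfg.include_motion:
        # Null motion summary: independent of every dynamic feature.
        behavior["mean_fd"] = rng.lognormal(mean=np.log(0.15), sigma=0.35, size=len(behavior))
    behavior.index.name = "subject_id"

    return SyntheticCohort(
        subjects=tuple(subjects),
        true_state_sequences=tuple(sequences),
        behavior=behavior,
        features=features,
        states=base_states,
        config=cfg,
        seed=cfg.seed,
    )
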