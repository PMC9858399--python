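"""Plain-text interchange: time-course TSVs, behavior CSVs, run artifacts.

The pipeline's natural inputs are post-decomposition component time
courses, for which there is no community binary standard, so everything is
TSV/CSV/JSON. The time-course reader is strict: ragged rows, non-numeric
cells and duplicate component names fail with the offending line number
rather than being silently coerced.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import SubjectTimecourse
from .synthetic import BEHAVIOR_MEASURES, SyntheticCohort
from .windows import WindowedFNCSeries

__all__ = [
    "AnalysisConfig",
    "read_timecourse_matrix",
    "write_timecourse_matrix",
    "read_behavior_table",
    "write_behavior_table",
    "write_cohort",
    "read_cohort_timecourses",
    "write_windowed_series",
    "file_checksum",
]


@dataclasses.dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the study's defaults."""

    # taper / window geometry (TRs)
    window_width: int = 15
    window_sigma: float = 3.0
    window_half_support: int = 8
    window_step: int = 1
    tr_seconds: float = 2.4
    # connectivity estimator
    estimator: str = "sample"          # "sample" | "glasso"
    glasso_lambda: float | str = "cv"  # penalty, or "cv" for per-subject selection
    glasso_folds: int = 5
    # state clustering
    k_min: int = 2
    k_max: int = 8
    n_states: int | None = None        # fixed k; None -> elbow selection
    replicates: int = 10
    max_iter: int = 200
    # meta-states
    n_patterns: int = 4
    # preprocessing
    cutoff_hz: float = 0.15
    filter_order: int = 5
    despike_threshold: float = 3.0
    despike_window: int = 7
    # statistics
    q_threshold: float = 0.05
    state_fnc_family_size: int | None = None    # None -> literal test count
    # cohort simulation
    n_subjects: int = 80
    n_timepoints: int = 190
    n_components: int = 6
    sim_states: int = 4
    separation: float = 0.6
    self_transition: float = 0.90
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_timecourse_matrix(
    path: str | Path,
    tr_seconds: float = 2.4,
    subject_id: str | None = None,
) -> SubjectTimecourse:
    """Read a T x C TSV (header row of component names) strictly."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        names = [h.strip() for h in header]
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicate component names in header")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(names):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(names)} fields, got {len(row)}"
                )
            try:
                rows.append([float(v) for v in row])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return SubjectTimecourse(
        np.asarray(rows, dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        component_names=tuple(names),
    )


def write_timecourse_matrix(tc: SubjectTimecourse, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(tc.values, columns=list(tc.component_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    """Behavior CSV keyed by subject id; extra columns kept as covariates."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids: {dupes}")
    missing = [m for m in BEHAVIOR_MEASURES if m not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing behavioral measures: {missing}")
    df = df.set_index("subject_id")
    if not np.isfinite(df[list(BEHAVIOR_MEASURES)].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite behavioral values")
    return df


def write_behavior_table(behavior: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    behavior.to_csv(path, index=True)
    return path


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """One TSV per subject, a manifest CSV, behavior CSV, truth-state TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tc_dir = outdir / "timecourses"
    tc_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for tc in cohort.subjects:
        p = write_timecourse_matrix(tc, tc_dir / f"{tc.subject_id}.tsv")
        manifest_rows.append({
            "subject_id": tc.subject_id,
            "file": str(p.relative_to(outdir)),
            "n_timepoints": tc.n_timepoints,
            "tr_seconds": tc.tr_seconds,
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    behavior = write_behavior_table(cohort.behavior, outdir / "behavior.csv")
    truth = outdir / "true_states.tsv"
    with truth.open("w") as fh:
        t = cohort.subjects[0].n_timepoints
        fh.write("subject_id\t" + "\t".join(f"t{i}" for i in range(t)) + "\n")
        for tc, seq in zip(cohort.subjects, cohort.true_state_sequences):
            fh.write(tc.subject_id + "\t" + "\t".join(str(int(s) + 1) for s in seq) + "\n")
    features = outdir / "true_features.csv"
    cohort.features.to_csv(features)
    return {"manifest": manifest, "behavior": behavior, "true_states": truth,
            "true_features": features, "timecourse_dir": tc_dir}


def read_cohort_timecourses(
    manifest_path: str | Path,
    tr_seconds: float = 2.4,
) -> list[SubjectTimecourse]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent
    out = []
    for _, row in manifest.iterrows():
        tr = float(row["tr_seconds"]) if "tr_seconds" in row else tr_seconds
        out.append(read_timecourse_matrix(root / row["file"], tr_seconds=tr,
                                          subject_id=str(row["subject_id"])))
    return out


def write_windowed_series(series: WindowedFNCSeries, outdir: str | Path) -> tuple[Path, Path]:
    """Per-subject TSV of W x P pair values plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{series.subject_id}_windows.tsv"
    df = pd.DataFrame(series.vectors, columns=series.pair_names)
    df.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    sidecar = outdir / f"{series.subject_id}_windows.json"
    sidecar.write_text(json.dumps({
        "subject_id": series.subject_id,
        "starts": [int(s) for s in series.starts],
        "n_windows": int(series.n_windows),
        "step": int(series.starts[1] - series.starts[0]) if len(series.starts) > 1 else 1,
        "estimator": series.estimator,
        "lambda": series.lam,
    }, indent=2))
    return tsv, sidecar


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
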