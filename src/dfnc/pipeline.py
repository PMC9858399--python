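"""End-to-end orchestration: cohort -> conditioning -> connectivity -> stats.

Each stage writes plain-text artifacts and a run-metadata JSON (config
snapshot, seed, per-stage counts, SHA-256 checksums) sufficient to
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnalysisConfig,
    file_checksum,
    read_behavior_table,
    read_cohort_timecourses,
    write_cohort,
    write_windowed_series,
)
from .metastates import discretize_weights, fit_connectivity_patterns, metastate_metrics
from .preprocess import ConditioningSettings, SubjectTimecourse, condition_timecourse
from .static import fisher_z, static_fnc_matrix
from .states import (
    StatePartition,
    cluster_windows,
    compute_state_metrics,
    select_k_elbow,
    subject_state_fnc,
)
from .stats import correlate_features_behavior, motion_state_qc
from .synthetic import BEHAVIOR_MEASURES, CohortConfig, generate_cohort
from .windows import SlidingWindowFNC, WindowedFNCSeries, build_taper, select_glasso_lambda

logger = logging.getLogger("dfnc")

__all__ = ["ResultsBundle", "simulate_stage", "run_pipeline"]


@dataclasses.dataclass
class ResultsBundle:
    """Paths and checksums of a run's artifacts plus its configuration."""

    outdir: Path
    artifacts: dict[str, Path]
    config: AnalysisConfig
    seed: int

    def write_metadata(self, extra: dict | None = None) -> Path:
        meta = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "artifacts": {
                name: {"path": str(p), "sha256": file_checksum(p)}
                for name, p in self.artifacts.items()
                if Path(p).is_file()
            },
        }
        if extra:
            meta.update(extra)
        path = self.outdir / "run_metadata.json"
        path.write_text(json.dumps(meta, indent=2, default=str))
        self.artifacts["run_metadata"] = path
        return path


def _cohort_config(cfg: AnalysisConfig) -> CohortConfig:
    return CohortConfig(
        n_subjects=cfg.n_subjects,
        n_timepoints=cfg.n_timepoints,
        n_components=cfg.n_components,
        n_states=cfg.sim_states,
        tr_seconds=cfg.tr_seconds,
        separation=cfg.separation,
        self_transition=cfg.self_transition,
        seed=cfg.seed,
    )


def simulate_stage(cfg: AnalysisConfig, outdir: str | Path) -> ResultsBundle:
    """Generate and write a synthetic cohort."""
    outdir = Path(outdir)
    cohort = generate_cohort(_cohort_config(cfg))
    paths = write_cohort(cohort, outdir)
    logger.info("simulated %d subjects x %d timepoints x %d components",
                cfg.n_subjects, cfg.n_timepoints, cfg.n_components)
    bundle = ResultsBundle(outdir, {k: Path(v) for k, v in paths.items()
                                    if Path(v).is_file()}, cfg, cfg.seed)
    bundle.write_metadata({"stage": "simulate"})
    return bundle


def _condition_all(subjects, cfg: AnalysisConfig):
    settings = ConditioningSettings(
        despike_threshold=cfg.despike_threshold,
        despike_window=cfg.despike_window,
        cutoff_hz=cfg.cutoff_hz,
        order=cfg.filter_order,
    )
    return [condition_timecourse(tc, settings) for tc in subjects]


def _windowed_all(subjects, cfg: AnalysisConfig) -> list[WindowedFNCSeries]:
    taper = build_taper(cfg.window_width, cfg.window_sigma, cfg.window_half_support)
    out = []
    for tc in subjects:
        if cfg.estimator == "glasso":
            if cfg.glasso_lambda == "cv":
                lam = select_glasso_lambda(tc, taper, folds=cfg.glasso_folds,
                                           step=cfg.window_step)
            else:
                lam = float(cfg.glasso_lambda)
            swf = SlidingWindowFNC(cfg.window_width, cfg.window_sigma,
                                   cfg.window_half_support, cfg.window_step,
                                   estimator="glasso", alpha=lam,
                                   tr_seconds=cfg.tr_seconds)
        else:
            swf = SlidingWindowFNC(cfg.window_width, cfg.window_sigma,
                                   cfg.window_half_support, cfg.window_step,
                                   estimator="sample", tr_seconds=cfg.tr_seconds)
        out.append(swf.series(tc))
    return out


def _state_z_features(partition: StatePartition, series_list) -> pd.DataFrame:
    """Per-state Fisher-z pair features; NaN for subjects absent from a state."""
    tables = subject_state_fnc(partition, series_list)
    all_ids = list(partition.assignments)
    cols = {}
    for k, table in tables.items():
        z = np.arctanh(np.clip(table.to_numpy(dtype=float), -0.999999, 0.999999))
        ztab = pd.DataFrame(z, index=table.index, columns=table.columns)
        for pair in ztab.columns:
            cols[f"state{k}_z_{pair}"] = ztab[pair].reindex(all_ids)
    return pd.DataFrame(cols, index=pd.Index(all_ids, name="subject_id"))


def run_pipeline(
    cfg: AnalysisConfig,
    outdir: str | Path,
    cohort_dir: str | Path | None = None,
    stages: tuple[str, ...] = ("static", "dfnc", "metastate", "correlate"),
) -> ResultsBundle:
    """Run the analysis chain and write its artifacts.

    When ``cohort_dir`` is given, time courses and behavior are read from a
    previously written cohort; otherwise a synthetic cohort is generated
    in memory with the config's simulation settings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, object] = {}

    if cohort_dir is not None:
        cohort_dir = Path(cohort_dir)
        subjects = read_cohort_timecourses(cohort_dir / "manifest.csv", cfg.tr_seconds)
        behavior = read_behavior_table(cohort_dir / "behavior.csv")
    else:
        cohort = generate_cohort(_cohort_config(cfg))
        subjects = list(cohort.subjects)
        behavior = cohort.behavior
    counts["n_subjects"] = len(subjects)
    logger.info("conditioning %d subjects", len(subjects))
    conditioned = _condition_all(subjects, cfg)
    ids = [tc.subject_id for tc in conditioned]

    measures = [m for m in BEHAVIOR_MEASURES if m in behavior.columns]
    behavior_measures = behavior[measures]
    correlation_frames = []

    if "static" in stages:
        results = [static_fnc_matrix(tc) for tc in conditioned]
        zmat = pd.DataFrame(
            [r.zvector for r in results],
            index=pd.Index(ids, name="subject_id"),
            columns=[f"static_z_{p}" for p in results[0].pair_names],
        )
        path = outdir / "static_fnc_z.csv"
        zmat.to_csv(path)
        artifacts["static_fnc_z"] = path
        counts["n_static_pairs"] = zmat.shape[1]
        if "correlate" in stages:
            corr = correlate_features_behavior(
                zmat, behavior_measures, family="static_fnc", q=cfg.q_threshold
            )
            correlation_frames.append(corr)

    partition = None
    series_list = None
    if "dfnc" in stages or "metastate" in stages:
        series_list = _windowed_all(conditioned, cfg)
        counts["n_windows_per_subject"] = int(series_list[0].n_windows)
        counts["n_windowed_matrices"] = int(sum(s.n_windows for s in series_list))
        win_dir = outdir / "windows"
        for s in series_list:
            write_windowed_series(s, win_dir)
        pooled = np.vstack([s.vectors for s in series_list])

    if "dfnc" in stages:
        if cfg.n_states is None:
            elbow = select_k_elbow(pooled, cfg.k_min, cfg.k_max,
                                   cfg.replicates, cfg.max_iter, cfg.seed)
            k = elbow.chosen_k
            counts["elbow_curve"] = dict(zip(elbow.ks, elbow.cluster_index))
            logger.info("elbow criterion selected k = %d", k)
        else:
            k = cfg.n_states
        counts["n_states"] = k
        partition = cluster_windows(series_list, k, cfg.replicates,
                                    cfg.max_iter, cfg.seed)
        metrics = compute_state_metrics(partition, cfg.tr_seconds, cfg.window_step)
        path = outdir / "state_metrics.csv"
        metrics.to_csv(path)
        artifacts["state_metrics"] = path

        assign_path = outdir / "state_assignments.tsv"
        with assign_path.open("w") as fh:
            w = series_list[0].n_windows
            fh.write("subject_id\t" + "\t".join(f"w{i}" for i in range(w)) + "\n")
            for sid in ids:
                fh.write(sid + "\t" + "\t".join(map(str, partition.assignments[sid])) + "\n")
        artifacts["state_assignments"] = assign_path

        state_z = _state_z_features(partition, series_list)
        path = outdir / "state_fnc_z.csv"
        state_z.to_csv(path)
        artifacts["state_fnc_z"] = path

        if "correlate" in stages:
            n_pairs = series_list[0].vectors.shape[1]
            family_size = cfg.state_fnc_family_size or n_pairs * k * len(measures)
            counts["state_fnc_family_size"] = family_size
            correlation_frames.append(correlate_features_behavior(
                state_z, behavior_measures, family="state_fnc",
                q=cfg.q_threshold, family_size=family_size,
            ))
            correlation_frames.append(correlate_features_behavior(
                metrics, behavior_measures, family="state_metrics",
                q=cfg.q_threshold,
            ))
            if "mean_fd" in behavior.columns:
                ft_cols = [c for c in metrics.columns if c.endswith("_ft")]
                qc = motion_state_qc(metrics[ft_cols], behavior["mean_fd"])
                path = outdir / "motion_qc.csv"
                qc.to_csv(path, index=False)
                artifacts["motion_qc"] = path

    if "metastate" in stages:
        vec_by_id = {s.subject_id: s.vectors for s in series_list}
        patterns = fit_connectivity_patterns(vec_by_id, cfg.n_patterns, cfg.seed)
        trajectories = discretize_weights(patterns)
        meta = metastate_metrics(trajectories)
        path = outdir / "metastate_metrics.csv"
        meta.to_csv(path)
        artifacts["metastate_metrics"] = path
        traj_dir = outdir / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for sid, traj in trajectories.items():
            np.savetxt(traj_dir / f"{sid}_metastates.tsv", traj,
                       fmt="%d", delimiter="\t")
        if "correlate" in stages:
            correlation_frames.append(correlate_features_behavior(
                meta, behavior_measures, family="metastate",
                q=cfg.q_threshold,
            ))

    if correlation_frames:
        all_corr = pd.concat(correlation_frames, ignore_index=True)
        path = outdir / "correlations.csv"
        all_corr.to_csv(path, index=False)
        artifacts["correlations"] = path
        counts["n_correlation_tests"] = int(len(all_corr))
        counts["n_significant"] = int(all_corr["significant"].sum())

    bundle = ResultsBundle(outdir, artifacts, cfg, cfg.seed)
    bundle.write_metadata({"stage": "+".join(stages), "counts": counts})
    return bundle
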