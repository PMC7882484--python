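"""Stage orchestration shared by the CLI and the analysis drivers.

Each stage reads/writes the plain-text formats of :mod:`mothtaxis.io` inside
one output directory:

    trajectories/trial_XXX.csv (+ .meta.json)   <- simulate
    rewards/trial_XXX.csv                       <- model (infotaxis replay)
    maneuvers/trial_XXX.csv, maneuver_matrix.json  <- classify
    report.json                                 <- analyze
    manifest.json                               <- all
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .belief import replay_trajectory
from .config import PipelineConfig, config_hash
from .episode import Trajectory, generate_cohort, summarize_cohort
from .maneuvers import classify_trajectory, cohort_matrix, maneuver_matrix
from .rewards import analysis_report, join_records, windowed_rmse_table

log = logging.getLogger("mothtaxis")

__all__ = ["simulate_stage", "model_stage", "classify_stage", "analyze_stage",
           "run_all", "load_trials"]


def _trial_paths(folder: Path) -> list[Path]:
    return sorted(Path(folder).glob("trial_*.csv"))


def load_trials(outdir) -> list[Trajectory]:
    return [mio.read_trajectory(p) for p in _trial_paths(Path(outdir) / "trajectories")]


def simulate_stage(cfg: PipelineConfig, seed: int, outdir, n_trials: int = 20
                   ) -> tuple[list[Trajectory], dict]:
    """Generate a cohort and write trajectory CSVs + a cohort summary."""
    outdir = Path(outdir)
    (outdir / "trajectories").mkdir(parents=True, exist_ok=True)
    trials, summary = generate_cohort(n_trials, cfg.arena, cfg.plume,
                                      cfg.policy, seed)
    chash = config_hash(cfg)
    for i, tr in enumerate(trials):
        mio.write_trajectory(tr, outdir / "trajectories" / f"trial_{i:03d}.csv",
                             config_hash=chash)
        log.info("trial %03d: %s (%.1f s, %d samples)", i, tr.outcome,
                 tr.search_time, len(tr))
    payload = {
        "n_trials": summary.n_trials, "n_success": summary.n_success,
        "success_rate_pct": summary.success_rate_pct,
        "mean_search_time": summary.mean_search_time,
        "sd_search_time": summary.sd_search_time,
        "search_times": summary.search_times,
    }
    (outdir / "cohort_summary.json").write_text(json.dumps(payload, indent=1))
    log.info("cohort: %d/%d success (%.1f%%)", summary.n_success,
             summary.n_trials, summary.success_rate_pct)
    return trials, payload


def model_stage(cfg: PipelineConfig, outdir, successful_only: bool = True
                ) -> list[pd.DataFrame]:
    """Infotaxis replay of each stored trajectory -> reward CSVs."""
    outdir = Path(outdir)
    (outdir / "rewards").mkdir(parents=True, exist_ok=True)
    rewards = []
    for path in _trial_paths(outdir / "trajectories"):
        traj = mio.read_trajectory(path)
        if successful_only and not traj.success:
            log.info("replay %s: skipped (timeout trial)", path.name)
            continue
        rdf = replay_trajectory(traj.samples, cfg.arena, cfg.likelihood,
                                hit_rate_window=cfg.analysis.hit_rate_window)
        mio.write_rewards(rdf, outdir / "rewards" / path.name)
        rewards.append(rdf)
        log.info("replay %s: S %.3f -> %.3f over %d samples", path.name,
                 rdf["S"].iloc[0], rdf["S"].iloc[-1] + rdf["dS"].iloc[-1], len(rdf))
    return rewards


def classify_stage(cfg: PipelineConfig, outdir, successful_only: bool = True
                   ) -> list[pd.DataFrame]:
    """Maneuver labelling of each stored trajectory -> maneuver CSVs + matrix."""
    outdir = Path(outdir)
    (outdir / "maneuvers").mkdir(parents=True, exist_ok=True)
    tables, matrices = [], []
    for path in _trial_paths(outdir / "trajectories"):
        traj = mio.read_trajectory(path)
        if successful_only and not traj.success:
            continue
        mdf = classify_trajectory(traj.samples, cfg.arena.wind_angle, cfg.classify)
        mio.write_maneuvers(mdf, outdir / "maneuvers" / path.name)
        tables.append(mdf)
        try:
            matrices.append(maneuver_matrix(mdf))
        except ValueError:
            log.info("classify %s: all samples excluded", path.name)
    if matrices:
        cm = cohort_matrix(matrices)
        payload = {"mean": cm["mean"].tolist(), "sd": cm["sd"].tolist(),
                   "excluded_mean": cm["excluded_mean"],
                   "excluded_sd": cm["excluded_sd"], "n_trials": cm["n_trials"],
                   "rows_kinematic": ["Surge", "Rotate"],
                   "cols_temporal": ["Surge", "Rotate"]}
        (outdir / "maneuver_matrix.json").write_text(json.dumps(payload, indent=1))
    return tables


def analyze_stage(cfg: PipelineConfig, outdir) -> dict:
    """Join rewards with labels and write the comparative report."""
    outdir = Path(outdir)
    reward_paths = {p.name: p for p in sorted((outdir / "rewards").glob("trial_*.csv"))}
    pooled = []
    rmse_tables = []
    for name, rpath in reward_paths.items():
        mpath = outdir / "maneuvers" / name
        if not mpath.exists():
            continue
        rdf, mdf = mio.read_rewards(rpath), mio.read_maneuvers(mpath)
        grouped = join_records(rdf, mdf)
        for status, df in grouped.groups.items():
            if len(df):
                pooled.append(df.assign(match=status))
        if len(rdf) >= cfg.analysis.rmse_window + 1:
            rmse_tables.append(windowed_rmse_table(rdf, mdf, cfg.analysis))
    if not pooled:
        raise ValueError("no included samples: run simulate/model/classify first")
    joined = pd.concat(pooled, ignore_index=True)
    from .rewards import GroupedRewards
    groups = GroupedRewards({s: joined[joined["match"] == s].drop(columns="match")
                             for s in ("match", "mismatch")})
    rmse_all = (pd.concat(rmse_tables, ignore_index=True)
                if rmse_tables else None)
    report = analysis_report(groups, rmse_all, cfg.analysis)
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    if rmse_all is not None:
        rmse_all.to_csv(outdir / "rmse_windows.csv", index=False,
                        lineterminator="\n")
    return report


def run_all(cfg: PipelineConfig, seed: int, outdir, n_trials: int = 20) -> dict:
    """Chain all stages and write a run manifest; returns the final report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = mio.RunManifest(config_hash=config_hash(cfg), seed=int(seed))
    simulate_stage(cfg, seed, outdir, n_trials)
    traj_files = [str(p) for p in _trial_paths(outdir / "trajectories")]
    manifest.add_stage("simulate", [], traj_files + [str(outdir / "cohort_summary.json")])
    model_stage(cfg, outdir)
    manifest.add_stage("model", traj_files,
                       [str(p) for p in sorted((outdir / "rewards").glob("*.csv"))])
    classify_stage(cfg, outdir)
    cls_out = [str(p) for p in sorted((outdir / "maneuvers").glob("*.csv"))]
    if (outdir / "maneuver_matrix.json").exists():
        cls_out.append(str(outdir / "maneuver_matrix.json"))
    manifest.add_stage("classify", traj_files, cls_out)
    report = analyze_stage(cfg, outdir)
    manifest.add_stage("analyze", cls_out, [str(outdir / "report.json")])
    manifest.write(outdir / "manifest.json")
    return report
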