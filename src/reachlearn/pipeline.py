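"""End-to-end orchestration: read → filter → detect → score → kinematics → stats.

``run_pipeline`` consumes a directory of pose tables (one per subject-day,
named ``<subject>_day<D>.csv``), a tab-separated manifest (subject, genotype,
sex, condition) and either a reach-annotation table or the geometric
auto-classifier, and produces every intermediate and final table. Outputs are
deterministic for fixed inputs and configuration; every table is written
alongside a run manifest carrying the configuration hash.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import scoring
from .config import PipelineConfig, config_hash, config_to_dict
from .detect import Reach, assign_reaches_to_trials, find_reaches
from .tracking_io import filter_track, preferred_paw, read_pose_table

log = logging.getLogger("reachlearn")

OUTCOME_METRICS = [
    "success_by_trial_pct",
    "success_by_reach_pct",
    "first_reach_success_pct",
    "complete_miss_pct",
    "contact_miss_pct",
    "vain_pct",
]
KINEMATIC_METRICS = ["path_length_px", "delta_y_px", "delta_x_px"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineResult:
    config: PipelineConfig
    reaches: pd.DataFrame
    metrics: pd.DataFrame  # per subject-day outcome metrics (+ manifest columns)
    kinematics: pd.DataFrame  # per reach
    kinematic_aggregates: pd.DataFrame  # per subject-day
    stats: pd.DataFrame
    learning_indices: pd.DataFrame
    day8_distribution: pd.DataFrame | None
    sample_reaches: list[Reach] = field(default_factory=list)

    @property
    def hash(self) -> str:
        return config_hash(self.config)


def _session_files(poses_dir: Path) -> list[tuple[str, int, Path]]:
    out = []
    for p in sorted(poses_dir.glob("*.csv")):
        m = re.match(r"(?P<subject>.+)_day(?P<day>\d+)$", p.stem)
        if m:
            out.append((m["subject"], int(m["day"]), p))
    return out


def _pellet_interval(pose, window: tuple[int, int], p_cutoff: float) -> tuple[int, int]:
    """[start, end) frames during which the pellet is confidently on the platform."""
    s, e = window
    lik = pose.point("pellet")["likelihood"].to_numpy(float)[s:e]
    conf = np.nonzero(lik >= p_cutoff)[0]
    if len(conf) == 0:
        return (s, s)
    return (s, s + int(conf[-1]) + 1)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all outputs under ``cfg.out_dir``."""
    poses_dir = Path(cfg.poses_dir)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        manifest = pd.read_csv(cfg.manifest, sep="\t")
    except OSError as exc:
        raise PipelineError(f"stage=read manifest {cfg.manifest}: {exc}") from exc
    annotations = None
    if cfg.annotations is not None:
        try:
            annotations = pd.read_csv(cfg.annotations, sep="\t")
        except OSError as exc:
            raise PipelineError(f"stage=score annotations {cfg.annotations}: {exc}") from exc

    meta = manifest.set_index("subject")
    sessions = _session_files(poses_dir)
    if not sessions:
        raise PipelineError(f"stage=read no pose tables found under {poses_dir}")

    reach_rows, kin_reaches, summaries, sample_reaches = [], [], [], []
    for subject, day, path in sessions:
        track = read_pose_table(path, fps=cfg.fps, subject=subject, day=day)
        paw = preferred_paw(track, cfg.p_cutoff, cfg.bounds)
        filtered = filter_track(track, paw, cfg.p_cutoff, cfg.bounds)
        log.info("%s day %d: %d/%d samples retained (%s)",
                 subject, day, len(filtered), track.n_frames, paw)
        reaches = find_reaches(filtered, cfg.detection)
        n_trials = track.n_frames // cfg.frames_per_trial
        windows = [(t, t * cfg.frames_per_trial, (t + 1) * cfg.frames_per_trial)
                   for t in range(n_trials)]
        trials, unassigned = assign_reaches_to_trials(reaches, windows)
        if unassigned:
            log.warning("%s day %d: %d reaches outside all trial windows",
                        subject, day, len(unassigned))
        for tr in trials:
            for r in tr.reaches:
                r.subject, r.day = subject, day
                reach_rows.append(dict(
                    subject=subject, day=day, trial=tr.trial, ordinal=r.ordinal,
                    start_frame=r.start_frame, end_frame=r.end_frame,
                    n_points=r.n_points, paw=paw,
                ))
        kin_reaches.extend(r for tr in trials for r in tr.reaches)
        if sample_reaches.__len__() < 40:
            sample_reaches.extend(r for tr in trials[:2] for r in tr.reaches)

        # --- outcome labels
        if annotations is not None:
            sub_ann = annotations[(annotations["subject"] == subject)
                                  & (annotations["day"] == day)]
            records = scoring.records_from_labels(
                sub_ann, n_trials=n_trials, subject=subject, day=day,
                condition=meta.at[subject, "condition"] if "condition" in meta else None,
                group=meta.at[subject, "genotype"] if "genotype" in meta else None,
            )
        else:
            records = []
            for tr in trials:
                labels = []
                interval = _pellet_interval(track, (tr.start_frame, tr.end_frame), cfg.p_cutoff)
                pellet = track.point("pellet")
                pellet_conf = pellet["likelihood"].to_numpy(float) >= cfg.p_cutoff
                sel = slice(tr.start_frame, tr.end_frame)
                pxy = pellet[["x", "y"]].to_numpy(float)[sel][pellet_conf[sel]]
                pellet_ref = tuple(np.median(pxy, axis=0)) if len(pxy) else None
                for r in tr.reaches:
                    if pellet_ref is None:
                        raise PipelineError(
                            f"stage=score subject={subject} day={day} trial={tr.trial}: "
                            "no confident pellet samples; auto-classifier unavailable")
                    retrieved = scoring.infer_retrieval(
                        r, track.point("pellet"), track.frames, cfg.slit_x,
                        cfg.toward_sign, cfg.p_cutoff)
                    labels.append(scoring.auto_classify_reach(
                        r, pellet_ref, interval, cfg.slit_x, cfg.toward_sign,
                        cfg.contact_radius_px, retrieved=retrieved))
                records.append(scoring.TrialRecord(
                    subject=subject, day=day, trial=tr.trial, labels=labels,
                    no_try=not labels,
                    condition=meta.at[subject, "condition"] if "condition" in meta else None,
                    group=meta.at[subject, "genotype"] if "genotype" in meta else None,
                ))
        summaries.append(scoring.summarize_session(records))

    reaches_table = pd.DataFrame(reach_rows)
    metrics = scoring.metrics_table(summaries)
    metrics = metrics.merge(manifest, on="subject", how="left", suffixes=("", "_manifest"))

    kin_table = kin.kinematics_table(
        kin_reaches, cfg.slit_x, cfg.toward_sign, cfg.fps, cfg.distance_metric)
    kin_agg = kin.aggregate_kinematics(kin_table)
    if not kin_agg.empty:
        kin_agg = kin_agg.merge(manifest, on="subject", how="left")

    # --- statistics
    from . import stats as ls

    stats_rows, li_rows = [], []
    curve_table = metrics
    for metric in OUTCOME_METRICS + KINEMATIC_METRICS:
        if metric in KINEMATIC_METRICS:
            if kin_agg.empty or metric not in kin_agg:
                continue
            tbl = kin_agg
        else:
            tbl = curve_table
        try:
            rep = ls.longitudinal_report(tbl, [metric], group_col="genotype")
            stats_rows.append(rep)
        except ls.InsufficientDataError as exc:
            log.warning("stats %s: %s", metric, exc)
        try:
            li = ls.learning_indices(tbl, metric)
            li_rows.append(li)
            groups = sorted(li["genotype"].dropna().unique()) if "genotype" in li else []
            if len(groups) == 2:
                a = li.loc[li["genotype"] == groups[0], "learning_index"]
                b = li.loc[li["genotype"] == groups[1], "learning_index"]
                tr = ls.group_li_test(a, b)
                stats_rows.append(pd.DataFrame([{
                    "metric": metric, "comparison": f"LI {groups[0]} vs {groups[1]}",
                    "effect": "genotype", "model": "welch", "test": tr.test,
                    "statistic": tr.statistic, "df": str(tr.df), "p": tr.pvalue,
                    "n_subjects": sum(tr.n) if isinstance(tr.n, tuple) else tr.n,
                    "n_missing_cells": 0,
                }]))
        except (ls.InsufficientDataError, ValueError) as exc:
            log.warning("LI %s: %s", metric, exc)
    stats_table = pd.concat(stats_rows, ignore_index=True) if stats_rows else pd.DataFrame()
    li_table = pd.concat(li_rows, ignore_index=True) if li_rows else pd.DataFrame()

    last_day = int(metrics["day"].max()) if not metrics.empty else None
    try:
        day8 = scoring.outcome_distribution(summaries, last_day) if last_day else None
    except scoring.ScoringError:
        day8 = None

    result = PipelineResult(
        config=cfg, reaches=reaches_table, metrics=metrics, kinematics=kin_table,
        kinematic_aggregates=kin_agg, stats=stats_table, learning_indices=li_table,
        day8_distribution=day8, sample_reaches=sample_reaches,
    )
    _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    h = result.hash
    tables = {
        "reaches.tsv": result.reaches,
        "metrics_by_subject_day.tsv": result.metrics,
        "kinematics_by_reach.tsv": result.kinematics,
        "kinematics_by_subject_day.tsv": result.kinematic_aggregates,
        "stats.tsv": result.stats,
        "learning_indices.tsv": result.learning_indices,
    }
    if result.day8_distribution is not None:
        tables["outcome_distribution_last_day.tsv"] = result.day8_distribution
    for name, df in tables.items():
        path = out_dir / name
        with path.open("w") as fh:
            fh.write(f"# config_hash={h}\n")
            df.to_csv(fh, sep="\t", index=False)
    (out_dir / "run_manifest.json").write_text(json.dumps({
        "config_hash": h,
        "config": config_to_dict(result.config),
        "n_reaches": int(len(result.reaches)),
        "n_subject_days": int(len(result.metrics)),
    }, indent=2, sort_keys=True))
    if not result.stats.empty:
        result.stats.to_json(out_dir / "stats.json", orient="records", indent=2)


# ---------------------------------------------------------------------------
# report


def make_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Figure bundle: time courses, Day1-vs-Day8 paired plots, last-day outcome
    pie, trajectory overlays (spline-smoothed for display only) and a
    parameters page. Deterministic SVG output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "reachlearn"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(fig, name):
        path = out / name
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
        written.append(path)

    metrics = result.metrics
    if metrics.empty:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.axis("off")
        ax.text(0.5, 0.5, "no data", ha="center", va="center", fontsize=20)
        save(fig, "report_empty.svg")
        return written

    group_col = "genotype" if "genotype" in metrics else "group"
    for metric in OUTCOME_METRICS:
        if metric not in metrics:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for g, sub in metrics.groupby(group_col):
            curve = sub.groupby("day")[metric].agg(["mean", "sem"])
            ax.errorbar(curve.index, curve["mean"], yerr=curve["sem"], label=str(g), capsize=2)
        ax.set_xlabel("training day")
        ax.set_ylabel(metric)
        ax.legend(frameon=False)
        fig.tight_layout()
        save(fig, f"timecourse_{metric}.svg")

        first, last = int(metrics["day"].min()), int(metrics["day"].max())
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        for _, sub in metrics[metrics["day"].isin([first, last])].groupby("subject"):
            sub = sub.sort_values("day")
            if len(sub) == 2:
                ax.plot([0, 1], sub[metric].to_numpy(), color="0.6", lw=0.8)
        ax.set_xticks([0, 1], [f"Day {first}", f"Day {last}"])
        ax.set_ylabel(metric)
        fig.tight_layout()
        save(fig, f"paired_day{first}_day{last}_{metric}.svg")

    if result.day8_distribution is not None:
        dist = result.day8_distribution
        labels = [c for c in dist.columns if c not in ("group", "day")]
        fig, axes = plt.subplots(1, len(dist), figsize=(3.2 * len(dist), 3.2))
        for ax, (_, row) in zip(np.atleast_1d(axes), dist.iterrows()):
            ax.pie(row[labels].to_numpy(float), labels=labels,
                   colors=["green", "red", "orange", "lightblue"])
            ax.set_title(str(row["group"]))
        fig.tight_layout()
        save(fig, "outcome_distribution_last_day.svg")

    if result.sample_reaches:
        from scipy.interpolate import make_interp_spline

        fig, ax = plt.subplots(figsize=(4, 4))
        for r in result.sample_reaches[:40]:
            xy = r.xy
            if len(xy) >= 4:  # spline interpolation for display only
                t = np.linspace(0, 1, len(xy))
                tt = np.linspace(0, 1, 10 * len(xy))
                xs = make_interp_spline(t, xy[:, 0], k=3)(tt)
                ys = make_interp_spline(t, xy[:, 1], k=3)(tt)
            else:
                xs, ys = xy[:, 0], xy[:, 1]
            ax.plot(xs, ys, lw=0.6, alpha=0.6)
        px, py = result.config.detection.pellet_ref
        ax.plot([px], [py], "o", color="red")
        ax.invert_yaxis()  # image coordinates: y grows downward
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        fig.tight_layout()
        save(fig, "trajectories.svg")

    cfg = result.config
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axis("off")
    lines = [
        f"config hash: {result.hash}",
        f"p-cutoff: {cfg.p_cutoff}",
        f"bounds: ({cfg.bounds.x_min}, {cfg.bounds.x_max}) x ({cfg.bounds.y_min}, {cfg.bounds.y_max})",
        f"detector: window={cfg.detection.window}, consensus={cfg.detection.consensus}, "
        f"min_points={cfg.detection.min_points}, max_gap={cfg.detection.max_gap}",
        f"slit_x={cfg.slit_x}, toward_sign={cfg.toward_sign}",
        f"distance metric: {cfg.distance_metric}",
        "LI orientation: success-type Day8−Day1; miss/vain/distance/ΔY/ΔX Day1−Day8",
        "two-sided tests; no multiple-testing correction across metrics",
    ]
    ax.text(0.02, 0.98, "\n".join(lines), va="top", family="monospace", fontsize=9)
    save(fig, "parameters.svg")
    return written
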