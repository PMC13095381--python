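"""Synthetic single-pellet reaching cohorts with exact ground truth.

The generator emulates the study's trial structure — 8 training days of 50
trials per subject, 13 s pellet-access windows filmed at 240 fps from the
side, slit on the left and pellet in a divot to its right — and produces
pose tables in the markerless-tracking CSV dialect together with a manifest
and a ground-truth reach table, so every downstream stage can be tested
without any recorded data.

Generative model (none of this is estimated from real data; see
docs/methods.md):

* Per-attempt success probability follows a per-group logistic learning curve
  ``q(day)``; attempts within a trial are independent Bernoulli(q) draws
  capped by a planned-attempt count, the trial ending on the first success.
  By Wald's identity the pooled success-by-reach rate then equals ``q(day)``
  in expectation, so learning effects can be imposed directly on that metric.
* A reach trajectory is a straight slit→apex drift plus a smooth vertical
  arc whose amplitude is drawn with sd = vertical_spread_curve(day), plus
  small iid Gaussian jitter; miss outcomes overshoot the pellet in x by
  overshoot_curve(day). The retraction mirrors the outward path with fewer,
  faster samples — real withdrawals are quick, and a sparse retraction also
  keeps the toward-the-pellet run after an overshoot apex below the
  detector's consensus, so one generated excursion is one detected reach.
* Occlusion dropout re-emits points with likelihood < 0.05 rather than
  deleting rows, as markerless trackers label every frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import REACH_LABELS, GroupParams, SimulationConfig
from .detect import Reach
from .tracking_io import PoseTrack, build_pose_track, write_pose_table


class UnknownOutcomeError(ValueError):
    """The requested reach outcome label is not part of the taxonomy."""


_MISS_LABELS = ("complete_miss", "contact_miss", "other")
_MISS_PROBS = (0.45, 0.45, 0.10)

#: outward samples per reach (uniform draw, inclusive bounds)
_N_OUT = (15, 30)
#: retraction samples per reach; sparse so that the post-apex toward-run of an
#: overshooting reach stays below the 4-of-5 consensus
_N_RET = (5, 7)


def _categorical(rng: np.random.Generator, probs) -> int:
    return int(rng.choice(len(probs), p=np.asarray(probs, dtype=float)))


# ---------------------------------------------------------------------------
# outcome labels


def draw_trial_labels(rng: np.random.Generator, q: float, config: SimulationConfig) -> list[str]:
    """Draw one trial's ordered reach labels (empty list = No Try).

    Targeted attempts are Bernoulli(``q``) draws, stopping at the first
    success or after the planned attempt count; at most one success per trial
    (the pellet is removed on retrieval). Vain reaches can only follow a
    success, after which the platform is empty.
    """
    if rng.random() < config.no_try_rate:
        return []
    planned = 1 + _categorical(rng, config.reaches_per_trial_dist)
    labels: list[str] = []
    for _ in range(planned):
        if rng.random() < q:
            labels.append("success")
            break
        labels.append(_MISS_LABELS[_categorical(rng, _MISS_PROBS)])
    if labels and labels[-1] == "success":
        for _ in range(2):
            if rng.random() < config.vain_rate:
                labels.append("vain")
    return labels


# ---------------------------------------------------------------------------
# trajectories


def simulate_reach_trajectory(
    config: SimulationConfig,
    day: int,
    group: GroupParams,
    outcome: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One paw excursion: returns ``(xy, likelihood, apex_index)``.

    The point sequence runs outward from the slit plane to the apex
    (``apex_index``) and back; one point per frame. With zero noise and a
    ``success`` outcome the apex touches the pellet exactly.
    """
    if outcome not in REACH_LABELS:
        raise UnknownOutcomeError(f"unknown outcome label {outcome!r}")
    if not 1 <= day <= config.days:
        raise ValueError(f"day {day} outside [1, {config.days}]")
    px, py = config.pellet_xy
    sign = config.toward_sign
    sigma = group.trajectory_noise_sigma_curve(day)
    spread = group.vertical_spread_curve(day)
    overshoot = group.overshoot_curve(day)

    if outcome == "success":
        entry_y = py + rng.normal(0.0, 2.0)
        apex = np.array([px, py])
    elif outcome in ("contact_miss", "other"):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = rng.uniform(4.0, 12.0)
        entry_y = py + rng.normal(0.0, 2.0)
        apex = np.array([px + rad * math.cos(ang), py + rad * math.sin(ang)])
    elif outcome == "complete_miss":
        side = rng.choice([-1.0, 1.0])
        entry_y = py + side * 10.0 + rng.normal(0.0, 2.0)
        apex = np.array(
            [px + sign * overshoot, py + side * (25.0 + abs(rng.normal(0.0, 8.0)))]
        )
    else:  # vain: aimed at the (absent) pellet position
        entry_y = py + rng.normal(0.0, 3.0)
        apex = np.array([px + rng.normal(0.0, 4.0), py + rng.normal(0.0, 8.0)])

    entry = np.array([config.slit_x, entry_y])
    n_out = int(rng.integers(_N_OUT[0], _N_OUT[1] + 1))
    n_ret = int(rng.integers(_N_RET[0], _N_RET[1] + 1))
    amp_out = rng.normal(0.0, spread)
    amp_ret = rng.normal(0.0, 0.5 * spread)

    t_out = np.linspace(0.0, 1.0, n_out + 1)
    out = entry + t_out[:, None] * (apex - entry)
    out[:, 1] += amp_out * np.sin(math.pi * t_out)
    if sigma > 0 and n_out > 1:  # endpoints stay exact
        out[1:-1] += rng.normal(0.0, sigma, size=(n_out - 1, 2))

    t_ret = np.linspace(0.0, 1.0, n_ret + 1)[1:]  # apex itself not repeated
    ret = apex + t_ret[:, None] * (entry - apex)
    ret[:, 1] += amp_ret * np.sin(math.pi * t_ret)
    if sigma > 0 and n_ret > 1:
        ret[:-1] += rng.normal(0.0, sigma, size=(n_ret - 1, 2))

    xy = np.vstack([out, ret])
    # keep the excursion beyond the slit plane and inside the tracking bounds
    b = config.bounds()
    if sign > 0:
        np.clip(xy[:, 0], config.slit_x, b.x_max, out=xy[:, 0])
    else:
        np.clip(xy[:, 0], b.x_min, config.slit_x, out=xy[:, 0])
    np.clip(xy[:, 1], b.y_min, b.y_max, out=xy[:, 1])

    likelihood = rng.uniform(0.88, 1.0, size=len(xy))
    if config.dropout_prob > 0:
        drop = rng.random(len(xy)) < config.dropout_prob
        likelihood[drop] = rng.uniform(0.0, 0.04, size=int(drop.sum()))
    return xy, likelihood, n_out


# ---------------------------------------------------------------------------
# trials and sessions


@dataclass
class TrialSim:
    """One simulated trial: per-frame point arrays plus exact ground truth."""

    points: dict[str, np.ndarray]  # bodypart -> (frames_per_trial, 3) x/y/lik
    ground_truth: list[tuple[int, int, str]]  # (start, retraction onset, label)
    no_try: bool
    pellet_present: tuple[int, int]  # [start, end) frame interval


def simulate_trial(
    config: SimulationConfig,
    group: GroupParams,
    day: int,
    trial_index: int,
    rng: np.random.Generator,
) -> TrialSim:
    """Simulate one 13-s trial at the configured frame rate."""
    F = config.frames_per_trial
    px, py = config.pellet_xy
    q = group.success_curve(day)
    labels = draw_trial_labels(rng, q, config)

    rest_paw = np.array([config.slit_x - 30.0 * config.toward_sign, py + 10.0])
    paw = np.empty((F, 3))
    paw[:, :2] = rest_paw + rng.normal(0.0, 2.0, size=(F, 2))
    paw[:, 2] = rng.uniform(0.5, 1.0, size=F)

    gt: list[tuple[int, int, str]] = []
    removal_frame = F  # pellet stays put unless retrieved
    carry: tuple[int, np.ndarray] | None = None
    cursor = 100 + int(rng.integers(0, 200))
    for lab in labels:
        xy, lik, apex = simulate_reach_trajectory(config, day, group, lab, rng)
        m = len(xy)
        if cursor + m >= F - 10:  # cannot happen under default timing
            raise RuntimeError("trial overran its access window")
        paw[cursor : cursor + m, :2] = xy
        paw[cursor : cursor + m, 2] = lik
        gt.append((cursor, cursor + apex, lab))
        if lab == "success":
            removal_frame = cursor + m
            carry = (cursor + apex, xy[apex:])
        cursor += m + int(rng.integers(60, 200))

    pellet = np.empty((F, 3))
    pellet[:, 0] = px + rng.normal(0.0, 0.5, size=F)
    pellet[:, 1] = py + rng.normal(0.0, 0.5, size=F)
    pellet[:, 2] = rng.uniform(0.95, 1.0, size=F)
    if carry is not None:
        start, path = carry  # pellet rides the retracting paw, then vanishes
        pellet[start : start + len(path), :2] = path
        pellet[removal_frame:, :2] = path[-1]
        pellet[removal_frame:, 2] = rng.uniform(0.0, 0.04, size=F - removal_frame)

    nose = np.empty((F, 3))
    nose[:, 0] = config.slit_x - 40.0 * config.toward_sign + rng.normal(0.0, 1.5, size=F)
    nose[:, 1] = py - 10.0 + rng.normal(0.0, 1.5, size=F)
    nose[:, 2] = rng.uniform(0.9, 1.0, size=F)

    other_paw = np.empty((F, 3))
    other_paw[:, 0] = config.slit_x - 35.0 * config.toward_sign + rng.normal(0.0, 2.0, size=F)
    other_paw[:, 1] = py + 25.0 + rng.normal(0.0, 2.0, size=F)
    other_paw[:, 2] = rng.uniform(0.6, 1.0, size=F)

    points = {"nose": nose, "pellet": pellet}
    if config.dropout_prob > 0:
        for arr in points.values():
            drop = rng.random(F) < config.dropout_prob
            arr[drop, 2] = rng.uniform(0.0, 0.04, size=int(drop.sum()))
    return TrialSim(
        points={"paw": paw, **points, "other_paw": other_paw},
        ground_truth=gt,
        no_try=not labels,
        pellet_present=(0, removal_frame),
    )


@dataclass
class SessionSim:
    """One simulated subject-day: pose track, trial windows and ground truth."""

    subject: str
    day: int
    group: GroupParams
    sex: str
    paw: str  # the reaching paw's bodypart label
    pose: PoseTrack
    ground_truth: pd.DataFrame  # subject, day, trial, ordinal, start/end_frame, label, no_try
    trial_windows: list[tuple[int, int, int]]


def _subject_rng(config: SimulationConfig, gi: int, si: int, day: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, si, day))
    )


def _subject_meta(config: SimulationConfig, gi: int, si: int) -> tuple[str, str, str]:
    group = config.groups[gi]
    subject = f"{group.label}{si:02d}"
    sex = "M" if si < (group.n_subjects + 1) // 2 else "F"
    meta_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, si)))
    paw = "right_paw" if meta_rng.random() < 0.7 else "left_paw"
    return subject, sex, paw


def simulate_subject_day(config: SimulationConfig, gi: int, si: int, day: int) -> SessionSim:
    """Simulate one subject-day session (all trials concatenated)."""
    group = config.groups[gi]
    subject, sex, paw = _subject_meta(config, gi, si)
    rng = _subject_rng(config, gi, si, day)
    F = config.frames_per_trial
    parts: dict[str, list[np.ndarray]] = {bp: [] for bp in ("paw", "other_paw", "nose", "pellet")}
    gt_rows = []
    windows = []
    for t in range(config.trials_per_day):
        trial = simulate_trial(config, group, day, t, rng)
        offset = t * F
        windows.append((t, offset, offset + F))
        for bp, arr in trial.points.items():
            parts[bp].append(arr)
        if trial.no_try:
            gt_rows.append(
                dict(subject=subject, day=day, trial=t, ordinal=0, start_frame=-1,
                     end_frame=-1, label="", no_try=True,
                     pellet_removed_frame=offset + trial.pellet_present[1])
            )
        for k, (s, e, lab) in enumerate(trial.ground_truth, start=1):
            gt_rows.append(
                dict(subject=subject, day=day, trial=t, ordinal=k, start_frame=offset + s,
                     end_frame=offset + e, label=lab, no_try=False,
                     pellet_removed_frame=offset + trial.pellet_present[1])
            )
    other = "left_paw" if paw == "right_paw" else "right_paw"
    point_arrays = {
        paw: np.vstack(parts["paw"]),
        other: np.vstack(parts["other_paw"]),
        "nose": np.vstack(parts["nose"]),
        "pellet": np.vstack(parts["pellet"]),
    }
    # canonical bodypart column order
    ordered = {bp: point_arrays[bp] for bp in ("left_paw", "right_paw", "nose", "pellet")}
    pose = build_pose_track(
        np.arange(F * config.trials_per_day), ordered, fps=config.fps, subject=subject, day=day
    )
    gt = pd.DataFrame(
        gt_rows,
        columns=["subject", "day", "trial", "ordinal", "start_frame", "end_frame",
                 "label", "no_try", "pellet_removed_frame"],
    )
    return SessionSim(
        subject=subject, day=day, group=group, sex=sex, paw=paw, pose=pose,
        ground_truth=gt, trial_windows=windows,
    )


@dataclass
class SimulatedCohort:
    """Lazy handle on a deterministic synthetic cohort."""

    config: SimulationConfig
    manifest: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for gi, group in enumerate(self.config.groups):
            for si in range(group.n_subjects):
                subject, sex, paw = _subject_meta(self.config, gi, si)
                rows.append(
                    dict(subject=subject, group=group.label, genotype=group.genotype,
                         sex=sex, condition=group.condition, preferred_paw=paw)
                )
        self.manifest = pd.DataFrame(rows)

    def iter_sessions(self) -> Iterator[SessionSim]:
        """Regenerate every subject-day deterministically, one at a time."""
        for gi, group in enumerate(self.config.groups):
            for si in range(group.n_subjects):
                for day in range(1, self.config.days + 1):
                    yield simulate_subject_day(self.config, gi, si, day)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    return SimulatedCohort(config=config)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write pose CSVs (one per subject-day), manifest.tsv and ground_truth.tsv."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    gts = []
    for session in cohort.iter_sessions():
        write_pose_table(session.pose, out / f"{session.subject}_day{session.day}.csv")
        gts.append(session.ground_truth)
    manifest_path = out / "manifest.tsv"
    cohort.manifest.to_csv(manifest_path, sep="\t", index=False)
    gt_path = out / "ground_truth.tsv"
    pd.concat(gts, ignore_index=True).to_csv(gt_path, sep="\t", index=False)
    return {"manifest": manifest_path, "ground_truth": gt_path, "poses": out}


# ---------------------------------------------------------------------------
# fast paths: outcome-only and reach-only cohorts

from .scoring import TrialRecord  # noqa: E402  (no cycle: scoring does not import simulate)


def simulate_outcome_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TrialRecord]:
    """Trial outcome labels for a whole cohort, skipping pose rendering.

    Uses the same label-generation path as :func:`simulate_trial`, so outcome
    statistics are distributed identically to the full simulation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records = []
    for gi, group in enumerate(config.groups):
        for si in range(group.n_subjects):
            subject = f"{group.label}{si:02d}"
            for day in range(1, config.days + 1):
                q = group.success_curve(day)
                for t in range(config.trials_per_day):
                    labels = draw_trial_labels(rng, q, config)
                    records.append(
                        TrialRecord(
                            subject=subject, day=day, trial=t, labels=labels,
                            no_try=not labels, condition=group.condition, group=group.label,
                        )
                    )
    return records


def simulate_session_reaches(
    config: SimulationConfig,
    group: GroupParams,
    subject: str,
    day: int,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> list[tuple[Reach, str]]:
    """Ground-truth reach point sequences for one subject-day, without frame
    placement (for kinematic simulations the 13-s timeline is irrelevant)."""
    out = []
    k = 0
    for t in range(n_trials if n_trials is not None else config.trials_per_day):
        for lab in draw_trial_labels(rng, group.success_curve(day), config):
            xy, _, apex = simulate_reach_trajectory(config, day, group, lab, rng)
            k += 1
            reach = Reach(
                frames=np.arange(apex + 1), xy=xy[: apex + 1],
                subject=subject, day=day, trial=t, ordinal=k,
            )
            out.append((reach, lab))
    return out
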