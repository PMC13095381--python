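"""Reach-outcome taxonomy, session summaries and the rate metrics.

Outcome labels:

* ``success`` — one continuous reach-and-grasp that retrieves the pellet;
* ``complete_miss`` — targeted reach with no paw–pellet contact;
* ``contact_miss`` — contact but failed grasp/retrieval;
* ``other`` — any other targeted reach;
* ``vain`` — reach made while no pellet was on the platform.

All labels except ``vain`` are "targeted reaches" and form the denominator of
the per-reach success and miss percentages; vain reaches are counted against
total reaches. Trials with no reach at all are "No Try" and are excluded from
trial-level success denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import REACH_LABELS, TARGETED_LABELS
from .detect import Reach


class ScoringError(ValueError):
    pass


MISSING = float("nan")


@dataclass
class TrialRecord:
    """One trial's labeled reaches and outcome flags."""

    subject: str
    day: int
    trial: int
    labels: list[str] = field(default_factory=list)
    no_try: bool = False
    condition: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in REACH_LABELS:
                raise ScoringError(f"unknown reach label {lab!r}")
        if self.no_try != (len(self.labels) == 0):
            raise ScoringError("no_try must hold exactly when the trial has zero reaches")
        if self.labels.count("success") > 1:
            raise ScoringError(
                "more than one success in a trial: the pellet is removed on retrieval"
            )

    @property
    def success(self) -> bool:
        return "success" in self.labels

    @property
    def first_reach_success(self) -> bool:
        return bool(self.labels) and self.labels[0] == "success"


@dataclass
class SessionSummary:
    """Per subject-day outcome counts."""

    subject: str
    day: int
    n_trials: int
    n_no_try: int
    n_success_trials: int
    n_first_reach_success_trials: int
    label_counts: dict[str, int]
    condition: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        for lab in REACH_LABELS:
            self.label_counts.setdefault(lab, 0)
        if any(v < 0 for v in self.label_counts.values()):
            raise ScoringError("negative label count")

    @property
    def n_trials_attempted(self) -> int:
        return self.n_trials - self.n_no_try

    @property
    def n_total_reaches(self) -> int:
        return sum(self.label_counts.values())

    @property
    def n_targeted(self) -> int:
        return sum(self.label_counts[lab] for lab in TARGETED_LABELS)


def summarize_session(trials: list[TrialRecord]) -> SessionSummary:
    """Aggregate one subject-day's trials into outcome counts."""
    if not trials:
        raise ScoringError("cannot summarize an empty trial list")
    keys = {(t.subject, t.day) for t in trials}
    if len(keys) > 1:
        raise ScoringError(f"trials span multiple subject-days: {sorted(keys)}")
    counts = {lab: 0 for lab in REACH_LABELS}
    for t in trials:
        for lab in t.labels:
            counts[lab] += 1
    return SessionSummary(
        subject=trials[0].subject,
        day=trials[0].day,
        n_trials=len(trials),
        n_no_try=sum(t.no_try for t in trials),
        n_success_trials=sum(t.success for t in trials),
        n_first_reach_success_trials=sum(t.first_reach_success for t in trials),
        label_counts=counts,
        condition=trials[0].condition,
        group=trials[0].group,
    )


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else MISSING


def success_rate_by_trial(summary: SessionSummary) -> float:
    """% of successful trials among trials with ≥ 1 reach (No Try excluded)."""
    return _pct(summary.n_success_trials, summary.n_trials_attempted)


def success_rate_by_reach(summary: SessionSummary) -> float:
    """% of successful reaches among targeted reaches."""
    return _pct(summary.label_counts["success"], summary.n_targeted)


def failure_and_vain_rates(summary: SessionSummary) -> dict[str, float]:
    """Complete/contact-miss % of targeted reaches, first-reach success % of
    attempted trials, and vain % of total reaches."""
    return {
        "complete_miss_pct": _pct(summary.label_counts["complete_miss"], summary.n_targeted),
        "contact_miss_pct": _pct(summary.label_counts["contact_miss"], summary.n_targeted),
        "first_reach_success_pct": _pct(
            summary.n_first_reach_success_trials, summary.n_trials_attempted
        ),
        "vain_pct": _pct(summary.label_counts["vain"], summary.n_total_reaches),
    }


def metrics_table(summaries: list[SessionSummary]) -> pd.DataFrame:
    """One row per subject-day with every outcome metric (the learning-curve input)."""
    rows = []
    for s in summaries:
        row = {
            "subject": s.subject,
            "day": s.day,
            "group": s.group,
            "condition": s.condition,
            "n_trials": s.n_trials,
            "n_no_try": s.n_no_try,
            "n_trials_attempted": s.n_trials_attempted,
            "n_total_reaches": s.n_total_reaches,
            "n_targeted": s.n_targeted,
            "success_by_trial_pct": success_rate_by_trial(s),
            "success_by_reach_pct": success_rate_by_reach(s),
        }
        row.update(failure_and_vain_rates(s))
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_distribution(
    summaries: list[SessionSummary],
    day: int,
    per_subject_weighting: bool = False,
) -> pd.DataFrame:
    """Per-group fractions of targeted-reach outcomes on one day.

    Fractions are over targeted reaches pooled within group (or, optionally,
    the unweighted mean of per-subject fractions) and sum to 1 per group.
    """
    day_summaries = [s for s in summaries if s.day == day and s.n_targeted > 0]
    if not day_summaries:
        raise ScoringError(f"no targeted reaches on day {day}")
    rows = []
    for group in sorted({s.group for s in day_summaries}, key=str):
        members = [s for s in day_summaries if s.group == group]
        if per_subject_weighting:
            fracs = np.mean(
                [
                    [s.label_counts[lab] / s.n_targeted for lab in TARGETED_LABELS]
                    for s in members
                ],
                axis=0,
            )
        else:
            tot = sum(s.n_targeted for s in members)
            fracs = [sum(s.label_counts[lab] for s in members) / tot for lab in TARGETED_LABELS]
        rows.append({"group": group, "day": day, **dict(zip(TARGETED_LABELS, fracs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# building trial records from detections + labels


def records_from_labels(
    labels: pd.DataFrame,
    n_trials: int | None = None,
    subject: str | None = None,
    day: int | None = None,
    **meta,
) -> list[TrialRecord]:
    """Build TrialRecords from a long label table (subject, day, trial, ordinal,
    label); trials absent from the table (up to ``n_trials``) become No Try."""
    if labels.empty and n_trials is None:
        return []
    subject = subject if subject is not None else labels["subject"].iloc[0]
    day = int(day if day is not None else labels["day"].iloc[0])
    by_trial: dict[int, list[tuple[int, str]]] = {}
    for _, row in labels.iterrows():
        by_trial.setdefault(int(row["trial"]), []).append((int(row["ordinal"]), str(row["label"])))
    trial_ids = range(n_trials) if n_trials is not None else sorted(by_trial)
    records = []
    for t in trial_ids:
        labs = [lab for _, lab in sorted(by_trial.get(t, []))]
        records.append(
            TrialRecord(
                subject=subject, day=day, trial=t, labels=labs, no_try=not labs, **meta
            )
        )
    return records


# ---------------------------------------------------------------------------
# optional geometric auto-classifier


def auto_classify_reach(
    reach: Reach,
    pellet_xy: tuple[float, float],
    pellet_present: tuple[int, int],
    slit_x: float,
    toward_sign: int = 1,
    contact_radius_px: float = 15.0,
    retrieved: bool | None = None,
) -> str:
    """Geometric surrogate for manual outcome scoring.

    ``pellet_present`` is the [start, end) frame interval during which the
    pellet sat on the platform. A reach starting outside it is ``vain``; a
    targeted reach whose minimal paw–pellet distance exceeds
    ``contact_radius_px`` is a ``complete_miss``; contact with retrieval
    (``retrieved`` — e.g. the pellet track crossing back through the slit or
    disappearing with the retracting paw) is a ``success``, contact without
    retrieval a ``contact_miss``. Never emits ``other``.
    """
    if pellet_xy is None:
        raise ScoringError("auto-classification requires a pellet track")
    lo, hi = pellet_present
    if not (lo <= reach.start_frame < hi):
        return "vain"
    dmin = min(
        math.hypot(x - pellet_xy[0], y - pellet_xy[1]) for x, y in reach.xy
    )
    if dmin > contact_radius_px:
        return "complete_miss"
    if retrieved:
        return "success"
    return "contact_miss"


def infer_retrieval(
    reach: Reach,
    pellet_point: pd.DataFrame,
    frames: np.ndarray,
    slit_x: float,
    toward_sign: int = 1,
    p_cutoff: float = 0.85,
    margin_frames: int = 120,
) -> bool:
    """Heuristic retrieval detector for the auto-classifier.

    Retrieval shows up in the pellet track as the pellet leaving the platform
    with the retracting paw: shortly after the reach end the pellet either
    crosses back through the slit plane or stops being confidently tracked.
    """
    lik = pellet_point["likelihood"].to_numpy(float)
    x = pellet_point["x"].to_numpy(float)
    sel = (frames > reach.end_frame) & (frames <= reach.end_frame + margin_frames)
    if not np.any(sel):
        return False
    gone = lik[sel] < p_cutoff
    crossed = toward_sign * (x[sel] - slit_x) < 0
    return bool(np.all(gone | crossed) and np.any(gone | crossed))
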