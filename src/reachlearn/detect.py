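"""Reach detection by directional-vector consensus.

A reach is an excursion of the paw dorsum out through the slit toward the
pellet and back. In a likelihood/bounds-filtered paw track, a reach START is
the earliest sample whose next ``window`` step vectors are (a) between
temporally adjacent retained samples and (b) at least ``consensus``-of-
``window`` directed toward the pellet. The RETRACTION ONSET (reach end) is
then the earliest subsequent sample whose window satisfies the opposite
predicate. Scanning alternates direction until the trial is exhausted;
candidates with fewer than ``min_points`` samples are discarded.

"Toward the pellet" is formalized as a strict decrease of the Euclidean
distance to the static per-trial pellet reference; a zero-length step counts
as neither toward nor away.

The start is the first sample of its qualifying window (that is how the
outward crossing is marked); the retraction onset is the pellet-distance
minimum within the first qualifying away-window — the sample at which the paw
actually begins moving back — so on a monotone out-and-back excursion the
reach ends exactly at the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import DetectionParams
from .tracking_io import FilteredTrack


class DetectionError(ValueError):
    pass


@dataclass
class Reach:
    """One detected outward-and-retract paw excursion.

    The point sequence runs from the outward start sample to the retraction
    onset inclusive; the retraction phase itself is not part of the reach.
    """

    frames: np.ndarray  # (n,) original frame indices
    xy: np.ndarray  # (n, 2) pixel coordinates
    paw: str = "right_paw"
    subject: str | None = None
    day: int | None = None
    trial: int | None = None
    ordinal: int | None = None  # 1-based order within trial

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy):
            raise DetectionError("frames and xy must have equal length")
        if len(self.frames) >= 2 and self.frames[0] >= self.frames[-1]:
            raise DetectionError("reach start_frame must precede end_frame")

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_points(self) -> int:
        return len(self.frames)


def step_toward_pellet(
    p_from: tuple[float, float],
    p_to: tuple[float, float],
    pellet: tuple[float, float],
) -> bool:
    """True iff the step strictly decreases Euclidean distance to the pellet.

    A zero-length step returns False (neither toward nor away).
    """
    d_from = math.hypot(p_from[0] - pellet[0], p_from[1] - pellet[1])
    d_to = math.hypot(p_to[0] - pellet[0], p_to[1] - pellet[1])
    return d_to < d_from


def find_reaches(track: FilteredTrack, params: DetectionParams) -> list[Reach]:
    """Segment a filtered paw track into reaches.

    Returns reaches in order of start frame; a track shorter than
    ``min_points`` yields an empty list.
    """
    n = len(track)
    w = params.window
    if n < params.min_points:
        return []
    frames = track.frames
    xy = track.xy
    dist = np.hypot(xy[:, 0] - params.pellet_ref[0], xy[:, 1] - params.pellet_ref[1])
    diff = np.diff(dist)  # (n-1,) step-wise change of pellet distance
    toward = diff < 0.0
    away = diff > 0.0
    adjacent = np.diff(frames) <= params.max_gap

    def window_ok(i: int, direction: np.ndarray) -> bool:
        # all w vectors from sample i must be adjacent, >= consensus directed
        if i + w >= n:
            return False
        sl = slice(i, i + w)
        return bool(np.all(adjacent[sl]) and int(np.count_nonzero(direction[sl])) >= params.consensus)

    reaches: list[Reach] = []
    i = 0
    while True:
        start = next((j for j in range(i, n - w) if window_ok(j, toward)), None)
        if start is None:
            break
        anchor = next((j for j in range(start + 1, n - w) if window_ok(j, away)), None)
        if anchor is None:
            break
        # retraction onset: the closest approach within the qualifying window
        end = anchor + int(np.argmin(dist[anchor : anchor + w + 1]))
        if end - start + 1 >= params.min_points:
            reaches.append(Reach(frames=frames[start : end + 1], xy=xy[start : end + 1]))
        i = end + 1
    for k, r in enumerate(reaches, start=1):
        r.ordinal = k
        r.paw = track.point
    return reaches


@dataclass
class TrialReaches:
    """Skeleton of a trial record: its window and the reaches assigned to it."""

    trial: int
    start_frame: int
    end_frame: int  # exclusive
    reaches: list[Reach] = field(default_factory=list)

    @property
    def no_try(self) -> bool:
        return len(self.reaches) == 0


def assign_reaches_to_trials(
    reaches: list[Reach],
    trial_windows: list[tuple[int, int, int]],
) -> tuple[list[TrialReaches], list[Reach]]:
    """Assign each reach to the trial window containing its start frame.

    ``trial_windows`` is a list of ``(trial_index, start_frame, end_frame)``
    with end exclusive; windows must not overlap. Returns the per-trial
    skeletons (trials with no reach are flagged ``no_try``) and the reaches
    falling outside every window.
    """
    wins = sorted(trial_windows, key=lambda t: t[1])
    for (_, s0, e0), (t1, s1, _) in zip(wins, wins[1:]):
        if s1 < e0:
            raise DetectionError(f"trial windows overlap at trial {t1}")
    for t, s, e in wins:
        if e <= s:
            raise DetectionError(f"empty trial window for trial {t}")
    trials = [TrialReaches(trial=t, start_frame=s, end_frame=e) for t, s, e in wins]
    unassigned: list[Reach] = []
    for reach in sorted(reaches, key=lambda r: r.start_frame):
        for tr in trials:
            if tr.start_frame <= reach.start_frame < tr.end_frame:
                reach.trial = tr.trial
                reach.ordinal = len(tr.reaches) + 1
                tr.reaches.append(reach)
                break
        else:
            unassigned.append(reach)
    return trials, unassigned
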