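"""Per-reach trajectory metrics and their subject-by-day aggregates.

Metrics are computed on the raw reach point sequence (outward start to
retraction onset) without any temporal smoothing:

* path length — sum of Euclidean step lengths along the sequence (a ``chord``
  variant, first-to-last straight-line distance, is selectable);
* ΔY — max(y) − min(y), the vertical spread of the reach;
* ΔX — maximal signed extension beyond the slit plane, floored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Reach


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class ReachKinematics:
    path_length: float
    delta_y: float
    delta_x: float
    n_points: int
    duration: float  # s


def reach_path_length(reach: Reach, metric: str = "path") -> float:
    """Trajectory length in px; ``metric="chord"`` gives first-to-last distance."""
    if reach.n_points < 2:
        raise KinematicsError("path length undefined for a reach with < 2 samples")
    if metric == "chord":
        return float(np.hypot(*(reach.xy[-1] - reach.xy[0])))
    if metric != "path":
        raise KinematicsError(f"unknown distance metric {metric!r}")
    steps = np.diff(reach.xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def reach_delta_y(reach: Reach) -> float:
    if reach.n_points < 1:
        raise KinematicsError("ΔY undefined for an empty reach")
    y = reach.xy[:, 1]
    return float(y.max() - y.min())


def reach_delta_x(reach: Reach, slit_x: float, toward_sign: int = 1) -> float:
    """Maximal extension beyond the slit plane, in the pellet direction, ≥ 0."""
    if reach.n_points < 1:
        raise KinematicsError("ΔX undefined for an empty reach")
    ext = toward_sign * (reach.xy[:, 0] - slit_x)
    return float(max(ext.max(), 0.0))


def compute_kinematics(
    reach: Reach,
    slit_x: float,
    toward_sign: int = 1,
    fps: float = 240.0,
    metric: str = "path",
) -> ReachKinematics:
    return ReachKinematics(
        path_length=reach_path_length(reach, metric=metric),
        delta_y=reach_delta_y(reach),
        delta_x=reach_delta_x(reach, slit_x, toward_sign),
        n_points=reach.n_points,
        duration=(reach.end_frame - reach.start_frame) / fps,
    )


def kinematics_table(
    reaches: list[Reach],
    slit_x: float,
    toward_sign: int = 1,
    fps: float = 240.0,
    metric: str = "path",
) -> pd.DataFrame:
    """One row per reach: subject, day, trial, ordinal and the three metrics."""
    rows = []
    for r in reaches:
        k = compute_kinematics(r, slit_x, toward_sign, fps, metric)
        rows.append(
            {
                "subject": r.subject,
                "day": r.day,
                "trial": r.trial,
                "ordinal": r.ordinal,
                "path_length_px": k.path_length,
                "delta_y_px": k.delta_y,
                "delta_x_px": k.delta_x,
                "duration_s": k.duration,
                "n_points": k.n_points,
            }
        )
    cols = [
        "subject",
        "day",
        "trial",
        "ordinal",
        "path_length_px",
        "delta_y_px",
        "delta_x_px",
        "duration_s",
        "n_points",
    ]
    return pd.DataFrame(rows, columns=cols)


def aggregate_kinematics(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject-day arithmetic means of the reach metrics.

    Subject-days with zero reaches are absent from the input and therefore
    yield missing values downstream (they are NOT zeros); the longitudinal
    statistics treat them as missing, switching to the mixed-model branch.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["subject", "day", "path_length_px", "delta_y_px", "delta_x_px", "n_reaches"]
        )
    g = table.groupby(["subject", "day"], as_index=False)
    out = g.agg(
        path_length_px=("path_length_px", "mean"),
        delta_y_px=("delta_y_px", "mean"),
        delta_x_px=("delta_x_px", "mean"),
        n_reaches=("path_length_px", "size"),
    )
    return out
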