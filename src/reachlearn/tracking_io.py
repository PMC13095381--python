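"""Reading, writing and filtering pose-coordinate tables.

The canonical on-disk format is the markerless pose-estimation CSV dialect
with three stacked header rows (scorer / bodyparts / coords) and per-bodypart
``x, y, likelihood`` column triples; the first column is the integer frame
index. An HDF5 variant of the same layout is supported read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BODYPARTS, COORDS, TrackingBounds


class PoseTableError(ValueError):
    """The pose table violates the dialect or a :class:`PoseTrack` invariant."""


@dataclass
class PoseTrack:
    """Per-frame coordinates and likelihoods for all tracked points of one video.

    ``data`` has a two-level column index ``(bodypart, coord)`` with coords
    ``x, y, likelihood`` and an integer, strictly increasing frame index.
    """

    data: pd.DataFrame
    fps: float = 240.0
    subject: str | None = None
    day: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        cols = self.data.columns
        if cols.nlevels != 2:
            raise PoseTableError("pose data must have (bodypart, coord) columns")
        for bp in self.bodyparts:
            for coord in COORDS:
                if (bp, coord) not in cols:
                    raise PoseTableError(f"missing column ({bp!r}, {coord!r})")
        idx = self.data.index.to_numpy()
        if len(idx) and (not np.issubdtype(idx.dtype, np.integer) or np.any(np.diff(idx) <= 0)):
            bad = int(np.argmax(np.diff(idx) <= 0)) + 1 if len(idx) > 1 else 0
            raise PoseTableError(f"frame index not strictly increasing at row {bad}")
        for bp in self.bodyparts:
            lik = self.data[(bp, "likelihood")].to_numpy(float)
            if len(lik) and (np.nanmin(lik) < 0.0 or np.nanmax(lik) > 1.0):
                row = int(np.argmax((lik < 0) | (lik > 1)))
                raise PoseTableError(
                    f"likelihood out of [0,1] for {bp!r} at row {row}: {lik[row]}"
                )

    @property
    def bodyparts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def point(self, bodypart: str) -> pd.DataFrame:
        """The (x, y, likelihood) sub-table of one tracked point."""
        if bodypart not in self.bodyparts:
            raise PoseTableError(f"unknown tracked point {bodypart!r}")
        return self.data[bodypart]

    def equals(self, other: "PoseTrack") -> bool:
        return self.data.equals(other.data)


@dataclass
class FilteredTrack:
    """Retained samples of ONE tracked point after likelihood/bounds filtering.

    Original frame indices are preserved; gaps where samples were rejected are
    allowed and visible as jumps in ``frames``.
    """

    point: str
    frames: np.ndarray  # (n,) int
    xy: np.ndarray  # (n, 2) float
    likelihood: np.ndarray  # (n,) float
    p_cutoff: float
    bounds: TrackingBounds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.frames) == len(self.xy) == len(self.likelihood)):
            raise PoseTableError("filtered track arrays must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise PoseTableError("filtered frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# I/O


def _format_value(v: float) -> str:
    # repr gives the shortest digit string that round-trips the float exactly,
    # which keeps write→read value-identical and writes byte-stable.
    if v != v:  # NaN
        return "nan"
    return repr(float(v))


def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "reachlearn") -> None:
    """Write a :class:`PoseTrack` as a three-header-row pose CSV."""
    path = Path(path)
    bps = track.bodyparts
    lines = [
        "scorer," + ",".join(scorer for _ in bps for _ in COORDS),
        "bodyparts," + ",".join(bp for bp in bps for _ in COORDS),
        "coords," + ",".join(c for _ in bps for c in COORDS),
    ]
    values = track.data[[(bp, c) for bp in bps for c in COORDS]].to_numpy(float)
    for frame, row in zip(track.frames, values):
        lines.append(str(int(frame)) + "," + ",".join(_format_value(v) for v in row))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write pose table to {path}: {exc}") from exc


def read_pose_table(
    path: str | Path,
    fps: float = 240.0,
    subject: str | None = None,
    day: int | None = None,
) -> PoseTrack:
    """Read a pose table (CSV dialect, or the HDF5 variant for ``.h5`` paths)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path)
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
        except (ValueError, pd.errors.ParserError) as exc:
            raise PoseTableError(f"{path}: malformed pose table header: {exc}") from exc
    if df.columns.nlevels != 3:
        raise PoseTableError(f"{path}: expected scorer/bodyparts/coords header rows")
    df = df.droplevel(0, axis=1)  # drop the scorer level
    coords = set(df.columns.get_level_values(1))
    unknown = coords - set(COORDS)
    if unknown:
        raise PoseTableError(f"{path}: unknown coord column(s) {sorted(unknown)}")
    df.index = df.index.astype(np.int64)
    df = df.astype(float)
    df.columns = df.columns.remove_unused_levels()
    return PoseTrack(data=df, fps=fps, subject=subject, day=day)


def build_pose_track(
    frames: np.ndarray,
    points: dict[str, np.ndarray],
    fps: float = 240.0,
    subject: str | None = None,
    day: int | None = None,
) -> PoseTrack:
    """Assemble a :class:`PoseTrack` from per-point ``(n, 3)`` x/y/likelihood arrays."""
    cols = {}
    for bp, arr in points.items():
        arr = np.asarray(arr, dtype=float)
        for j, coord in enumerate(COORDS):
            cols[(bp, coord)] = arr[:, j]
    df = pd.DataFrame(cols, index=pd.Index(np.asarray(frames, dtype=np.int64)))
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return PoseTrack(data=df, fps=fps, subject=subject, day=day)


# ---------------------------------------------------------------------------
# filtering


def filter_track(
    track: PoseTrack | FilteredTrack,
    point: str | None = None,
    p_cutoff: float = 0.85,
    bounds: TrackingBounds | None = None,
) -> FilteredTrack:
    """Retain the samples of one tracked point with likelihood ≥ ``p_cutoff``
    that lie inside ``bounds`` (boundary included).

    Accepts an already-filtered track, in which case re-filtering with the same
    parameters is the identity.
    """
    if not 0.0 <= p_cutoff <= 1.0:
        raise PoseTableError(f"p_cutoff {p_cutoff} not in [0,1]")
    if isinstance(track, FilteredTrack):
        frames, xy, lik = track.frames, track.xy, track.likelihood
        point = point or track.point
        bounds = bounds or track.bounds
    else:
        if point is None:
            raise PoseTableError("a tracked point label is required")
        sub = track.point(point)
        frames = track.frames
        xy = sub[["x", "y"]].to_numpy(float)
        lik = sub["likelihood"].to_numpy(float)
        if bounds is None:
            raise PoseTableError("tracking bounds are required")
    keep = (
        (lik >= p_cutoff)
        & (xy[:, 0] >= bounds.x_min)
        & (xy[:, 0] <= bounds.x_max)
        & (xy[:, 1] >= bounds.y_min)
        & (xy[:, 1] <= bounds.y_max)
    )
    return FilteredTrack(
        point=point,
        frames=frames[keep],
        xy=xy[keep],
        likelihood=lik[keep],
        p_cutoff=p_cutoff,
        bounds=bounds,
    )


def preferred_paw(track: PoseTrack, p_cutoff: float, bounds: TrackingBounds) -> str:
    """The paw with more retained in-bounds samples (proxy for the animal's
    preferred reaching paw); ties go to the right paw."""
    n_left = len(filter_track(track, "left_paw", p_cutoff, bounds))
    n_right = len(filter_track(track, "right_paw", p_cutoff, bounds))
    return "left_paw" if n_left > n_right else "right_paw"
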