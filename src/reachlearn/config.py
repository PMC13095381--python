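"""Shared parameter types and configuration loading.

All coordinates are image pixels with the origin at the top-left corner and y
increasing downward, the native convention of markerless pose-tracking output;
frame indices are 0-based. Every module in the package uses this convention.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

#: Bodyparts tracked in the single-pellet task, in canonical column order.
BODYPARTS: tuple[str, ...] = ("left_paw", "right_paw", "nose", "pellet")
COORDS: tuple[str, ...] = ("x", "y", "likelihood")

#: Likelihood threshold below which tracked points are discarded.
DEFAULT_P_CUTOFF: float = 0.85

#: Reach outcome taxonomy. All labels except ``vain`` require the pellet to be
#: on the platform ("targeted reaches"); a vain reach is made with no pellet
#: present.
REACH_LABELS: tuple[str, ...] = (
    "success",
    "complete_miss",
    "contact_miss",
    "vain",
    "other",
)
TARGETED_LABELS: tuple[str, ...] = ("success", "complete_miss", "contact_miss", "other")


class ConfigError(ValueError):
    """A configuration value violates its invariants."""


@dataclass(frozen=True)
class TrackingBounds:
    """Axis-aligned pixel rectangle covering the area outside the slit.

    Reach detection only considers paw samples inside these bounds; points on
    the boundary are retained.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ConfigError(
                f"degenerate tracking bounds {self.x_min, self.x_max, self.y_min, self.y_max}"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the directional-vector consensus reach detector.

    A reach needs at least ``min_points`` samples; a start (or retraction
    onset) is declared when at least ``consensus`` of ``window`` consecutive
    step vectors point toward (away from) the pellet, with consecutive retained
    samples no more than ``max_gap`` frames apart.
    """

    pellet_ref: tuple[float, float]
    min_points: int = 6
    window: int = 5
    consensus: int = 4
    max_gap: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.consensus <= self.window):
            raise ConfigError(f"consensus {self.consensus} not in [1, window={self.window}]")
        if self.min_points < self.window + 1:
            raise ConfigError(
                f"min_points {self.min_points} must be >= window+1 ({self.window + 1})"
            )
        if self.max_gap < 1:
            raise ConfigError("max_gap must be >= 1")


@dataclass(frozen=True)
class DecayCurve:
    """Exponential day-decay ``value(day) = end + (start-end)·exp(-rate·(day-1))``.

    Used for trajectory noise, overshoot and vertical spread, which all shrink
    as the animal refines its reach over training days.
    """

    start: float
    end: float
    rate: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.start, self.end, self.rate):
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"decay curve parameters must be finite nonnegative, got {self}")

    def __call__(self, day: int | float) -> float:
        return self.end + (self.start - self.end) * math.exp(-self.rate * (day - 1))


@dataclass(frozen=True)
class LogisticCurve:
    """Logistic learning curve for per-attempt success probability.

    ``q(day) = baseline + (asymptote-baseline) / (1 + exp(-rate·(day-midpoint)))``
    """

    baseline: float
    asymptote: float
    rate: float = 1.0
    midpoint: float = 4.5

    def __post_init__(self) -> None:
        for v in (self.baseline, self.asymptote):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"success probabilities must lie in [0,1], got {self}")
        if self.rate < 0:
            raise ConfigError("learning rate must be nonnegative")

    def __call__(self, day: int | float) -> float:
        return self.baseline + (self.asymptote - self.baseline) / (
            1.0 + math.exp(-self.rate * (day - self.midpoint))
        )


@dataclass(frozen=True)
class GroupParams:
    """Per-group generative parameters of a simulated cohort."""

    label: str
    genotype: str = "WT"  # {"WT", "KO"}
    condition: str = "door"  # {"door", "no_door"}
    n_subjects: int = 10
    success_curve: LogisticCurve = field(
        default_factory=lambda: LogisticCurve(baseline=0.08, asymptote=0.45, rate=1.0)
    )
    trajectory_noise_sigma_curve: DecayCurve = field(
        default_factory=lambda: DecayCurve(start=3.0, end=1.0)
    )
    overshoot_curve: DecayCurve = field(default_factory=lambda: DecayCurve(start=25.0, end=5.0))
    vertical_spread_curve: DecayCurve = field(
        default_factory=lambda: DecayCurve(start=18.0, end=6.0)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.genotype not in ("WT", "KO"):
            raise ConfigError(f"unknown genotype {self.genotype!r}")
        if self.condition not in ("door", "no_door"):
            raise ConfigError(f"unknown condition {self.condition!r}")


def default_groups() -> list[GroupParams]:
    """A WT and an Fmr1-KO group mirroring the study's Door-condition design."""
    return [
        GroupParams(label="WT", genotype="WT"),
        GroupParams(
            label="KO",
            genotype="KO",
            success_curve=LogisticCurve(baseline=0.08, asymptote=0.25, rate=1.0),
            vertical_spread_curve=DecayCurve(start=18.0, end=10.0),
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic reaching cohort.

    Defaults reproduce the task structure of the study: 8 training days of 50
    trials each, 13 s of pellet access per trial filmed at 240 fps from the
    side, with the slit on the left and the pellet in a divot to its right.
    """

    groups: Sequence[GroupParams] = field(default_factory=default_groups)
    days: int = 8
    trials_per_day: int = 50
    fps: float = 240.0
    access_window_s: float = 13.0
    slit_x: float = 100.0
    pellet_xy: tuple[float, float] = (160.0, 200.0)
    vain_rate: float = 0.15
    no_try_rate: float = 0.08
    dropout_prob: float = 0.0
    #: probability of drawing 1, 2, ... planned attempts per trial
    reaches_per_trial_dist: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 2:
            raise ConfigError("days must be >= 2")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.trials_per_day < 1:
            raise ConfigError("trials_per_day must be >= 1")
        for name in ("vain_rate", "no_try_rate", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0,1]")
        p = self.reaches_per_trial_dist
        if not p or any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigError("reaches_per_trial_dist must be a probability vector")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.access_window_s * self.fps))

    @property
    def toward_sign(self) -> int:
        """+1 if the pellet lies at larger x than the slit plane."""
        return 1 if self.pellet_xy[0] >= self.slit_x else -1

    def bounds(self) -> TrackingBounds:
        """Default tracking bounds: the region beyond the slit around the pellet."""
        px, py = self.pellet_xy
        span = max(3.0 * abs(px - self.slit_x), 60.0) + 60.0
        if self.toward_sign > 0:
            return TrackingBounds(self.slit_x, self.slit_x + span, py - 140.0, py + 140.0)
        return TrackingBounds(self.slit_x - span, self.slit_x, py - 140.0, py + 140.0)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(pellet_ref=self.pellet_xy)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration (paths + analysis parameters)."""

    poses_dir: str
    manifest: str
    out_dir: str
    annotations: str | None = None
    auto_classify: bool = False
    p_cutoff: float = DEFAULT_P_CUTOFF
    bounds: TrackingBounds = field(
        default_factory=lambda: TrackingBounds(100.0, 380.0, 60.0, 340.0)
    )
    detection: DetectionParams = field(
        default_factory=lambda: DetectionParams(pellet_ref=(160.0, 200.0))
    )
    slit_x: float = 100.0
    toward_sign: int = 1
    fps: float = 240.0
    frames_per_trial: int = 3120
    trials_per_day: int = 50
    contact_radius_px: float = 15.0
    distance_metric: str = "path"  # {"path", "chord"}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ConfigError("p_cutoff must lie in [0,1]")
        if self.toward_sign not in (-1, 1):
            raise ConfigError("toward_sign must be +1 or -1")
        if self.distance_metric not in ("path", "chord"):
            raise ConfigError(f"unknown distance metric {self.distance_metric!r}")
        if self.annotations is None and not self.auto_classify:
            raise ConfigError(
                "no reach annotations given and auto_classify disabled: "
                "outcome scoring has no label source"
            )


# ---------------------------------------------------------------------------
# serialization helpers


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg) -> dict:
    return _to_jsonable(cfg)


#: fields that locate inputs/outputs rather than parameterize the analysis
_PATH_FIELDS = frozenset({"poses_dir", "manifest", "out_dir", "annotations"})


def config_hash(cfg) -> str:
    """Short stable hash of the analysis parameters (path fields excluded, so
    identical analyses of the same data hash equal wherever they run)."""
    payload = {k: v for k, v in config_to_dict(cfg).items() if k not in _PATH_FIELDS}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _build(cls, data: dict):
    """Recursively construct a (frozen) dataclass from plain dict data."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "groups":
            v = [_build(GroupParams, g) if isinstance(g, dict) else g for g in v]
        elif f.name == "bounds" and isinstance(v, dict):
            v = _build(TrackingBounds, v)
        elif f.name == "detection" and isinstance(v, dict):
            v = _build(DetectionParams, v)
        elif isinstance(v, dict) and f.name.endswith("_curve"):
            curve_cls = LogisticCurve if "success" in f.name else DecayCurve
            v = _build(curve_cls, v)
        elif f.name in ("pellet_xy", "pellet_ref") and isinstance(v, list):
            v = tuple(v)
        elif f.name == "reaches_per_trial_dist" and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML (or JSON) file."""
    data = yaml.safe_load(Path(path).read_text())
    return _build(SimulationConfig, data or {})


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return _build(PipelineConfig, data or {})
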