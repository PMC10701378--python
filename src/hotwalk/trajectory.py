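"""Core trajectory types, CSV I/O and basic movement-path features.

A trajectory is an ordered sequence of timestamped planar positions for one
participant walking inside a 3 x 4 m arena, nominally sampled at 13 Hz.
The three basic features mirror the clinical report: total distance walked,
total duration, and mean speed (distance over duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GROUPS = ("AD", "aMCI", "NC")

#: canonical spelling for case-insensitive group parsing
_GROUP_ALIASES = {g.lower(): g for g in GROUPS}


def parse_group(label: str) -> str:
    """Normalize a group label (case-insensitive) to one of ``AD, aMCI, NC``."""
    try:
        return _GROUP_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown group label {label!r}; expected one of {GROUPS}"
        ) from None


@dataclass(frozen=True)
class TrajectoryPoint:
    """One tracked sample: time (s since session start) and position (m)."""

    t: float
    x: float
    y: float

    def __post_init__(self):
        if not (self.t >= 0 and math.isfinite(self.t)):
            raise ValidationError(f"timestamp must be finite and >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"coordinates must be finite, got ({self.x}, {self.y})")


@dataclass
class Trajectory:
    """Ordered position samples for one participant.

    Timestamps must be strictly increasing and the trajectory must contain at
    least two samples.  Internally the samples are held as float64 arrays
    (``t``, ``xy``) for speed; the ``points`` property offers the record view.
    """

    participant_id: str
    group: str
    t: np.ndarray
    xy: np.ndarray
    nominal_rate_hz: float = 13.0

    def __post_init__(self):
        self.group = parse_group(self.group)
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.nominal_rate_hz <= 0:
            raise ValidationError("nominal_rate_hz must be positive")
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValidationError("t must be 1-D and xy must be (n, 2)")
        if self.t.size < 2:
            raise ValidationError(
                f"trajectory for {self.participant_id!r} needs >= 2 samples"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValidationError(
                f"non-finite values in trajectory for {self.participant_id!r}"
            )
        if self.t[0] < 0:
            raise ValidationError("timestamps must be >= 0")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError(
                f"timestamps must be strictly increasing (participant "
                f"{self.participant_id!r} has duplicated or unordered times)"
            )

    @classmethod
    def from_points(
        cls,
        participant_id: str,
        group: str,
        points: Iterable[TrajectoryPoint | tuple],
        nominal_rate_hz: float = 13.0,
    ) -> "Trajectory":
        pts = [p if isinstance(p, TrajectoryPoint) else TrajectoryPoint(*p) for p in points]
        t = np.array([p.t for p in pts])
        xy = np.array([[p.x, p.y] for p in pts])
        return cls(participant_id, group, t, xy, nominal_rate_hz)

    @property
    def points(self) -> list[TrajectoryPoint]:
        return [TrajectoryPoint(ti, xi, yi) for ti, (xi, yi) in zip(self.t, self.xy)]

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and sampling of the virtual living room.

    The tracked floor is a ``width_m`` x ``depth_m`` rectangle (default
    3 x 4 m); sessions start at the arena center where the item box sits,
    and positions are sampled at ``rate_hz`` (default 13 Hz).
    """

    width_m: float = 3.0
    depth_m: float = 4.0
    start_xy: tuple[float, float] | None = None
    rate_hz: float = 13.0

    def __post_init__(self):
        if self.width_m <= 0 or self.depth_m <= 0:
            raise ValidationError("arena dimensions must be positive")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if self.start_xy is None:
            object.__setattr__(self, "start_xy", (self.width_m / 2, self.depth_m / 2))
        sx, sy = self.start_xy
        if not (0 <= sx <= self.width_m and 0 <= sy <= self.depth_m):
            raise ValidationError("start point must lie inside the arena")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_m / 2, self.depth_m / 2)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz


#: Column order of the participant-by-feature table.
FEATURE_COLUMNS = [
    "participant_id",
    "group",
    "total_distance_m",
    "total_duration_s",
    "mean_speed_mps",
    "n_outliers",
    "mean_outlier_run_distance_m",
    "n_stay_points",
]

#: Feature columns that belong to the trajectory-pattern-mining family
#: (the family over which FDR correction is applied downstream).
MINING_FEATURES = ["n_outliers", "mean_outlier_run_distance_m", "n_stay_points"]
BASIC_FEATURES = ["total_distance_m", "total_duration_s", "mean_speed_mps"]


def to_arena_frame(traj: Trajectory, arena: ArenaConfig) -> Trajectory:
    """Translate a trajectory so its first sample sits at the arena center.

    The raw tracker reports positions in an opaque world frame; every feature
    computed here is translation-invariant, so this is only a convenience for
    plotting and containment checks.
    """
    cx, cy = arena.center
    shift = np.array([cx, cy]) - traj.xy[0]
    return Trajectory(traj.participant_id, traj.group, traj.t.copy(),
                      traj.xy + shift, traj.nominal_rate_hz)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["participant_id", "group", "t", "x", "y"]


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV (columns participant_id, group, t, x, y).

    Rows are grouped by participant and sorted by time within each.  Returns
    trajectories in order of first appearance of each participant.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"trajectory file {path!s} is missing column(s): {', '.join(missing)}"
        )
    out = []
    for pid in df["participant_id"].astype(str).unique():
        sub = df[df["participant_id"].astype(str) == pid].sort_values("t")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"participant {pid!r} has multiple group labels")
        t = sub["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"participant {pid!r} has duplicated timestamps after sorting"
            )
        out.append(Trajectory(pid, parse_group(groups[0]), t,
                              sub[["x", "y"]].to_numpy(dtype=float)))
    return out


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories to CSV in the package dialect (6 decimal places)."""
    frames = [
        pd.DataFrame({
            "participant_id": traj.participant_id,
            "group": traj.group,
            "t": traj.t,
            "x": traj.xy[:, 0],
            "y": traj.xy[:, 1],
        })
        for traj in trajectories
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_REQUIRED_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Basic features
# ---------------------------------------------------------------------------


def path_length(traj: Trajectory) -> float:
    """Total distance walked: sum of Euclidean step lengths (m)."""
    steps = np.diff(traj.xy, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def duration(traj: Trajectory) -> float:
    """Total duration: last minus first timestamp (s)."""
    return float(traj.t[-1] - traj.t[0])


def mean_speed(traj: Trajectory) -> float:
    """Mean speed as total distance over total duration (m/s)."""
    dur = duration(traj)
    if dur <= 0:
        raise ValidationError("mean speed undefined for zero duration")
    return path_length(traj) / dur


def basic_features(traj: Trajectory) -> dict:
    """Distance, duration and mean speed as a partial feature row."""
    dist = path_length(traj)
    dur = duration(traj)
    return {
        "participant_id": traj.participant_id,
        "group": traj.group,
        "total_distance_m": dist,
        "total_duration_s": dur,
        "mean_speed_mps": dist / dur,
    }
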