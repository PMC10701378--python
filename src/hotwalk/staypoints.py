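"""Stay-point detection: dwells within a distance threshold for a minimum time.

A stay point marks a stretch of samples that all remain within
``dist_threshold_m`` of an anchor sample for at least ``time_threshold_s``
(defaults 0.3 m and 2 s).  The scan is the classic anchor-based formulation:
from anchor ``i`` advance ``j`` while ``dist(p_i, p_j) <= d``; at the first
excursion (or trailing end) emit a stay point iff ``t[j-1] - t[i] >= tau``,
with centroid the mean of samples ``i..j-1``; afterwards the anchor jumps to
``j`` (emitted) or ``i+1`` (not emitted), so emitted windows never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .trajectory import Trajectory


@dataclass(frozen=True)
class StayPointConfig:
    dist_threshold_m: float = 0.3
    time_threshold_s: float = 2.0

    def __post_init__(self):
        if self.dist_threshold_m <= 0 or self.time_threshold_s <= 0:
            raise ValidationError("stay-point thresholds must be strictly positive")


@dataclass(frozen=True)
class StayPoint:
    """One dwell event: centroid of its member samples and arrival/departure."""

    centroid_x: float
    centroid_y: float
    t_arrive: float
    t_depart: float
    i_start: int
    i_end: int  # inclusive index of the last member sample

    @property
    def dwell_s(self) -> float:
        return self.t_depart - self.t_arrive


def detect_stay_points(
    traj: Trajectory, cfg: StayPointConfig | None = None
) -> list[StayPoint]:
    """Anchor-scan stay-point detection (see module docstring for semantics)."""
    cfg = cfg or StayPointConfig()
    d = cfg.dist_threshold_m
    tau = cfg.time_threshold_s
    xs = traj.xy[:, 0].tolist()
    ys = traj.xy[:, 1].tolist()
    ts = traj.t.tolist()
    n = len(ts)
    out: list[StayPoint] = []
    i = 0
    while i < n:
        xi, yi = xs[i], ys[i]
        j = i + 1
        while j < n and math.hypot(xs[j] - xi, ys[j] - yi) <= d:
            j += 1
        if ts[j - 1] - ts[i] >= tau:
            k = j - i
            out.append(StayPoint(
                centroid_x=math.fsum(xs[i:j]) / k,
                centroid_y=math.fsum(ys[i:j]) / k,
                t_arrive=ts[i],
                t_depart=ts[j - 1],
                i_start=i,
                i_end=j - 1,
            ))
            i = j
        else:
            i += 1
    return out


def count_stay_points(traj: Trajectory, cfg: StayPointConfig | None = None) -> int:
    """Number of stay points under the given thresholds."""
    return len(detect_stay_points(traj, cfg))


def stay_points_table(per_participant: dict[str, list[StayPoint]]) -> pd.DataFrame:
    """Flatten per-participant stay points into a tidy table."""
    rows = [
        {
            "participant_id": pid,
            "centroid_x": sp.centroid_x,
            "centroid_y": sp.centroid_y,
            "t_arrive": sp.t_arrive,
            "t_depart": sp.t_depart,
        }
        for pid, sps in per_participant.items()
        for sp in sps
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "centroid_x", "centroid_y",
                       "t_arrive", "t_depart"])
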