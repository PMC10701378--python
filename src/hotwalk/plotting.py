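"""Basic static plot of a trajectory with its mined annotations."""

from __future__ import annotations

from .outliers import OutlierResult
from .staypoints import StayPoint
from .trajectory import ArenaConfig, Trajectory


def plot_trajectory(
    traj: Trajectory,
    stay_points: list[StayPoint] | None = None,
    outliers: OutlierResult | None = None,
    arena: ArenaConfig | None = None,
    ax=None,
):
    """Plot the walk, optionally overlaying stay points and outlier samples.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 6))
    ax.plot(traj.xy[:, 0], traj.xy[:, 1], lw=0.6, color="0.4",
            label=traj.participant_id)
    if outliers is not None:
        flagged = traj.xy[outliers.flags]
        if len(flagged):
            ax.scatter(flagged[:, 0], flagged[:, 1], s=8, color="crimson",
                       zorder=3, label="outliers")
    if stay_points:
        ax.scatter([s.centroid_x for s in stay_points],
                   [s.centroid_y for s in stay_points],
                   s=60, facecolors="none", edgecolors="tab:blue",
                   zorder=4, label="stay points")
    if arena is not None:
        ax.set_xlim(-0.1, arena.width_m + 0.1)
        ax.set_ylim(-0.1, arena.depth_m + 0.1)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.legend(loc="upper right", fontsize=7)
    return ax
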