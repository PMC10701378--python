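"""Assembly of the participant-by-feature table (basic + mined features)."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .outliers import StateSpaceConfig, detect_outliers, summarize_outliers
from .staypoints import StayPointConfig, count_stay_points
from .trajectory import FEATURE_COLUMNS, Trajectory, basic_features


def feature_row(
    traj: Trajectory,
    ss_cfg: StateSpaceConfig | None = None,
    sp_cfg: StayPointConfig | None = None,
) -> dict:
    """All features for one participant: distance, duration, speed,
    outlier count, mean outlier-run distance, stay-point count."""
    row = basic_features(traj)
    n_out, mean_run = summarize_outliers(detect_outliers(traj, ss_cfg))
    row["n_outliers"] = n_out
    row["mean_outlier_run_distance_m"] = mean_run
    row["n_stay_points"] = count_stay_points(traj, sp_cfg)
    return row


def feature_table(
    trajectories: Iterable[Trajectory],
    ss_cfg: StateSpaceConfig | None = None,
    sp_cfg: StayPointConfig | None = None,
) -> pd.DataFrame:
    """One feature row per trajectory, in input order."""
    rows = [feature_row(t, ss_cfg, sp_cfg) for t in trajectories]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
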