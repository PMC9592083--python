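"""Migration statistics of droplet-carrying cells.

Tracks arrive as 2D centroid trajectories (4-min frame interval, 2 h
movies).  Only migrating cells are analyzed: net displacement above
20 um, trajectory cropped from the onset of migration (first step larger
than 6 um, one cell radius) through the following 30 frames.  On the
cropped segment two scalars are reported: the confinement ratio (net
displacement over path length) and the mean directional change rate
(unsigned turning angle per unit time), following the trajr conventions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import InvalidParameterError

__all__ = [
    "filter_migrating",
    "confinement_ratio",
    "directional_change_rate",
    "read_trackmate_csv",
    "write_trajectory_csv",
]


def filter_migrating(
    traj: Trajectory,
    net_threshold: float = 20.0,
    start_step: float = 6.0,
    keep_frames: int = 30,
) -> Trajectory | None:
    """Select and crop a migrating-cell trajectory, or return None.

    A cell migrates when its start-to-end displacement exceeds
    ``net_threshold`` um.  The analyzed segment starts at the first step
    longer than ``start_step`` um (migration onset) and keeps the
    following ``keep_frames`` frames; a shorter remainder is kept whole
    with ``short_flag`` set.
    """
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    if net <= net_threshold:
        return None
    step_len = np.linalg.norm(traj.steps, axis=1)
    onset = np.nonzero(step_len > start_step)[0]
    if onset.size == 0:
        warnings.warn("trajectory passes the net-displacement filter but never steps "
                      f"more than {start_step} um; excluded")
        return None
    i0 = int(onset[0])
    i1 = min(i0 + keep_frames, len(traj) - 1)
    cropped = Trajectory(
        traj.times[i0 : i1 + 1] - traj.times[i0],
        traj.positions[i0 : i1 + 1].copy(),
        cell_id=traj.cell_id,
    )
    cropped.short_flag = (i1 - i0) < keep_frames
    return cropped


def confinement_ratio(traj: Trajectory) -> float:
    """Net displacement divided by total path length, in [0, 1]."""
    path = float(np.linalg.norm(traj.steps, axis=1).sum())
    if path == 0:
        raise InvalidParameterError("zero path length")
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return net / path


def directional_change_rate(traj: Trajectory) -> float:
    """Mean unsigned turning angle per second (rad/s).

    Turning angles are taken between successive nonzero steps (stalled
    frames are dropped) and divided by the per-step time interval; a
    straight path scores 0, a path reversing every frame scores
    ``pi / dt``, the maximum.
    """
    if len(traj) < 3:
        raise InvalidParameterError("need at least 3 points")
    steps = traj.steps
    lengths = np.linalg.norm(steps, axis=1)
    nonzero = lengths > 0
    if nonzero.sum() < 2:
        raise InvalidParameterError("fewer than 2 nonzero steps")
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} zero-length steps")
    v = steps[nonzero]
    ln = lengths[nonzero]
    cosang = (v[:-1] * v[1:]).sum(axis=1) / (ln[:-1] * ln[1:])
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    return float(angles.mean() / traj.dt)


def read_trackmate_csv(path, frame_interval: float | None = None) -> list[Trajectory]:
    """Read trajectories from a TrackMate-style spot export.

    Expects columns TRACK_ID, POSITION_T (s), POSITION_X, POSITION_Y (um);
    returns one Trajectory per track, sorted by time.  ``frame_interval``
    overrides the timestamps with a uniform grid when exports carry frame
    indices instead of seconds.
    """
    df = pd.read_csv(path)
    needed = {"TRACK_ID", "POSITION_T", "POSITION_X", "POSITION_Y"}
    if not needed.issubset(df.columns):
        raise InvalidParameterError(f"trajectory CSV must have columns {sorted(needed)}")
    out = []
    for tid, grp in df.groupby("TRACK_ID"):
        grp = grp.sort_values("POSITION_T")
        times = grp["POSITION_T"].to_numpy(float)
        if frame_interval is not None:
            times = np.arange(len(grp)) * frame_interval
        out.append(
            Trajectory(times, grp[["POSITION_X", "POSITION_Y"]].to_numpy(float), cell_id=str(tid))
        )
    return out


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as columns t_s, x_um, y_um."""
    pd.DataFrame(
        {"t_s": traj.times, "x_um": traj.positions[:, 0], "y_um": traj.positions[:, 1]}
    ).to_csv(path, index=False)
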