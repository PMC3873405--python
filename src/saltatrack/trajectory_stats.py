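"""Per-trajectory motion statistics.

The primary measurements are the instantaneous-velocity series

    v_n = sqrt((x_{n+1}-x_n)^2 + (y_{n+1}-y_n)^2) * pixel_size / t

(with t the frame interval in seconds and pixel_size in nm/px, so v is in
nm/s), its maximum over the trajectory, and the total displacement

    d_total = sqrt((x_last-x_first)^2 + (y_last-y_first)^2)

in pixels — the straight-line distance between the trajectory's endpoints,
distinct from its path length. Trajectories shorter than a minimum number
of frames (default 10) are discarded before any population statistics.

Two derived features support algorithmic motion classification: the
time-averaged mean-squared-displacement curve with its log-log slope alpha
(alpha < 1 confined, ~1 diffusive, ~2 ballistic) and the straightness ratio
d_total / path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcquisitionMeta, Trajectory

__all__ = [
    "TrajectoryStats",
    "filter_trajectories",
    "instantaneous_velocities",
    "max_instantaneous_velocity",
    "total_displacement",
    "path_length",
    "straightness",
    "msd_curve",
    "compute_stats",
    "stats_table",
]


@dataclass
class TrajectoryStats:
    """Measurements for one trajectory. Velocities in nm/s, displacement in
    px (nm alongside), MSD in um^2; alpha and straightness dimensionless."""

    trajectory_id: int | str
    n_frames: int
    v: np.ndarray
    v_max: float
    d_total_px: float
    d_total_nm: float
    msd: np.ndarray          # MSD at lags 1..len(msd), um^2
    alpha: float             # NaN when undefined (static trajectory)
    straightness: float
    gap_steps: np.ndarray    # mask over v: True where the step spans a closed gap


def filter_trajectories(trajs: list[Trajectory], min_frames: int = 10) -> list[Trajectory]:
    """Drop trajectories observed in fewer than ``min_frames`` frames.

    The cut is strict — a trajectory with exactly ``min_frames`` points
    survives — and input order is preserved.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    return [t for t in trajs if t.n_frames >= min_frames]


def instantaneous_velocities(traj: Trajectory, meta: AcquisitionMeta) -> np.ndarray:
    """Velocity for each consecutive pair of observed points, nm/s.

    A pair spanning a closed detection gap uses the elapsed time
    ``frame_difference * frame_interval`` as denominator (the particle was
    simply unobserved in between); :meth:`Trajectory.gap_step_mask` flags
    those entries.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 points for velocities")
    step_px = np.hypot(*np.diff(traj.xy, axis=0).T)
    dt = np.diff(traj.frames) * meta.frame_interval
    return step_px * meta.pixel_size / dt


def max_instantaneous_velocity(traj: Trajectory, meta: AcquisitionMeta,
                               include_gap_steps: bool = False) -> float:
    """Maximum of the instantaneous-velocity series, nm/s.

    Steps that span a closed gap are excluded by default: their velocity is
    an average over unobserved frames, so including them would bias the
    per-trajectory maximum downward (and never reflects a real single-frame
    burst). Set ``include_gap_steps=True`` to keep them.
    """
    v = instantaneous_velocities(traj, meta)
    if not include_gap_steps:
        keep = ~traj.gap_step_mask()
        if keep.any():
            v = v[keep]
    return float(v.max())


def total_displacement(traj: Trajectory) -> float:
    """Straight-line distance between first and last positions, in px."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 points for displacement")
    return float(np.hypot(*(traj.xy[-1] - traj.xy[0])))


def path_length(traj: Trajectory) -> float:
    """Sum of step lengths along the trajectory, in px."""
    return float(np.hypot(*np.diff(traj.xy, axis=0).T).sum())


def straightness(traj: Trajectory) -> float:
    """d_total / path length, in [0, 1]; 1 for collinear monotone motion.

    A static trajectory (zero path length) is maximally non-displacing;
    straightness is reported as 0 there.
    """
    L = path_length(traj)
    if L == 0:
        return 0.0
    return min(1.0, total_displacement(traj) / L)


def msd_curve(traj: Trajectory, meta: AcquisitionMeta,
              max_lag: int | None = None) -> tuple[np.ndarray, float]:
    """Time-averaged MSD over lags 1..max_lag (um^2) and its log-log slope.

    MSD(tau) averages the squared displacement over every pair of points
    separated by exactly ``tau`` frames. ``max_lag`` defaults to
    min(4, n/4): with short (tens of frames) trajectories only the first few
    lags are well averaged. alpha is the least-squares slope of
    log MSD vs log(tau); it is NaN (undefined sentinel) for static or
    near-degenerate trajectories where the MSD vanishes.
    """
    n = traj.n_frames
    if max_lag is None:
        max_lag = max(2, min(4, n // 4))
    if max_lag < 2 or n <= max_lag:
        raise ValueError("need trajectory length > max_lag >= 2")
    um = traj.xy * meta.pixel_size / 1000.0
    frames = traj.frames
    msd = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        # pairs at exact frame separation `lag` (robust to closed gaps)
        idx = {int(f): i for i, f in enumerate(frames)}
        d2 = [np.sum((um[idx[f + lag]] - um[i]) ** 2)
              for f, i in ((int(f), i) for i, f in enumerate(frames)) if f + lag in idx]
        if d2:
            msd[lag - 1] = float(np.mean(d2))
    lags = np.arange(1, max_lag + 1)
    valid = np.isfinite(msd) & (msd > 0)
    if valid.sum() < 2:
        return msd, float("nan")
    slope = np.polyfit(np.log(lags[valid].astype(float)), np.log(msd[valid]), 1)[0]
    return msd, float(slope)


def compute_stats(traj: Trajectory, meta: AcquisitionMeta,
                  max_lag: int | None = None,
                  include_gap_steps_in_vmax: bool = False) -> TrajectoryStats:
    """All per-trajectory measurements in one pass."""
    v = instantaneous_velocities(traj, meta)
    d_px = total_displacement(traj)
    msd, alpha = msd_curve(traj, meta, max_lag=max_lag)
    return TrajectoryStats(
        trajectory_id=traj.id,
        n_frames=traj.n_frames,
        v=v,
        v_max=max_instantaneous_velocity(traj, meta, include_gap_steps=include_gap_steps_in_vmax),
        d_total_px=d_px,
        d_total_nm=d_px * meta.pixel_size,
        msd=msd,
        alpha=alpha,
        straightness=straightness(traj),
        gap_steps=traj.gap_step_mask(),
    )


def stats_table(trajs: list[Trajectory], meta: AcquisitionMeta,
                min_frames: int = 10, **kwargs) -> pd.DataFrame:
    """Filter by minimum length, compute stats, return a tidy table."""
    rows = []
    for t in filter_trajectories(trajs, min_frames=min_frames):
        s = compute_stats(t, meta, **kwargs)
        rows.append({
            "trajectory_id": s.trajectory_id,
            "n_frames": s.n_frames,
            "v_max_nm_s": s.v_max,
            "v_mean_nm_s": float(s.v.mean()),
            "d_total_px": s.d_total_px,
            "d_total_nm": s.d_total_nm,
            "alpha": s.alpha,
            "straightness": s.straightness,
        })
    return pd.DataFrame(rows, columns=["trajectory_id", "n_frames", "v_max_nm_s",
                                       "v_mean_nm_s", "d_total_px", "d_total_nm",
                                       "alpha", "straightness"])
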