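"""Report figures: per-class trajectory galleries and the displacement dot
plot (one point per trajectory, grouped by motion class, median bar)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import MotionClass, Trajectory
from .trajectory_stats import TrajectoryStats

__all__ = ["plot_displacement_dotplot", "plot_trajectory_gallery"]

_CLASS_LABELS = {
    MotionClass.P1_RESTRICTED: "P1\nrestricted",
    MotionClass.P2_BROWNIAN: "P2\nBrownian",
    MotionClass.P3_DIRECTED: "P3\ndirected",
}
_CLASS_COLORS = {
    MotionClass.P1_RESTRICTED: "tab:blue",
    MotionClass.P2_BROWNIAN: "tab:orange",
    MotionClass.P3_DIRECTED: "tab:green",
}


def plot_displacement_dotplot(classes, stats_list: list[TrajectoryStats], path) -> None:
    """Total displacement per trajectory, jittered by class, with median bars."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for k, c in enumerate(MotionClass):
        d = np.array([s.d_total_px for cl, s in zip(classes, stats_list) if cl is c])
        if not len(d):
            continue
        x = k + rng.uniform(-0.12, 0.12, len(d))
        ax.plot(x, d, "o", ms=4, alpha=0.6, color=_CLASS_COLORS[c])
        ax.hlines(np.median(d), k - 0.25, k + 0.25, color="k", lw=2)
    ax.set_xticks(range(len(MotionClass)))
    ax.set_xticklabels([_CLASS_LABELS[c] for c in MotionClass])
    ax.set_ylabel("total displacement (px)")
    ax.set_title("Per-trajectory displacement by motion class\n(bar = median; "
                 "class boundaries are configured thresholds)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory_gallery(trajs: list[Trajectory], classes, path,
                            per_class: int = 6) -> None:
    """A few example trajectories per class, each re-centred on its start."""
    fig, axes = plt.subplots(1, len(MotionClass), figsize=(11, 3.6), sharex=True, sharey=True)
    for ax, c in zip(axes, MotionClass):
        members = [t for t, cl in zip(trajs, classes) if cl is c][:per_class]
        for t in members:
            xy = t.xy - t.xy[0]
            ax.plot(xy[:, 0], xy[:, 1], "-", lw=1, alpha=0.8)
            ax.plot(0, 0, "k.", ms=3)
        ax.set_title(_CLASS_LABELS[c].replace("\n", " "), fontsize=10)
        ax.set_aspect("equal")
        ax.set_xlabel("x (px)")
    axes[0].set_ylabel("y (px)")
    fig.suptitle("Example trajectories (re-centred on start)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
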