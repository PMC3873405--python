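"""Frame-to-frame spot linking by exact cost-minimizing assignment.

Consecutive-frame associations are solved as a rectangular assignment
problem: squared displacement (optionally plus an intensity-moment mismatch
term) between candidate pairs, with dummy rows/columns of cost
``max_disp**2`` standing in for particle disappearances and appearances.
Solving each frame pair exactly (Hungarian algorithm) makes the linker's
cost directly checkable against exhaustive enumeration. A second pass closes
detection gaps of up to ``max_gap`` frames between tracklet ends and starts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import Spot, Trajectory

__all__ = ["link_spots", "frame_pair_assignment", "import_manual_tracks",
           "trajectories_to_dataframe"]

_FORBIDDEN = 1e30


def _pair_cost_matrix(spots_a: list[Spot], spots_b: list[Spot], max_disp: float,
                      intensity_weight: float) -> np.ndarray:
    cost = np.full((len(spots_a), len(spots_b)), _FORBIDDEN)
    for i, a in enumerate(spots_a):
        for j, b in enumerate(spots_b):
            d2 = (a.x - b.x) ** 2 + (a.y - b.y) ** 2
            if d2 <= max_disp ** 2:
                c = d2
                if intensity_weight > 0:
                    c += intensity_weight * ((a.m0 - b.m0) ** 2 + (a.m2 - b.m2) ** 2)
                cost[i, j] = c
    return cost


def frame_pair_assignment(spots_a: list[Spot], spots_b: list[Spot], max_disp: float,
                          intensity_weight: float = 0.0) -> tuple[list[tuple[int, int]], float]:
    """Optimal association between two frames' spots.

    Returns (links, total_cost) where links are (index_a, index_b) pairs and
    total_cost includes a ``max_disp**2`` penalty for every unlinked spot on
    either side (the dummy "appeared/disappeared" assignment). Ties between
    equal-cost assignments are resolved deterministically by the solver's
    fixed scan order over spot indices.
    """
    na, nb = len(spots_a), len(spots_b)
    if na == 0 and nb == 0:
        return [], 0.0
    b_pen = max_disp ** 2
    cost = _pair_cost_matrix(spots_a, spots_b, max_disp, intensity_weight)
    # augmented square matrix: [[cost, end-dummies], [start-dummies, 0]]
    big = np.full((na + nb, nb + na), _FORBIDDEN)
    big[:na, :nb] = cost
    big[:na, nb:] = np.where(np.eye(na, dtype=bool), b_pen, _FORBIDDEN)
    big[na:, :nb] = np.where(np.eye(nb, dtype=bool), b_pen, _FORBIDDEN)
    big[na:, nb:] = 0.0
    rows, cols = linear_sum_assignment(big)
    links = []
    total = 0.0
    for r, c in zip(rows, cols):
        if r < na and c < nb and cost[r, c] < _FORBIDDEN:
            links.append((int(r), int(c)))
            total += cost[r, c]
        elif (r < na) != (c < nb):
            total += b_pen
    return links, float(total)


def link_spots(spots_by_frame: list[list[Spot]] | dict[int, list[Spot]],
               max_disp: float, max_gap: int = 2, intensity_weight: float = 0.0,
               gap_cost_factor: float = 0.25) -> list[Trajectory]:
    """Assemble per-frame detections into trajectories.

    Parameters
    ----------
    spots_by_frame : list or dict
        Spots per frame. A list is interpreted with list index = frame
        index; a dict maps frame index -> spots.
    max_disp : float
        Maximum frame-to-frame displacement in px. A sensible default is the
        fastest expected speed (2 um/s for motor-driven cargo) times the
        frame interval, in px.
    max_gap : int
        Maximum number of consecutive missed frames bridged by gap closing.
    gap_cost_factor : float
        Extra cost per skipped frame for a gap link, as a fraction of
        ``max_disp**2``; longer gaps cost more.

    Returns trajectories of length >= 2 (unlinked singleton spots are
    dropped), ids assigned in (first frame, position) order.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if isinstance(spots_by_frame, dict):
        frames_present = sorted(spots_by_frame)
        by_frame = {f: list(spots_by_frame[f]) for f in frames_present}
    else:
        by_frame = {f: list(s) for f, s in enumerate(spots_by_frame)}
        frames_present = sorted(by_frame)
    if not frames_present:
        return []

    fmin, fmax = frames_present[0], frames_present[-1]
    tracklets: list[list[tuple[int, Spot]]] = []
    open_by_frame: dict[int, list[int]] = {}  # frame -> tracklet indices ending there

    for f in range(fmin, fmax + 1):
        spots = by_frame.get(f, [])
        prev = open_by_frame.pop(f - 1, [])
        spots_a = [tracklets[t][-1][1] for t in prev]
        links, _ = frame_pair_assignment(spots_a, spots, max_disp, intensity_weight)
        matched_b = set()
        ends_here: list[int] = []
        for ia, ib in links:
            tracklets[prev[ia]].append((f, spots[ib]))
            ends_here.append(prev[ia])
            matched_b.add(ib)
        for ib, s in enumerate(spots):
            if ib not in matched_b:
                tracklets.append([(f, s)])
                ends_here.append(len(tracklets) - 1)
        if ends_here:
            open_by_frame[f] = ends_here

    if max_gap > 0:
        tracklets = _close_gaps(tracklets, max_disp, max_gap, gap_cost_factor)

    tracklets = [t for t in tracklets if len(t) >= 2]
    tracklets.sort(key=lambda t: (t[0][0], t[0][1].x, t[0][1].y))
    out = []
    for i, t in enumerate(tracklets):
        frames = np.array([f for f, _ in t])
        xy = np.array([[s.x, s.y] for _, s in t])
        out.append(Trajectory(id=i, frames=frames, xy=xy, source="automated"))
    return out


def _close_gaps(tracklets, max_disp, max_gap, gap_cost_factor):
    ends = [(i, t[-1][0], t[-1][1]) for i, t in enumerate(tracklets)]
    starts = [(i, t[0][0], t[0][1]) for i, t in enumerate(tracklets)]
    b_pen = max_disp ** 2
    ne, ns = len(ends), len(starts)
    cost = np.full((ne, ns), _FORBIDDEN)
    for i, (ti, fe, se) in enumerate(ends):
        for j, (tj, fs, ss) in enumerate(starts):
            skip = fs - fe - 1  # frames with no detection between the two
            if ti == tj or skip < 1 or skip > max_gap:
                continue
            d2 = (se.x - ss.x) ** 2 + (se.y - ss.y) ** 2
            if d2 <= ((skip + 1) * max_disp) ** 2:
                cost[i, j] = d2 + skip * gap_cost_factor * b_pen
    big = np.full((ne + ns, ns + ne), _FORBIDDEN)
    big[:ne, :ns] = cost
    big[:ne, ns:] = np.where(np.eye(ne, dtype=bool), b_pen, _FORBIDDEN)
    big[ne:, :ns] = np.where(np.eye(ns, dtype=bool), b_pen, _FORBIDDEN)
    big[ne:, ns:] = 0.0
    rows, cols = linear_sum_assignment(big)
    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    for r, c in zip(rows, cols):
        if r < ne and c < ns and cost[r, c] < _FORBIDDEN:
            successor[ends[r][0]] = starts[c][0]
            has_pred.add(starts[c][0])
    merged = []
    for i, t in enumerate(tracklets):
        if i in has_pred:
            continue
        chain = list(t)
        j = i
        while j in successor:
            j = successor[j]
            chain.extend(tracklets[j])
        merged.append(chain)
    return merged


# ----------------------------------------------------------------------
# manual-track import / export
# ----------------------------------------------------------------------

def import_manual_tracks(table: pd.DataFrame) -> list[Trajectory]:
    """Build trajectories from a manually-tracked table.

    The table needs columns (trajectory_id, frame, x, y); within each id the
    frames must appear in strictly increasing order — duplicated or
    out-of-order frames are rejected with the offending row numbers, since
    they indicate a transcription error rather than something to silently
    repair. Output trajectories carry ``source="manual"``.
    """
    required = {"trajectory_id", "frame", "x", "y"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manual track table missing columns: {sorted(missing)}")
    bad_rows: list[int] = []
    trajs: list[Trajectory] = []
    for tid, grp in table.groupby("trajectory_id", sort=True):
        frames = grp["frame"].to_numpy()
        nonmono = np.where(np.diff(frames) <= 0)[0]
        if len(nonmono):
            bad_rows.extend(int(grp.index[k + 1]) for k in nonmono)
            continue
        if len(grp) < 2:
            raise ValueError(f"trajectory {tid!r} has fewer than 2 points")
        trajs.append(Trajectory(id=tid, frames=frames,
                                xy=grp[["x", "y"]].to_numpy(dtype=float),
                                source="manual"))
    if bad_rows:
        raise ValueError(f"non-monotone frames in manual tracks at rows {sorted(bad_rows)}")
    return trajs


def trajectories_to_dataframe(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format export: one row per (trajectory_id, frame) observation."""
    rows = [(t.id, int(f), float(x), float(y), t.source)
            for t in trajs for f, (x, y) in zip(t.frames, t.xy)]
    return pd.DataFrame(rows, columns=["trajectory_id", "frame", "x", "y", "source"])
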