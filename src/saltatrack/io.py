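"""Readers and writers for the pipeline's on-disk formats.

Image stacks are multi-page TIFF (frame-major, one channel per file);
spots, trajectories and per-trajectory statistics are plain CSV; acquisition
metadata and configuration are YAML; summaries are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AcquisitionMeta, MotionClass, Spot, Trajectory
from .synthetic_data import FilamentMap, GroundTruth, MotionModel, MotionModelParams

__all__ = [
    "write_stack", "read_stack", "write_image", "read_image",
    "write_spots", "read_spots", "write_trajectories", "read_trajectories",
    "write_meta", "read_meta", "write_filaments", "read_filaments",
    "write_ground_truth", "read_ground_truth", "write_json",
]


# -- images ------------------------------------------------------------

def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


write_image = write_stack


def read_image(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[0]
    return arr.astype(float)


# -- spots -------------------------------------------------------------

def write_spots(path, spots_by_frame: list[list[Spot]]) -> None:
    rows = [(s.frame, s.x, s.y, s.m0, s.m2, s.snr, s.on_border)
            for frame in spots_by_frame for s in frame]
    pd.DataFrame(rows, columns=["frame", "x", "y", "m0", "m2", "snr", "on_border"]
                 ).to_csv(path, index=False)


def read_spots(path) -> list[list[Spot]]:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Spot]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(Spot(frame=int(row.frame), x=row.x, y=row.y,
                                        m0=row.m0, m2=row.m2, snr=row.snr,
                                        on_border=bool(row.on_border)))
    return out


# -- trajectories ------------------------------------------------------

def write_trajectories(path, trajs: list[Trajectory]) -> None:
    from .linking import trajectories_to_dataframe
    trajectories_to_dataframe(trajs).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    trajs = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        source = grp["source"].iloc[0] if "source" in grp else "automated"
        trajs.append(Trajectory(id=tid, frames=grp["frame"].to_numpy(),
                                xy=grp[["x", "y"]].to_numpy(dtype=float),
                                source=str(source)))
    return trajs


# -- metadata ----------------------------------------------------------

def write_meta(path, meta: AcquisitionMeta) -> None:
    d = asdict(meta)
    d["image_shape"] = list(meta.image_shape)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_meta(path) -> AcquisitionMeta:
    d = yaml.safe_load(Path(path).read_text())
    d["image_shape"] = tuple(d["image_shape"])
    return AcquisitionMeta(**d)


# -- filaments ---------------------------------------------------------

def write_filaments(path, filaments: FilamentMap) -> None:
    rows = [(i, k, float(x), float(y))
            for i, poly in enumerate(filaments.polylines)
            for k, (x, y) in enumerate(poly)]
    pd.DataFrame(rows, columns=["filament_id", "vertex", "x", "y"]).to_csv(path, index=False)


def read_filaments(path) -> FilamentMap:
    df = pd.read_csv(path)
    polys = [grp.sort_values("vertex")[["x", "y"]].to_numpy(dtype=float)
             for _, grp in df.groupby("filament_id", sort=True)]
    return FilamentMap(polys)


# -- ground truth ------------------------------------------------------

def write_ground_truth(csv_path, truth: GroundTruth, params_json_path=None) -> None:
    """Trajectory points + labels as CSV, per-trajectory model parameters as
    a JSON sidecar (same stem, ``.params.json``, unless given)."""
    rows = []
    for traj, label in zip(truth.trajectories, truth.labels):
        for f, (x, y) in zip(traj.frames, traj.xy):
            rows.append((traj.id, int(f), float(x), float(y), label.value))
    pd.DataFrame(rows, columns=["trajectory_id", "frame", "x_px", "y_px", "label"]
                 ).to_csv(csv_path, index=False)
    if params_json_path is None:
        params_json_path = Path(csv_path).with_suffix(".params.json")
    sidecar = {
        "seed": truth.seed,
        "params": [_params_to_dict(p) for p in truth.params],
    }
    Path(params_json_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_ground_truth(csv_path, params_json_path=None) -> GroundTruth:
    df = pd.read_csv(csv_path)
    if params_json_path is None:
        params_json_path = Path(csv_path).with_suffix(".params.json")
    sidecar = json.loads(Path(params_json_path).read_text())
    trajs, labels = [], []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        trajs.append(Trajectory(id=tid, frames=grp["frame"].to_numpy(),
                                xy=grp[["x_px", "y_px"]].to_numpy(dtype=float),
                                source="ground_truth"))
        labels.append(MotionClass(grp["label"].iloc[0]))
    params = [_params_from_dict(d) for d in sidecar["params"]]
    return GroundTruth(trajectories=trajs, labels=labels, params=params,
                       seed=int(sidecar["seed"]))


def _params_to_dict(p: MotionModelParams) -> dict:
    d = asdict(p)
    d["model"] = p.model.value
    return d


def _params_from_dict(d: dict) -> MotionModelParams:
    d = dict(d)
    d["model"] = MotionModel(d["model"])
    return MotionModelParams(**d)


# -- json --------------------------------------------------------------

def write_json(path, obj: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
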