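"""End-to-end orchestration: simulate (or ingest) → detect → track →
analyze → classify → colocalize, with every intermediate written to disk
and a deterministic JSON summary at the end.

Identical configuration + seed produce byte-identical summaries; wall-clock
timings and library versions go to the log only, never into the summary.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import numpy as np

from . import io
from .classification import classify_all, summarize_populations
from .colocalization import colocalization_fraction
from .config import PipelineConfig
from .core import MotionClass
from .detection import detect_stack
from .linking import link_spots
from .synthetic_data import make_benchmark_dataset
from .trajectory_stats import compute_stats, filter_trajectories, stats_table

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: Path, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed (artifact: {artifact}): {cause}")
        self.stage = stage
        self.artifact = artifact


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("saltatrack")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))


def run_pipeline(config: PipelineConfig, movie_path=None, make_plots: bool = True) -> dict:
    """Run the full pipeline under one configuration.

    With ``movie_path`` set, that TIFF stack is ingested instead of
    simulating (ground-truth-dependent outputs are then skipped).
    Returns the summary dict; all artifacts land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    meta = config.meta
    config.to_yaml(out / "config.yaml")
    io.write_meta(out / "meta.yaml", meta)
    summary: dict = {"seed": config.seed}
    t0 = time.perf_counter()

    truth = None
    if movie_path is None:
        stage = "simulate"
        try:
            sim = config.simulation
            stack, truth = make_benchmark_dataset(
                mixture=sim.mixture, n_trajectories=sim.n_trajectories, meta=meta,
                seed=config.seed, min_separation=sim.min_separation_px,
                n_filaments=sim.n_filaments, psf_sigma=sim.psf_sigma_px,
                photon_scale=sim.photon_scale, background=sim.background,
                read_noise_sd=sim.read_noise_sd)
            io.write_stack(out / "movie.tif", stack)
            io.write_ground_truth(out / "ground_truth.csv", truth)
            io.write_filaments(out / "filaments.csv", truth.filaments)
            logger.info("simulate: %d trajectories, %d filaments (%.1fs)",
                        len(truth.trajectories), len(truth.filaments),
                        time.perf_counter() - t0)
        except Exception as e:
            raise StageError(stage, out / "movie.tif", e) from e
    else:
        stack = io.read_stack(movie_path)

    stage = "detect"
    try:
        spots = detect_stack(stack, radius=config.detection.radius_px,
                             percentile=config.detection.percentile, meta=meta,
                             smoothing=config.detection.smoothing)
        io.write_spots(out / "spots.csv", spots)
        summary["n_spots"] = int(sum(len(s) for s in spots))
        logger.info("detect: %d spots", summary["n_spots"])
    except Exception as e:
        raise StageError(stage, out / "spots.csv", e) from e

    stage = "track"
    try:
        max_disp = config.linking.resolve_max_disp(meta)
        trajs = link_spots(spots, max_disp=max_disp, max_gap=config.linking.max_gap,
                           intensity_weight=config.linking.intensity_weight)
        io.write_trajectories(out / "tracks.csv", trajs)
        summary["n_trajectories"] = len(trajs)
        logger.info("track: %d trajectories (max_disp=%.1f px)", len(trajs), max_disp)
    except Exception as e:
        raise StageError(stage, out / "tracks.csv", e) from e

    stage = "analyze"
    try:
        kept = filter_trajectories(trajs, min_frames=config.analysis.min_frames)
        table = stats_table(trajs, meta, min_frames=config.analysis.min_frames)
        table.to_csv(out / "stats.csv", index=False)
        stats_list = [compute_stats(t, meta) for t in kept]
        summary["n_trajectories_after_filter"] = len(kept)
    except Exception as e:
        raise StageError(stage, out / "stats.csv", e) from e

    stage = "classify"
    try:
        classes = classify_all(stats_list, config.thresholds)
        pop = summarize_populations(classes, stats_list)
        io.write_json(out / "populations.json", pop.to_dict())
        cls_rows = [{"trajectory_id": t.id, "motion_class": c.value}
                    for t, c in zip(kept, classes)]
        import pandas as pd
        pd.DataFrame(cls_rows, columns=["trajectory_id", "motion_class"]
                     ).to_csv(out / "classes.csv", index=False)
        summary["populations"] = pop.to_dict()
    except Exception as e:
        raise StageError(stage, out / "populations.json", e) from e

    stage = "coloc"
    try:
        if truth is not None and truth.filaments is not None and len(kept):
            coloc = colocalization_fraction(kept, truth.filaments, meta,
                                            threshold_nm=config.analysis.coloc_threshold_nm,
                                            classes=classes)
            coloc.per_trajectory.to_csv(out / "coloc.csv", index=False)
            summary["colocalization"] = coloc.to_dict()
    except Exception as e:
        raise StageError(stage, out / "coloc.csv", e) from e

    if make_plots:
        stage = "plots"
        try:
            from .plots import plot_displacement_dotplot, plot_trajectory_gallery
            if stats_list:
                plot_displacement_dotplot(classes, stats_list, out / "displacement_dotplot.png")
                plot_trajectory_gallery(kept, classes, out / "trajectory_gallery.png")
        except Exception as e:
            raise StageError(stage, out / "displacement_dotplot.png", e) from e

    io.write_json(out / "summary.json", summary)
    logger.info("pipeline done in %.1fs -> %s", time.perf_counter() - t0, out)
    return summary
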