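"""Pipeline configuration.

One YAML document drives the whole pipeline; every stage reads its
parameters from here and all randomness flows from the single ``seed``.
Numeric defaults fall into two groups: physical/observed values (frame
interval, speed calibration, population mixture) and declared analysis
choices (detection radius and percentile, link range, thresholds) — the
field comments below mark which is which.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classification import ClassifierThresholds
from .colocalization import DEFAULT_THRESHOLD_NM
from .core import AcquisitionMeta

__all__ = ["SimulationConfig", "DetectionConfig", "LinkingConfig",
           "AnalysisConfig", "PipelineConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark-movie generation. The mixture mirrors the observed
    population frequencies (15% restricted / 41% Brownian / 44% directed);
    imaging values emulate the source regime (5 s frames for 2 min)."""

    # 20 particles per 512x512 field matches analysing a cell subsection;
    # much denser fields make frame-to-frame association ambiguous during
    # fast transport bursts (see docs)
    n_trajectories: int = 20
    mixture: tuple[float, float, float] = (0.15, 0.41, 0.44)
    n_filaments: int | None = None
    min_separation_px: float = 12.0
    psf_sigma_px: float = 1.3       # declared: diffraction-limited-like spot width
    photon_scale: float = 150.0     # declared: peak photons per spot
    background: float = 20.0        # declared: background photons per px
    read_noise_sd: float = 2.0      # declared: camera read noise (counts)


@dataclass(frozen=True)
class DetectionConfig:
    radius_px: int = 3              # declared: spot neighbourhood radius
    percentile: float = 0.005       # declared: top-intensity retention fraction
    smoothing: str = "gaussian"


@dataclass(frozen=True)
class LinkingConfig:
    """``max_disp_px`` of None derives the link range from the fastest
    expected speed, 2 um/s (motor-driven burst ceiling), times the frame
    interval."""

    max_disp_px: float | None = None
    max_gap: int = 2                # declared: frames bridged by gap closing
    intensity_weight: float = 0.0   # declared: pure-displacement cost by default

    def resolve_max_disp(self, meta: AcquisitionMeta) -> float:
        if self.max_disp_px is not None:
            return self.max_disp_px
        return 2000.0 * meta.frame_interval / meta.pixel_size * 1.15  # 15% headroom


@dataclass(frozen=True)
class AnalysisConfig:
    min_frames: int = 10            # observed protocol: trajectories < 10 frames dropped
    coloc_threshold_nm: float = DEFAULT_THRESHOLD_NM


@dataclass(frozen=True)
class PipelineConfig:
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    seed: int = 0
    out_dir: str = "saltatrack_out"

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["meta"]["image_shape"] = list(self.meta.image_shape)
        d["simulation"]["mixture"] = list(self.simulation.mixture)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        meta = d.get("meta", {})
        if "image_shape" in meta:
            meta = dict(meta, image_shape=tuple(meta["image_shape"]))
        sim = d.get("simulation", {})
        if "mixture" in sim:
            sim = dict(sim, mixture=tuple(sim["mixture"]))
        return cls(
            meta=AcquisitionMeta(**meta),
            simulation=SimulationConfig(**sim),
            detection=DetectionConfig(**d.get("detection", {})),
            linking=LinkingConfig(**d.get("linking", {})),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            thresholds=ClassifierThresholds(**d.get("thresholds", {})),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "saltatrack_out")),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def demo(cls, out_dir: str = "saltatrack_demo", seed: int = 7) -> "PipelineConfig":
        """The default end-to-end configuration with a fixed seed and output
        directory: a 2-minute, 5-s-interval movie of 20 particles."""
        return cls(seed=seed, out_dir=out_dir)
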