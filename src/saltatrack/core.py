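"""Core data containers shared by every pipeline stage.

Coordinate convention: image coordinates in pixels, pixel-center origin at
the top-left pixel, x increasing rightward (columns), y increasing downward
(rows). Physical conversions go through :class:`AcquisitionMeta`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionMeta", "MotionClass", "Spot", "Trajectory"]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata tying pixel-space trajectories to physical units.

    Parameters
    ----------
    frame_interval : float
        Seconds between successive frames. The default (5 s) matches a
        2-minute time-lapse recorded every 5 seconds.
    pixel_size : float
        Nanometres per pixel. 107 nm/px is typical for a 60X objective on a
        CCD with ~6.5 um pixel pitch; it is a declared default, carried
        everywhere and always configurable.
    n_frames : int
        Number of frames in the movie.
    image_shape : (int, int)
        Field of view as (height, width) in pixels.
    """

    frame_interval: float = 5.0
    pixel_size: float = 107.0
    n_frames: int = 24
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise ValueError("image dimensions must be >= 16 px")

    # -- unit helpers -------------------------------------------------
    def px_to_nm(self, px: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(px) * self.pixel_size if isinstance(px, np.ndarray) else px * self.pixel_size

    def px_to_um(self, px: float | np.ndarray):
        return self.px_to_nm(px) / 1000.0

    def nm_to_px(self, nm: float | np.ndarray):
        return nm / self.pixel_size

    @property
    def duration(self) -> float:
        """Total elapsed time from first to last frame, in seconds."""
        return (self.n_frames - 1) * self.frame_interval

    @classmethod
    def filament_channel(cls, image_shape: tuple[int, int] = (512, 512)) -> "AcquisitionMeta":
        """Preset for the faster tubulin-channel regime (1 s for 1 min)."""
        return cls(frame_interval=1.0, pixel_size=107.0, n_frames=60, image_shape=image_shape)


class MotionClass(enum.Enum):
    """The three particle populations observed in live-cell capsid movies.

    P1_RESTRICTED
        Little to no displacement; particle effectively anchored.
    P2_BROWNIAN
        Erratic diffusive wandering with small net displacement.
    P3_DIRECTED
        Long-range saltatory transport: directed runs along curvilinear
        tracks interleaved with pauses and reversals.
    """

    P1_RESTRICTED = "P1_RESTRICTED"
    P2_BROWNIAN = "P2_BROWNIAN"
    P3_DIRECTED = "P3_DIRECTED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Spot:
    """A sub-pixel 2D detection in a single frame.

    ``m0`` is the total (background-subtracted) intensity in the detection
    window and ``m2`` the radius-weighted second intensity moment, i.e. a
    measure of spot spread.
    """

    frame: int
    x: float
    y: float
    m0: float
    m2: float
    snr: float = float("nan")
    on_border: bool = False

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Trajectory:
    """An ordered, frame-indexed sequence of positions for one particle.

    Attributes
    ----------
    id : int | str
        Identifier unique within a dataset.
    frames : (N,) int array
        Strictly increasing frame indices. A jump of more than one frame
        marks a closed detection gap (blinking / missed detection).
    xy : (N, 2) float array
        Positions in pixels, columns (x, y).
    source : str
        One of ``automated``, ``manual``, ``ground_truth``.
    """

    id: int | str
    frames: np.ndarray
    xy: np.ndarray
    source: str = "automated"

    VALID_SOURCES = ("automated", "manual", "ground_truth")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("frames must be (N,), xy must be (N, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy length mismatch")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"trajectory {self.id}: frames must be strictly increasing")
        if self.source not in self.VALID_SOURCES:
            raise ValueError(f"unknown trajectory source {self.source!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        """Number of observed points (what the minimum-length filter counts)."""
        return len(self.frames)

    @property
    def points(self) -> list[tuple[int, float, float]]:
        """(frame, x, y) tuples, convenient for export and inspection."""
        return [(int(f), float(x), float(y)) for f, (x, y) in zip(self.frames, self.xy)]

    def gap_step_mask(self) -> np.ndarray:
        """Boolean mask over the N-1 steps; True where a step spans a closed gap."""
        return np.diff(self.frames) > 1
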