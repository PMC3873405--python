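"""Synthetic time-lapse generator for capsid-transport imaging.

Ground-truth trajectories are simulated under three motion regimes —
tethered/confined, free Brownian, and directed-saltatory transport along
curvilinear filament tracks — and rendered into noisy diffraction-limited
movies so the whole detection → linking → statistics → classification
pipeline can be exercised against a known answer.

Motion-model mechanics (the observations being emulated are phenomenological,
so the simplest generative models reproducing them are used):

* CONFINED: an Ornstein–Uhlenbeck tether about the start point, hard-truncated
  at ``confinement_radius``. Stationary per-axis spread defaults to one third
  of the radius.
* BROWNIAN: 2D isotropic diffusion; per-frame displacements are i.i.d.
  Gaussian with total variance ``4 * D * frame_interval``.
* DIRECTED: a two-state run/pause Markov chain moving along a filament
  polyline at a per-trajectory run speed, with a Bernoulli direction reversal
  at each resume and reflection at the filament ends. This reproduces
  intermittent (saltatory), bidirectional long-range transport whose
  instantaneous velocity oscillates between near-zero and burst values.

All randomness flows from one root seed; per-trajectory child seeds are
derived by counter (``numpy.random.SeedSequence.spawn``) so datasets are
stable under trajectory reordering.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import AcquisitionMeta, MotionClass, Trajectory

__all__ = [
    "MotionModel",
    "MotionModelParams",
    "FilamentMap",
    "GroundTruth",
    "simulate_trajectory",
    "generate_filament_map",
    "render_movie",
    "render_filament_image",
    "make_benchmark_dataset",
    "apportion_counts",
]

logger = logging.getLogger(__name__)

_SUBSTEPS_PER_FRAME = 20  # Euler/Markov substeps per frame interval


class MotionModel(enum.Enum):
    CONFINED = "confined"
    BROWNIAN = "brownian"
    DIRECTED = "directed"


_MODEL_TO_CLASS = {
    MotionModel.CONFINED: MotionClass.P1_RESTRICTED,
    MotionModel.BROWNIAN: MotionClass.P2_BROWNIAN,
    MotionModel.DIRECTED: MotionClass.P3_DIRECTED,
}


@dataclass(frozen=True)
class MotionModelParams:
    """Parameters for one motion regime.

    Only the fields relevant to ``model`` are used. Units:

    * ``diffusion_coeff`` — um^2/s (BROWNIAN free diffusion, or the local
      diffusivity of the CONFINED tether; ``None`` derives the tether value
      from ``tether_stiffness`` and ``confinement_radius``).
    * ``confinement_radius`` — nm; hard bound on distance from the anchor.
    * ``tether_stiffness`` — 1/s; OU relaxation rate of the tether.
    * ``run_speed_mean`` / ``run_speed_sd`` — nm/s; between-trajectory mean
      and spread of the (constant within a trajectory) run speed.
    * ``pause_rate`` / ``resume_rate`` — 1/s; run→pause and pause→run rates.
    * ``reversal_prob`` — probability of a direction flip at each resume.
    * ``track_id`` — index of the filament polyline a DIRECTED particle rides.
    """

    model: MotionModel
    diffusion_coeff: float | None = None
    confinement_radius: float = 300.0
    tether_stiffness: float = 0.5
    run_speed_mean: float = 700.0
    run_speed_sd: float = 300.0
    run_speed_max: float = 2000.0
    pause_rate: float = 0.2
    resume_rate: float = 0.05
    reversal_prob: float = 0.5
    track_id: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.model, MotionModel):
            raise ValueError(f"unknown motion model {self.model!r}; expected a MotionModel")
        for name in ("confinement_radius", "tether_stiffness", "run_speed_mean",
                     "run_speed_sd", "pause_rate", "resume_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.diffusion_coeff is not None and self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be non-negative")
        if not 0.0 <= self.reversal_prob <= 1.0:
            raise ValueError("reversal_prob must be in [0, 1]")
        if self.model is MotionModel.DIRECTED and self.track_id is None:
            raise ValueError("DIRECTED motion requires a track_id referencing a filament")

    # -- calibrated defaults per regime -------------------------------
    @classmethod
    def confined(cls, confinement_radius: float = 300.0, tether_stiffness: float = 0.5,
                 diffusion_coeff: float | None = None) -> "MotionModelParams":
        """Anchored particle. Defaults give ~1.5 px median net displacement
        over a 24-frame movie at 107 nm/px (the restricted population)."""
        return cls(model=MotionModel.CONFINED, confinement_radius=confinement_radius,
                   tether_stiffness=tether_stiffness, diffusion_coeff=diffusion_coeff)

    @classmethod
    def brownian(cls, diffusion_coeff: float = 0.0017) -> "MotionModelParams":
        """Free cytoplasmic diffusion. D = 0.0017 um^2/s makes the median
        2-minute net displacement ~7 px at 107 nm/px — slow diffusion, as
        expected for a several-hundred-nm capsid in crowded cytoplasm."""
        return cls(model=MotionModel.BROWNIAN, diffusion_coeff=diffusion_coeff)

    @classmethod
    def directed(cls, track_id: int, run_speed_mean: float = 700.0,
                 run_speed_sd: float = 300.0, pause_rate: float = 0.2,
                 resume_rate: float = 0.05, reversal_prob: float = 0.5) -> "MotionModelParams":
        """Saltatory transport along a filament. Defaults: ~5 s runs separated
        by ~20 s pauses, an even chance of reversing direction at each resume
        (strongly bidirectional), and a per-trajectory speed centred on
        700 nm/s (spread 300 nm/s, capped at 2 um/s) so the population's
        median maximum instantaneous velocity lands near 700 nm/s with
        bursts toward 2 um/s."""
        return cls(model=MotionModel.DIRECTED, track_id=track_id,
                   run_speed_mean=run_speed_mean, run_speed_sd=run_speed_sd,
                   pause_rate=pause_rate, resume_rate=resume_rate,
                   reversal_prob=reversal_prob)

    @property
    def motion_class(self) -> MotionClass:
        return _MODEL_TO_CLASS[self.model]


class FilamentMap:
    """A set of filament (microtubule-like) polylines in pixel coordinates.

    Each polyline is an (M, 2) float array of (x, y) vertices, M >= 2, with
    consecutive vertices distinct. Polyline ids are list indices.
    """

    def __init__(self, polylines: list[np.ndarray]):
        self.polylines = [np.asarray(p, dtype=float) for p in polylines]
        for i, p in enumerate(self.polylines):
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
                raise ValueError(f"polyline {i} must be (M>=2, 2)")
            if np.any(np.all(np.diff(p, axis=0) == 0, axis=1)):
                raise ValueError(f"polyline {i} has repeated consecutive vertices")

    def __len__(self) -> int:
        return len(self.polylines)

    def __getitem__(self, track_id: int) -> np.ndarray:
        return self.polylines[track_id]

    def translated(self, dx: float, dy: float) -> "FilamentMap":
        return FilamentMap([p + np.array([dx, dy]) for p in self.polylines])


@dataclass
class GroundTruth:
    """Labelled simulation output: trajectories, classes and parameters
    aligned one-to-one, plus the filament map directed particles rode."""

    trajectories: list[Trajectory]
    labels: list[MotionClass]
    params: list[MotionModelParams]
    seed: int
    filaments: FilamentMap | None = None

    def __post_init__(self) -> None:
        if not (len(self.trajectories) == len(self.labels) == len(self.params)):
            raise ValueError("trajectories, labels and params must align one-to-one")


# ----------------------------------------------------------------------
# polyline geometry helpers
# ----------------------------------------------------------------------

def _polyline_cumlen(poly: np.ndarray) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _point_at_arclength(poly: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = float(np.clip(s, 0.0, cum[-1]))
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.array([x, y])


def project_point_to_polyline(poly: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Arc-length coordinate and distance of the closest point on ``poly`` to ``p``."""
    cum = _polyline_cumlen(poly)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(ab2 > 0, ab2, 1.0), 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.hypot(*(p - foot).T)
    k = int(np.argmin(d))
    s = cum[k] + t[k] * np.sqrt(ab2[k])
    return float(s), float(d[k])


# ----------------------------------------------------------------------
# trajectory simulation
# ----------------------------------------------------------------------

def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(params: MotionModelParams, meta: AcquisitionMeta,
                        start: np.ndarray, seed,
                        filaments: FilamentMap | None = None) -> Trajectory:
    """Simulate one ground-truth trajectory, one position per frame.

    ``start`` is an (x, y) position in pixels and must lie inside the field
    of view. DIRECTED motion requires ``filaments``; the start is projected
    onto the referenced polyline and the particle stays on it thereafter.
    """
    start = np.asarray(start, dtype=float)
    h, w = meta.image_shape
    if not (0 <= start[0] < w and 0 <= start[1] < h):
        raise ValueError(f"start {start} outside image bounds {meta.image_shape}")
    rng = _rng_from(seed)

    if params.model is MotionModel.BROWNIAN:
        xy = _simulate_brownian(params, meta, start, rng)
    elif params.model is MotionModel.CONFINED:
        xy = _simulate_confined(params, meta, start, rng)
    elif params.model is MotionModel.DIRECTED:
        if filaments is None:
            raise ValueError("DIRECTED simulation needs a FilamentMap")
        xy = _simulate_directed(params, meta, start, rng, filaments)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown motion model {params.model!r}")

    frames = np.arange(meta.n_frames)
    return Trajectory(id=-1, frames=frames, xy=xy, source="ground_truth")


def _simulate_brownian(params, meta, start, rng):
    D = params.diffusion_coeff if params.diffusion_coeff is not None else 0.0017
    # per-axis step sd in px: sqrt(2 D t), D in um^2/s -> nm -> px
    sd_px = np.sqrt(2.0 * D * meta.frame_interval) * 1000.0 / meta.pixel_size
    steps = rng.normal(0.0, sd_px, size=(meta.n_frames - 1, 2))
    return start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def _simulate_confined(params, meta, start, rng):
    k = params.tether_stiffness
    radius_px = params.confinement_radius / meta.pixel_size
    if params.diffusion_coeff is not None:
        D_px2 = params.diffusion_coeff * 1e6 / meta.pixel_size ** 2  # um^2/s -> px^2/s
    else:
        # stationary per-axis sd = radius / 3  =>  D = k * (radius/3)^2
        D_px2 = k * (radius_px / 3.0) ** 2
    dt = meta.frame_interval / _SUBSTEPS_PER_FRAME
    pos = start.copy()
    out = np.empty((meta.n_frames, 2))
    out[0] = pos
    noise_sd = np.sqrt(2.0 * D_px2 * dt)
    for i in range(1, meta.n_frames):
        for _ in range(_SUBSTEPS_PER_FRAME):
            pos = pos - k * (pos - start) * dt + rng.normal(0.0, noise_sd, 2)
            r = np.hypot(*(pos - start))
            if r > radius_px:  # hard wall at the confinement radius
                pos = start + (pos - start) * (radius_px / r)
        out[i] = pos
    return out


def _simulate_directed(params, meta, start, rng, filaments):
    poly = filaments[params.track_id]
    cum = _polyline_cumlen(poly)
    L = cum[-1]
    s, _ = project_point_to_polyline(poly, start)

    speed_nm = params.run_speed_mean + params.run_speed_sd * rng.standard_normal()
    speed_nm = float(np.clip(speed_nm, 0.0, params.run_speed_max))
    speed_px = speed_nm / meta.pixel_size

    direction = 1.0 if rng.random() < 0.5 else -1.0
    running = True  # start mid-run so pause-free simulations move from frame 0
    dt = meta.frame_interval / _SUBSTEPS_PER_FRAME
    p_pause = 1.0 - np.exp(-params.pause_rate * dt)
    p_resume = 1.0 - np.exp(-params.resume_rate * dt)

    out = np.empty((meta.n_frames, 2))
    out[0] = _point_at_arclength(poly, cum, s)
    for i in range(1, meta.n_frames):
        for _ in range(_SUBSTEPS_PER_FRAME):
            if running:
                if rng.random() < p_pause:
                    running = False
                else:
                    s += direction * speed_px * dt
                    if s < 0.0:
                        s, direction = -s, -direction
                    elif s > L:
                        s, direction = 2.0 * L - s, -direction
            else:
                if rng.random() < p_resume:
                    running = True
                    if rng.random() < params.reversal_prob:
                        direction = -direction
        out[i] = _point_at_arclength(poly, cum, s)
    return out


# ----------------------------------------------------------------------
# filament map generation
# ----------------------------------------------------------------------

def generate_filament_map(meta: AcquisitionMeta, n_filaments: int, seed,
                          step_px: float = 6.0, curvature_sd: float = 0.05) -> FilamentMap:
    """Smooth random polylines spanning the field of view.

    Each filament starts on a random image edge, heads inward, and performs a
    gently curving walk (heading perturbed by ``curvature_sd`` radians per
    ``step_px`` advance) until it leaves the field. Curvature is kept low so
    arc length and chord length agree to well under a percent per frame-step
    at the default transport speeds.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = _rng_from(seed)
    h, w = meta.image_shape
    polylines = []
    for _ in range(n_filaments):
        edge = rng.integers(4)
        if edge == 0:    # left
            pos = np.array([1.0, rng.uniform(0.1 * h, 0.9 * h)]); heading = rng.uniform(-0.6, 0.6)
        elif edge == 1:  # right
            pos = np.array([w - 2.0, rng.uniform(0.1 * h, 0.9 * h)]); heading = np.pi + rng.uniform(-0.6, 0.6)
        elif edge == 2:  # top
            pos = np.array([rng.uniform(0.1 * w, 0.9 * w), 1.0]); heading = np.pi / 2 + rng.uniform(-0.6, 0.6)
        else:            # bottom
            pos = np.array([rng.uniform(0.1 * w, 0.9 * w), h - 2.0]); heading = -np.pi / 2 + rng.uniform(-0.6, 0.6)
        pts = [pos.copy()]
        for _ in range(int(3 * (h + w) / step_px)):
            heading += rng.normal(0.0, curvature_sd)
            pos = pos + step_px * np.array([np.cos(heading), np.sin(heading)])
            if not (0 <= pos[0] < w and 0 <= pos[1] < h):
                break
            pts.append(pos.copy())
        if len(pts) < 2:  # degenerate start; fall back to a short straight stub
            pts.append(pts[0] + step_px * np.array([np.cos(heading), np.sin(heading)]))
            pts[-1] = np.clip(pts[-1], [0, 0], [w - 1, h - 1])
        polylines.append(np.array(pts))
    return FilamentMap(polylines)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def render_movie(truth: GroundTruth, meta: AcquisitionMeta, psf_sigma: float = 1.3,
                 photon_scale: float = 150.0, background: float = 20.0,
                 read_noise_sd: float = 2.0, seed=0, noise: bool = True) -> np.ndarray:
    """Render ground-truth trajectories into a noisy image stack.

    Each frame is ``background`` plus a 2D Gaussian of peak amplitude
    ``photon_scale`` (in photon counts) and width ``psf_sigma`` at every
    trajectory position present in that frame, then Poisson shot noise and
    additive Gaussian read noise are applied (unless ``noise=False``).
    Returns a float32 stack of shape (n_frames, H, W), values >= 0.
    """
    if psf_sigma <= 0 or photon_scale <= 0:
        raise ValueError("psf_sigma and photon_scale must be > 0")
    h, w = meta.image_shape
    stack = np.full((meta.n_frames, h, w), float(background))
    half = max(3, int(np.ceil(4 * psf_sigma)))
    clipped = False
    for traj in truth.trajectories:
        for f, (x, y) in zip(traj.frames, traj.xy):
            if f < 0 or f >= meta.n_frames:
                continue
            if not (0 <= x < w and 0 <= y < h):
                clipped = True
            _add_gaussian(stack[f], x, y, photon_scale, psf_sigma, half)
    if clipped:
        logger.warning("some trajectory positions fell outside the field of view; spots clipped")
    if noise:
        rng = _rng_from(seed)
        stack = rng.poisson(stack).astype(float)
        if read_noise_sd > 0:
            stack = stack + rng.normal(0.0, read_noise_sd, stack.shape)
        stack = np.clip(stack, 0.0, None)
    return stack.astype(np.float32)


def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float, sigma: float, half: int) -> None:
    h, w = img.shape
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    img[y0:y1, x0:x1] += amp * g


def render_filament_image(filaments: FilamentMap, meta: AcquisitionMeta,
                          line_sigma: float = 1.0, amplitude: float = 120.0,
                          background: float = 20.0, seed=0, noise: bool = True) -> np.ndarray:
    """Render the filament map as a single fluorescence image (tubulin channel).

    Polylines are resampled densely, blurred to ``line_sigma`` and scaled to
    ``amplitude`` counts above ``background``; Poisson noise optional.
    """
    from scipy.ndimage import gaussian_filter

    h, w = meta.image_shape
    canvas = np.zeros((h, w))
    for poly in filaments.polylines:
        cum = _polyline_cumlen(poly)
        n = max(2, int(cum[-1] / 0.5))
        ss = np.linspace(0.0, cum[-1], n)
        xs = np.interp(ss, cum, poly[:, 0])
        ys = np.interp(ss, cum, poly[:, 1])
        ix = np.clip(np.round(xs).astype(int), 0, w - 1)
        iy = np.clip(np.round(ys).astype(int), 0, h - 1)
        canvas[iy, ix] = 1.0
    canvas = gaussian_filter(canvas, line_sigma)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()
    img = background + amplitude * canvas
    if noise:
        rng = _rng_from(seed)
        img = np.clip(rng.poisson(img).astype(float), 0.0, None)
    return img.astype(np.float32)


# ----------------------------------------------------------------------
# benchmark datasets
# ----------------------------------------------------------------------

def apportion_counts(fractions, n: int) -> list[int]:
    """Deterministic largest-remainder apportionment of ``n`` among fractions."""
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    quota = fractions * n
    counts = np.floor(quota).astype(int)
    remainder = int(n - counts.sum())
    # ties in fractional part broken by lowest index (stable argsort)
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def make_benchmark_dataset(mixture=(0.15, 0.41, 0.44), n_trajectories: int = 100,
                           meta: AcquisitionMeta | None = None, seed: int = 0,
                           min_separation: float = 12.0, n_filaments: int | None = None,
                           render: bool = True, psf_sigma: float = 1.3,
                           photon_scale: float = 150.0, background: float = 20.0,
                           read_noise_sd: float = 2.0,
                           confined_params: MotionModelParams | None = None,
                           brownian_params: MotionModelParams | None = None,
                           directed_params: MotionModelParams | None = None,
                           ) -> tuple[np.ndarray | None, GroundTruth]:
    """Generate a labelled benchmark: ground truth plus (optionally) a movie.

    ``mixture`` gives the fractions of (confined, Brownian, directed)
    trajectories; the default mirrors the observed population frequencies
    (15% restricted, 41% Brownian, 44% directed). Counts are assigned by
    largest-remainder apportionment, so the split is deterministic. Starts
    are rejection-sampled to be at least ``min_separation`` px apart
    (directed starts sit on their filament). With ``render=False`` the stack
    is ``None`` — useful for trajectory-level benchmarks that skip imaging.
    """
    meta = meta or AcquisitionMeta()
    counts = apportion_counts(mixture, n_trajectories)
    if n_filaments is None:
        # enough filament arc that directed starts fit at the separation
        n_filaments = max(8, int(np.ceil(counts[2] / 7)))
    root = np.random.SeedSequence(seed)
    ss_filaments, ss_place, ss_render, *ss_traj = root.spawn(3 + n_trajectories)

    filaments = generate_filament_map(meta, n_filaments, np.random.default_rng(ss_filaments))
    rng_place = np.random.default_rng(ss_place)
    h, w = meta.image_shape
    margin = 18.0

    labels: list[MotionClass] = []
    params_list: list[MotionModelParams] = []
    for model_i, n_i in enumerate(counts):
        for _ in range(n_i):
            if model_i == 0:
                p = confined_params or MotionModelParams.confined()
                p = replace(p, model=MotionModel.CONFINED)
            elif model_i == 1:
                p = brownian_params or MotionModelParams.brownian()
                p = replace(p, model=MotionModel.BROWNIAN)
            else:
                base = directed_params or MotionModelParams.directed(track_id=0)
                p = replace(base, model=MotionModel.DIRECTED,
                            track_id=int(rng_place.integers(len(filaments))))
            labels.append(p.motion_class)
            params_list.append(p)

    starts, params_list = _place_starts(params_list, filaments, meta, rng_place,
                                        min_separation, margin)

    trajectories = []
    for i, (p, start) in enumerate(zip(params_list, starts)):
        traj = simulate_trajectory(p, meta, start, np.random.default_rng(ss_traj[i]),
                                   filaments=filaments)
        traj.id = i
        trajectories.append(traj)

    truth = GroundTruth(trajectories=trajectories, labels=labels, params=params_list,
                        seed=seed, filaments=filaments)
    stack = None
    if render:
        stack = render_movie(truth, meta, psf_sigma=psf_sigma, photon_scale=photon_scale,
                             background=background, read_noise_sd=read_noise_sd,
                             seed=np.random.default_rng(ss_render))
    return stack, truth


def _place_starts(params_list, filaments, meta, rng, min_separation, margin):
    """Rejection-sample non-overlapping start positions.

    Directed particles start on a filament; if their assigned filament is too
    crowded, the filament is re-drawn (track_id updated) rather than failing.
    Returns (starts, possibly-updated params list).
    """
    h, w = meta.image_shape
    placed: list[np.ndarray] = []
    starts_by_index: dict[int, np.ndarray] = {}
    params_by_index: dict[int, MotionModelParams] = {}
    max_attempts = 2000
    # directed particles are constrained to filament arcs, so place them
    # before the freely-placed ones fill the field
    order = sorted(range(len(params_list)),
                   key=lambda i: params_list[i].model is not MotionModel.DIRECTED)
    for i in order:
        p = params_list[i]
        for attempt in range(max_attempts):
            if p.model is MotionModel.DIRECTED:
                if attempt and attempt % 50 == 0:  # crowded filament: re-draw
                    p = replace(p, track_id=int(rng.integers(len(filaments))))
                poly = filaments[p.track_id]
                cum = _polyline_cumlen(poly)
                cand = _point_at_arclength(poly, cum, rng.uniform(0.15, 0.85) * cum[-1])
                if not (margin <= cand[0] < w - margin and margin <= cand[1] < h - margin):
                    continue
            else:
                cand = np.array([rng.uniform(margin, w - margin),
                                 rng.uniform(margin, h - margin)])
            if all(np.hypot(*(cand - q)) >= min_separation for q in placed):
                placed.append(cand)
                starts_by_index[i] = cand
                params_by_index[i] = p
                break
        else:
            raise ValueError(
                f"could not place {len(params_list)} spots with min_separation="
                f"{min_separation} px in a {w}x{h} field; lower the density")
    return ([starts_by_index[i] for i in range(len(params_list))],
            [params_by_index[i] for i in range(len(params_list))])
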