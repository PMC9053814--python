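"""Synthetic blebbing-cell movies with exact ground truth.

Renders a calibrated time-lapse of one cell — an elliptical cell body with
circular (optionally radially elongated) blebs attached at its rim — plus
the noise-free truth masks, bleb tracks, and phenotype implied by the scene
parameters.  Every pipeline stage can therefore be tested closed-loop
without any real data.

Geometry is deterministic given the scene parameters; a single integer seed
drives one ``numpy.random.default_rng`` for both preset randomization
(bleb angles, birth frames) and rendering noise, so the same seed always
reproduces the identical movie bit for bit.

The presets emulate the confined-melanoma phenotypes (LM, LNM, NL) and the
two qualitative bleb-dynamics regimes — apoptotic-like cells with many
short-lived blebs versus low-confinement cells with few long-lived,
elongated blebs.  Default imaging conditions follow the reference regime
for confined-cell time lapses: 0.5 µm pixels, 8 min between frames, and
additive Gaussian noise at 5% of the cell-to-background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dynamics import BlebTrack, Phenotype, Trajectory, classify
from .stack_io import ImageStack, MaskStack

PRESETS = ("LM", "LNM", "NL", "apoptotic_like", "low_confinement_like")

DEFAULT_IMAGE_SIZE = 192
DEFAULT_PIXEL_SIZE_UM = 0.5
DEFAULT_FRAME_INTERVAL_MIN = 8.0
DEFAULT_N_FRAMES = 10
DEFAULT_BACKGROUND = 20.0
DEFAULT_CELL_INTENSITY = 120.0


@dataclass
class BlebSpec:
    """One bleb: a disk attached to the body rim at a fixed body angle."""

    angle_deg: float
    radius_um: float
    birth_frame: int
    lifetime_frames: int
    elongation: float = 1.0  # >1 stretches the bleb radially (outward)

    def alive(self, frame: int) -> bool:
        return self.birth_frame <= frame < self.birth_frame + self.lifetime_frames


@dataclass
class SceneParams:
    """Full description of one synthetic movie."""

    image_size_px: int = DEFAULT_IMAGE_SIZE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    n_frames: int = DEFAULT_N_FRAMES
    body_center_um: tuple[float, float] = (48.0, 48.0)  # (x, y)
    body_axes_um: tuple[float, float] = (12.0, 9.0)  # semi-axes (x, y)
    body_orientation_deg: float = 0.0
    motion: str = "none"  # "none" | "linear" | "random_walk"
    velocity_um_min: tuple[float, float] = (0.0, 0.0)  # for "linear"
    step_um: float = 0.0  # per-frame step for "random_walk"
    blebs: list[BlebSpec] = field(default_factory=list)
    background_intensity: float = DEFAULT_BACKGROUND
    cell_intensity: float = DEFAULT_CELL_INTENSITY
    noise_sigma: float = 0.05 * (DEFAULT_CELL_INTENSITY - DEFAULT_BACKGROUND)
    seed: int = 0
    name: str = "synthetic"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Noise-free truth accompanying a rendered movie."""

    whole_cell: MaskStack
    cell_body: MaskStack
    all_blebs: MaskStack
    largest_bleb: MaskStack
    tracks: list[BlebTrack]
    trajectory: Trajectory
    phenotype: Phenotype


def _body_centers(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """(T, 2) body center (x, y) in µm per frame."""
    c0 = np.asarray(params.body_center_um, dtype=float)
    centers = np.tile(c0, (params.n_frames, 1))
    if params.motion == "linear":
        v = np.asarray(params.velocity_um_min, dtype=float)
        t = np.arange(params.n_frames)[:, None] * params.frame_interval_min
        centers = c0 + v * t
    elif params.motion == "random_walk":
        angles = rng.uniform(0, 2 * np.pi, size=params.n_frames - 1)
        steps = params.step_um * np.column_stack([np.cos(angles), np.sin(angles)])
        centers[1:] = c0 + np.cumsum(steps, axis=0)
    elif params.motion != "none":
        raise ValueError(f"unknown motion {params.motion!r}")
    return centers


def _ellipse_mask(
    shape: tuple[int, int],
    center_um: np.ndarray,
    axes_um: tuple[float, float],
    orientation_deg: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Pixels whose centers fall inside the ellipse."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx * pixel_size_um - center_um[0]
    y = yy * pixel_size_um - center_um[1]
    th = np.deg2rad(orientation_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    a, b = axes_um
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _bleb_center_um(
    body_center: np.ndarray, params: SceneParams, bleb: BlebSpec
) -> np.ndarray:
    """Bleb center sits on the body rim along the bleb's body angle."""
    th = np.deg2rad(bleb.angle_deg + params.body_orientation_deg)
    a, b = params.body_axes_um
    rim = body_center + np.array([a * np.cos(th), b * np.sin(th)])
    return rim


def _bleb_mask(
    shape: tuple[int, int],
    body_center: np.ndarray,
    params: SceneParams,
    bleb: BlebSpec,
) -> np.ndarray:
    center = _bleb_center_um(body_center, params, bleb)
    # Elongation stretches the bleb along its outward (radial) direction.
    axes = (bleb.radius_um * bleb.elongation, bleb.radius_um)
    orient = bleb.angle_deg + params.body_orientation_deg
    return _ellipse_mask(shape, center, axes, orient, params.pixel_size_um)


def render(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Rasterize a scene into a noisy movie plus its exact ground truth.

    Truth semantics mirror the pipeline's own mask algebra: the whole cell
    is body ∪ blebs, all-blebs is whole minus the body ellipse (so bleb
    pixels inside the body belong to the body), and the truth tracks carry
    the per-frame visible (outside-body) bleb areas.  The truth phenotype
    is derived from the scene parameters by the same persistence rules the
    classifier uses, applied to the *noise-free* truth — bookkeeping that is
    independent of the segmentation pipeline under test.
    """
    shape = (params.image_size_px, params.image_size_px)
    rng = np.random.default_rng(params.seed)
    centers = _body_centers(params, rng)

    whole = np.zeros((params.n_frames,) + shape, dtype=bool)
    body = np.zeros_like(whole)
    blebs_mask = np.zeros_like(whole)
    movie = np.zeros((params.n_frames,) + shape, dtype=np.float64)
    track_areas: dict[int, dict[int, float]] = {i: {} for i in range(len(params.blebs))}
    px_area = params.pixel_size_um**2

    for t in range(params.n_frames):
        body_t = _ellipse_mask(
            shape, centers[t], params.body_axes_um, params.body_orientation_deg,
            params.pixel_size_um,
        )
        whole_t = body_t.copy()
        for i, bleb in enumerate(params.blebs):
            if not bleb.alive(t):
                continue
            bm = _bleb_mask(shape, centers[t], params, bleb)
            visible = bm & ~body_t
            if not bm.any() or _touches_border(bm):
                raise ValueError(f"bleb {i} leaves the frame at frame {t}")
            whole_t |= bm
            track_areas[i][t] = float(visible.sum() * px_area)
        if _touches_border(whole_t) or not body_t.any():
            raise ValueError(f"cell geometry leaves the frame at frame {t}")
        whole[t] = whole_t
        body[t] = body_t
        blebs_mask[t] = whole_t & ~body_t
        movie[t] = np.where(
            whole_t, params.cell_intensity, params.background_intensity
        )

    if params.noise_sigma > 0:
        movie = movie + rng.normal(0.0, params.noise_sigma, size=movie.shape)

    cal = dict(
        pixel_size_um=params.pixel_size_um,
        frame_interval_min=params.frame_interval_min,
    )
    stack = ImageStack(movie, name=params.name, calibrated=True, **cal)

    tracks = [
        BlebTrack(
            track_id=i,
            components={t: i + 1 for t in areas},
            areas_um2=dict(areas),
            frame_interval_min=params.frame_interval_min,
        )
        for i, areas in track_areas.items()
        if areas
    ]
    largest = np.zeros_like(blebs_mask)
    for t in range(params.n_frames):
        live = [
            (track_areas[i][t], i)
            for i in track_areas
            if t in track_areas[i] and track_areas[i][t] > 0
        ]
        if live:
            _, best = max(live, key=lambda p: (p[0], -p[1]))
            bm = _bleb_mask(shape, centers[t], params, params.blebs[best])
            largest[t] = bm & ~body[t]

    traj = Trajectory(
        cell_id=params.name,
        points_um=_truth_centroids(whole, params.pixel_size_um),
        frame_interval_min=params.frame_interval_min,
    )
    whole_areas = whole.reshape(params.n_frames, -1).sum(axis=1) * px_area
    phenotype = classify(traj, tracks, whole_areas)

    def _mask(arr: np.ndarray, comp: str) -> MaskStack:
        return MaskStack(arr, compartment=comp, name=params.name, **cal)

    truth = GroundTruth(
        whole_cell=_mask(whole, "whole_cell"),
        cell_body=_mask(body, "cell_body"),
        all_blebs=_mask(blebs_mask, "all_blebs"),
        largest_bleb=_mask(largest, "largest_bleb"),
        tracks=tracks,
        trajectory=traj,
        phenotype=phenotype,
    )
    return stack, truth


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _truth_centroids(whole: np.ndarray, pixel_size_um: float) -> np.ndarray:
    pts = []
    for frame in whole:
        rr, cc = np.nonzero(frame)
        pts.append((cc.mean() * pixel_size_um, rr.mean() * pixel_size_um))
    return np.asarray(pts)


def preset(name: str, seed: int = 0, n_frames: int = DEFAULT_N_FRAMES) -> SceneParams:
    """Scene parameters for one of the named phenotype/dynamics regimes.

    * ``LM`` — linear mover at 0.6 µm/min with a persistent leader bleb
      around 25% of the cell area.
    * ``LNM`` — static cell with the same leader bleb.
    * ``NL`` — static cell with six small (~2.5 µm) blebs living ≤ 2 frames.
    * ``apoptotic_like`` — static cell with eight highly dynamic 1–2-frame
      blebs.
    * ``low_confinement_like`` — static cell with two long-lived, radially
      elongated blebs.

    The seed randomizes bleb attachment angles and birth frames within the
    regime and also drives the rendering noise.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    params = SceneParams(seed=seed, n_frames=n_frames, name=f"{name}_seed{seed}")

    def _angles(n: int, spread: float = 360.0, jitter: float = 12.0) -> np.ndarray:
        base = np.linspace(0, spread, n, endpoint=False)
        return base + rng.uniform(-jitter, jitter, size=n) + rng.uniform(0, 360)

    if name in ("LM", "LNM"):
        leader_angle = float(rng.uniform(0, 360))
        params.blebs = [
            BlebSpec(
                angle_deg=leader_angle,
                radius_um=10.0,
                birth_frame=0,
                lifetime_frames=n_frames,
            )
        ]
        if name == "LM":
            th = np.deg2rad(leader_angle)
            # Migrate toward the leader bleb, the hallmark of LBBM.
            speed = 0.5  # um/min, the fast-amoeboid regime (~30 um/hr)
            params.motion = "linear"
            params.velocity_um_min = (speed * np.cos(th), speed * np.sin(th))
            span = speed * params.frame_interval_min * (n_frames - 1)
            start = np.array([48.0, 48.0]) - span * np.array([np.cos(th), np.sin(th)]) / 2
            params.body_center_um = (float(start[0]), float(start[1]))
    elif name == "NL":
        n = 6
        angles = _angles(n)
        births = rng.integers(0, n_frames - 1, size=n)
        for i in range(n):
            params.blebs.append(
                BlebSpec(
                    angle_deg=float(angles[i]),
                    radius_um=2.5,
                    birth_frame=int(births[i]),
                    lifetime_frames=int(rng.integers(1, 3)),
                )
            )
    elif name == "apoptotic_like":
        n = 8
        angles = _angles(n)
        births = rng.integers(0, n_frames - 1, size=n)
        for i in range(n):
            params.blebs.append(
                BlebSpec(
                    angle_deg=float(angles[i]),
                    radius_um=3.0,
                    birth_frame=int(births[i]),
                    lifetime_frames=int(rng.integers(1, 3)),
                )
            )
    elif name == "low_confinement_like":
        angles = _angles(2, spread=360.0, jitter=20.0)
        for i in range(2):
            birth = int(rng.integers(0, 2))
            params.blebs.append(
                BlebSpec(
                    angle_deg=float(angles[i]),
                    radius_um=4.0,
                    birth_frame=birth,
                    lifetime_frames=n_frames - birth,
                    elongation=2.0,
                )
            )
    return params
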