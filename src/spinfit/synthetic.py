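"""Ground-truthed synthetic sequences of rotating textured spheroids.

Real inspection data comes as ordered, pre-segmented views of one object
on a black background, with the object rotated by an imperfectly known
amount between frames.  This module renders exactly that: an
orthographic camera, a spheroid of configurable type and semi-axes, a
seeded band-limited scalar texture attached to the body frame, and a
per-transition ground-truth rotation vector (optionally jittered to
mimic slip on the rollers).

The texture is a sum of random 3-D cosine waves evaluated on the unit
direction sphere of the body frame.  Band-limiting matters: features a
few reduced-resolution pixels wide survive the 4x downsample of the
matching stage, whereas white noise aliases away — and a perfectly
smooth skin is unmatchable by any method, which the ``contrast`` knob
lets tests demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ModelType, SpheroidShape, ViewPose, _pose_rows, _solve_surface_z, quadric_matrix
from .rotation import rodrigues

__all__ = ["SyntheticConfig", "SyntheticSequence", "TextureField",
           "render_sequence", "rasterize_ellipse"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a rendered sequence.

    Defaults emulate typical inspection-line data: object diameters of a
    few hundred pixels, 10-16 views per sequence, inter-view rotations of
    10-30 degrees dominated by the x-axis component.

    Attributes
    ----------
    model_type : sphere | oblate | prolate.
    A, B : float
        Semi-axes in pixels (``A >= B``; sphere requires ``A == B``).
    image_size : (height, width) in pixels.
    n_views : int
        Number of views; ``n_views - 1`` transitions.
    rotation_deg : (rx, ry)
        Nominal per-transition rotation vector in degrees (rz = 0).
    rotations_deg : optional sequence of (rx, ry)
        Explicit per-transition rotations; overrides ``rotation_deg``.
    initial_elevation_deg : float
        Elevation of the unique axis in the first view (ignored for
        spheres).
    texture_waves : int
        Number of cosine waves in the surface texture.
    texture_wavelength_px : (min, max)
        Surface feature wavelengths in full-resolution pixels at the
        equator; sets the band limit.
    contrast : float
        Standard deviation of the texture in grey levels (0 renders a
        textureless object).
    noise_sigma : float
        Additive per-view Gaussian noise (grey levels) on the green
        channel, independent between views.
    slip_sigma_deg : float
        Std of Gaussian jitter added to rx and ry of every transition,
        modelling slip on the rollers.
    seed : int
        Seed for all randomness; a fixed seed reproduces the frames
        byte for byte.
    """

    model_type: ModelType | str = ModelType.SPHERE
    A: float = 150.0
    B: float = 150.0
    image_size: tuple[int, int] = (384, 384)
    n_views: int = 12
    rotation_deg: tuple[float, float] = (18.0, 0.0)
    rotations_deg: tuple | None = None
    initial_elevation_deg: float = 40.0
    texture_waves: int = 64
    texture_wavelength_px: tuple[float, float] = (15.0, 45.0)
    contrast: float = 40.0
    noise_sigma: float = 0.0
    slip_sigma_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "model_type", ModelType(self.model_type))
        if self.A < self.B:
            raise ValueError(f"require A >= B, got A={self.A}, B={self.B}")
        if self.model_type is ModelType.SPHERE and self.A != self.B:
            raise ValueError("sphere model requires A == B")
        if self.model_type is not ModelType.SPHERE and self.A == self.B:
            raise ValueError(f"{self.model_type.value} model requires A > B")
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if self.rotations_deg is not None and len(self.rotations_deg) != self.n_views - 1:
            raise ValueError("rotations_deg must have n_views - 1 entries")
        h, w = self.image_size
        if 2 * self.A + 2 > min(h, w):
            raise ValueError(
                f"image size {self.image_size} too small for semi-axis A={self.A}"
            )

    @property
    def shape(self) -> SpheroidShape:
        return SpheroidShape(self.model_type, self.A, self.B)


@dataclass(frozen=True)
class SyntheticSequence:
    """Rendered frames plus everything the renderer knew.

    ``rotations_deg[t]`` is the true camera-frame rotation vector
    (degrees, rz = 0) taking view t to view t+1, including slip jitter.
    ``poses[i]`` is the true pose matrix of view i.
    """

    frames: list
    masks: list
    rotations_deg: np.ndarray
    poses: list
    config: SyntheticConfig

    @property
    def n_views(self) -> int:
        return len(self.frames)


class TextureField:
    """Seeded band-limited scalar field on the unit sphere of directions."""

    def __init__(self, rng: np.random.Generator, n_waves: int,
                 omega_min: float, omega_max: float):
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = rng.uniform(omega_min, omega_max, size=n_waves)
        self.omega = dirs * mags[:, None]
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
        # sum of unit-amplitude cosines with random phases
        self.std = np.sqrt(n_waves / 2.0)

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        return np.cos(directions @ self.omega.T + self.phase).sum(axis=-1)


def _initial_pose(cfg: SyntheticConfig) -> np.ndarray:
    """True pose of the first view.

    Oblate objects sit with their equator horizontal (major direction v1
    along image x); prolate objects tumble end over end with the long
    axis projecting along image y.
    """
    theta = np.radians(cfg.initial_elevation_deg)
    if cfg.model_type is ModelType.SPHERE:
        return np.eye(3)
    if cfg.model_type is ModelType.OBLATE:
        v1, v2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    else:
        v1, v2 = np.array([0.0, 1.0]), np.array([-1.0, 0.0])
    return _pose_rows(v1, v2, theta, cfg.model_type)


def _render_view(P: np.ndarray, cfg: SyntheticConfig, texture: TextureField,
                 noise: np.ndarray | None):
    h, w = cfg.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    shape = cfg.shape
    pose = ViewPose(theta=0.0, P=P, center=(cx, cy))
    amat = quadric_matrix(shape, pose)

    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z, valid = _solve_surface_z(amat, X - cx, Y - cy)

    ys, xs = np.nonzero(valid)
    pcam = np.column_stack([X[ys, xs] - cx, Y[ys, xs] - cy, z[ys, xs]])
    pbody = pcam @ P.T  # body coordinates: rows of P are body axes
    s = pbody / shape.semi_axes_body
    s /= np.linalg.norm(s, axis=1, keepdims=True)

    g = np.zeros((h, w))
    vals = 128.0 + cfg.contrast * texture(s) / texture.std
    if noise is not None:
        vals = vals + noise[ys, xs]
    g[ys, xs] = np.clip(vals, 8.0, 255.0)

    green = np.rint(g).astype(np.uint8)
    frame = np.stack(
        [np.rint(0.55 * g).astype(np.uint8),
         green,
         np.rint(0.30 * g).astype(np.uint8)],
        axis=-1,
    )
    return frame, valid


def render_sequence(cfg: SyntheticConfig) -> SyntheticSequence:
    """Render a full ground-truthed sequence.

    Pixels on the object get the body-frame texture sampled at the
    visible surface point; the background stays black (RGB = 0).  The
    texture lives in the green channel — the channel the matching stage
    uses — with the other channels scaled copies.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.texture_wavelength_px
    omega_max = 2.0 * np.pi * cfg.A / lo
    omega_min = 2.0 * np.pi * cfg.A / hi
    texture = TextureField(rng, cfg.texture_waves, omega_min, omega_max)

    n_t = cfg.n_views - 1
    if cfg.rotations_deg is not None:
        base = np.asarray(
            [[r[0], r[1]] for r in cfg.rotations_deg], dtype=float
        ).reshape(n_t, 2)
    else:
        base = np.tile(np.asarray(cfg.rotation_deg, dtype=float), (n_t, 1))
    rotations = np.zeros((n_t, 3))
    rotations[:, :2] = base
    if cfg.slip_sigma_deg > 0.0:
        rotations[:, :2] += rng.normal(0.0, cfg.slip_sigma_deg, size=(n_t, 2))

    poses = [_initial_pose(cfg)]
    for t in range(n_t):
        R = rodrigues(np.radians(rotations[t]))
        # camera-frame rotation of the object: body axes rows update as P R^T
        poses.append(poses[-1] @ R.T)

    frames, masks = [], []
    for P in poses:
        noise = (rng.normal(0.0, cfg.noise_sigma, size=cfg.image_size)
                 if cfg.noise_sigma > 0.0 else None)
        frame, mask = _render_view(P, cfg, texture, noise)
        frames.append(frame)
        masks.append(mask)
    return SyntheticSequence(frames=frames, masks=masks,
                             rotations_deg=rotations, poses=poses, config=cfg)


def rasterize_ellipse(a: float, b: float, angle_deg: float,
                      cx: float, cy: float, shape_hw: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a filled ellipse — the silhouette test substrate.

    ``a``/``b`` are the semi-axes in pixels and ``angle_deg`` the
    major-axis direction measured from the +x axis.
    """
    h, w = shape_hw
    phi = np.radians(angle_deg)
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dx, dy = X - cx, Y - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
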