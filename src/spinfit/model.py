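"""Model/results interface over the full pipeline.

:class:`SpheroidRotationModel` holds an ordered sequence of segmented
views and the pipeline configuration; :meth:`~SpheroidRotationModel.fit`
runs silhouette-moment ellipse fitting, spheroid-axis pooling, per-view
pose recovery, working-image preprocessing and the per-transition
rotation search, and returns a :class:`SpheroidRotationResults` carrying
the estimates, their error maps and diagnostics.  Tracking and plotting
hang off the results object.

    >>> seq = render_sequence(SyntheticConfig(seed=7))
    >>> res = SpheroidRotationModel(seq.frames, model_type="sphere").fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import geometry, preprocess, rotation, tracking
from .geometry import ModelType
from .io import load_sequence, mask_from_frame

__all__ = ["PipelineConfig", "SpheroidRotationModel", "SpheroidRotationResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the pipeline with their defaults.

    model_type     geometric model of the object (not auto-detected)
    direction      rotation sense as seen by the camera ("down" | "up")
    stride         moment-sum stride for ellipse fitting (speed trick)
    factor         downsampling factor of the matching images
    sigma          high-pass Gaussian width, reduced-resolution pixels
    shrink         border-ellipse shrink factor for relevant points
    percentile     |high-pass| percentile for relevant-point selection
    beta_max/alpha/gamma   rotation search grid, degrees
    """

    model_type: ModelType = ModelType.SPHERE
    direction: str = "down"
    stride: int = 4
    factor: int = 4
    sigma: float = 1.25
    shrink: float = 0.85
    percentile: float = 97.0
    beta_max: float = 35.0
    alpha: float = 10.0
    gamma: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "model_type", ModelType(self.model_type))

    @property
    def grid(self) -> rotation.SearchGrid:
        return rotation.SearchGrid(self.beta_max, self.alpha, self.gamma)


class SpheroidRotationModel:
    """Single-camera 3-D rotation estimator for a quasi-spheroidal object.

    Parameters
    ----------
    frames : sequence of (H, W, 3) arrays
        Ordered views of one object on a black background.
    masks : optional sequence of boolean arrays
        Foreground masks; derived from the frames (any channel non-zero)
        when omitted.
    model_type, direction, **overrides
        Pipeline configuration; any :class:`PipelineConfig` field can be
        overridden by keyword.
    """

    def __init__(self, frames, masks=None, model_type="sphere",
                 direction="down", config: PipelineConfig | None = None,
                 **overrides):
        if config is None:
            config = PipelineConfig(model_type=ModelType(model_type),
                                    direction=direction, **overrides)
        self.config = config
        self.frames = [np.asarray(f) for f in frames]
        if len(self.frames) < 2:
            raise ValueError("need at least 2 views to estimate rotations")
        shape0 = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape0:
                raise ValueError(f"view {i} has shape {f.shape}, expected {shape0}")
        if masks is None:
            masks = [mask_from_frame(f) for f in self.frames]
        self.masks = [np.asarray(m, dtype=bool) for m in masks]

    @classmethod
    def from_directory(cls, path, **kwargs) -> "SpheroidRotationModel":
        """Build the model from a directory of ordered PNG frames."""
        record = load_sequence(path)
        return cls(record.frames, masks=record.masks, **kwargs)

    @classmethod
    def from_synthetic(cls, sequence, **kwargs) -> "SpheroidRotationModel":
        """Build the model from a :class:`~spinfit.synthetic.SyntheticSequence`,
        defaulting the model type to the one that generated it."""
        kwargs.setdefault("model_type", sequence.config.model_type)
        return cls(sequence.frames, masks=sequence.masks, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "SpheroidRotationResults":
        cfg = self.config
        timings: dict[str, float] = {}

        t0 = time.perf_counter()
        ellipses = [geometry.fit_ellipse(m, stride=cfg.stride) for m in self.masks]
        shape = geometry.fit_spheroid(ellipses, cfg.model_type)
        timings["geometry"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if cfg.model_type is ModelType.SPHERE:
            thetas = np.zeros(len(ellipses))
            poses = [geometry.pose_matrix(e, 0.0, cfg.model_type) for e in ellipses]
        else:
            # the varying projected axis carries the elevation: the minor
            # axis for oblate objects, the major axis for prolate ones
            if cfg.model_type is ModelType.OBLATE:
                varying = [e.b for e in ellipses]
                direction = cfg.direction
            else:
                varying = [e.a for e in ellipses]
                # the prolate monotonicity rule is the oblate one mirrored
                direction = "up" if cfg.direction.lower().startswith("down") else "down"
            magnitudes = [geometry.elevation_angle_magnitude(v, shape) for v in varying]
            thetas = geometry.assign_elevation_signs(varying, magnitudes, direction)
            poses = [geometry.pose_matrix(e, th, cfg.model_type)
                     for e, th in zip(ellipses, thetas)]
        timings["pose"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        inv = 1.0 / cfg.factor
        red_shape = shape.scaled(inv)
        working, points, points3d = [], [], []
        for frame, mask, ellipse, pose in zip(self.frames, self.masks, ellipses, poses):
            img = preprocess.make_working_image(
                frame, factor=cfg.factor, sigma=cfg.sigma, mask=mask,
                center=(ellipse.cx, ellipse.cy),
            )
            red_ellipse = ellipse.scaled(inv)
            pts = preprocess.select_relevant_points(
                img, red_ellipse, shrink=cfg.shrink, percentile=cfg.percentile
            )
            lifted, valid = geometry.lift_points(pts.points, red_shape, pose.scaled(inv))
            if not valid.all():  # shrink ellipse should preclude this; guard anyway
                pts = preprocess.RelevantPointList(pts.points[valid], pts.scores[valid])
                lifted = lifted[valid]
            working.append(img)
            points.append(pts)
            points3d.append(lifted)
        timings["preprocess"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        grid = cfg.grid
        rotations = [
            rotation.estimate_rotation(
                working[t], points[t], points3d[t], working[t + 1], grid=grid,
            )
            for t in range(len(self.frames) - 1)
        ]
        timings["rotation"] = time.perf_counter() - t0

        return SpheroidRotationResults(
            model=self, config=cfg, shape=shape, ellipses=ellipses,
            thetas=np.asarray(thetas), poses=poses, working_images=working,
            relevant_points=points, rotations=rotations, timings=timings,
        )


@dataclass
class SpheroidRotationResults:
    """Fitted geometry and per-transition rotation estimates."""

    model: SpheroidRotationModel
    config: PipelineConfig
    shape: geometry.SpheroidShape
    ellipses: list
    thetas: np.ndarray
    poses: list
    working_images: list
    relevant_points: list
    rotations: list
    timings: dict

    @property
    def n_views(self) -> int:
        return len(self.ellipses)

    @property
    def rotation_vectors_deg(self) -> np.ndarray:
        """(n_transitions, 3) refined rotation vectors in degrees."""
        return np.degrees(np.vstack([r.vector for r in self.rotations]))

    @property
    def rotation_magnitudes_deg(self) -> np.ndarray:
        return np.array([r.angle_deg for r in self.rotations])

    # -- tracking ---------------------------------------------------------

    def track(self, point_xy, view: int = 0) -> tracking.TrackedPoint:
        """Track a full-resolution pixel of ``view`` across all views."""
        return tracking.track(point_xy, view, self.rotations, self.shape, self.poses)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "        Spheroid rotation estimation",
            "=" * 58,
            f"Model type:      {self.shape.model_type.value:<10}  Views: {self.n_views}",
            f"Semi-axes:       A = {self.shape.A:7.2f} px   B = {self.shape.B:7.2f} px",
            f"Search grid:     rx 0..{cfg.beta_max:g} deg, ry +-{cfg.alpha:g} deg, "
            f"step {cfg.gamma:g} deg",
            f"Matching:        factor {cfg.factor}, sigma {cfg.sigma:g}, "
            f"shrink {cfg.shrink:g}, percentile {cfg.percentile:g}",
            "-" * 58,
            "transition    rx (deg)   ry (deg)   |rot|      eps    |S|",
        ]
        for t, r in enumerate(self.rotations):
            lines.append(
                f"{t:3d} -> {t + 1:<3d}   {r.rx_deg:8.2f}  {r.ry_deg:9.2f}  "
                f"{r.angle_deg:7.2f}  {r.error:8.3f}  {r.n_points:5d}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fitted model and the estimates."""
        per_view = [
            {
                "cx": e.cx, "cy": e.cy, "a": e.a, "b": e.b,
                "theta": float(th), "P": p.P.reshape(-1).tolist(),
            }
            for e, th, p in zip(self.ellipses, self.thetas, self.poses)
        ]
        transitions = [
            {
                "from": t, "to": t + 1,
                "rx_deg": r.rx_deg, "ry_deg": r.ry_deg,
                "matrix": r.matrix.reshape(-1).tolist(),
                "epsilon": r.error, "n_points": r.n_points,
                "refined": bool(r.refined),
            }
            for t, r in enumerate(self.rotations)
        ]
        return {
            "model_type": self.shape.model_type.value,
            "A": self.shape.A,
            "B": self.shape.B,
            "factor": self.config.factor,
            "per_view": per_view,
            "transitions": transitions,
        }

    # -- plotting ---------------------------------------------------------

    def plot_error_map(self, transition: int, ax=None):
        """Error map of one transition with the refined minimum marked."""
        import matplotlib.pyplot as plt

        r = self.rotations[transition]
        emap = r.error_map
        if ax is None:
            _, ax = plt.subplots()
        extent = [emap.ry_deg[0] - 0.5, emap.ry_deg[-1] + 0.5,
                  emap.rx_deg[-1] + 0.5, emap.rx_deg[0] - 0.5]
        im = ax.imshow(emap.values, extent=extent, aspect="auto", cmap="viridis")
        ax.plot(r.ry_deg, r.rx_deg, "r+", markersize=12)
        ax.set_xlabel("ry (deg)")
        ax.set_ylabel("rx (deg)")
        ax.set_title(f"error map, transition {transition} -> {transition + 1}")
        plt.colorbar(im, ax=ax, label="eps")
        return ax

    def plot_track(self, tracked: tracking.TrackedPoint, ncols: int = 5):
        """Overlay a tracked point on every view: green when visible,
        dark when on the hidden hemisphere."""
        import matplotlib.pyplot as plt

        n = self.n_views
        nrows = int(np.ceil(n / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows))
        axes = np.atleast_1d(axes).ravel()
        for j in range(n):
            ax = axes[j]
            ax.imshow(self.model.frames[j])
            x, y = tracked.positions[j]
            color = "lime" if tracked.visible[j] else "#303030"
            ax.plot(x, y, "o", color=color, markersize=8, markerfacecolor="none",
                    markeredgewidth=2)
            ax.set_title(f"view {j}", fontsize=8)
            ax.axis("off")
        for ax in axes[n:]:
            ax.axis("off")
        fig.tight_layout()
        return fig
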