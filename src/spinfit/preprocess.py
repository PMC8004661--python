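"""Reduced-resolution high-pass matching images and relevant-point selection.

Candidate rotations are scored by comparing texture, not raw colour.  Each
RGB view is reduced to a small signed "working image": green channel,
block-averaged downsample (default factor 4), minus a Gaussian blur of
itself (sigma = 1.25 at reduced resolution).  The result is ~0 on smooth
skin and large in magnitude at texture, and is 16x cheaper to sample.

Scoring every fruit pixel would defeat the purpose, so a small list of
*relevant points* is kept: pixels inside a shrunken version of the
projected ellipse (points near the limb may rotate out of view) whose
absolute high-pass response exceeds a high percentile (default 97th).
Typical cardinality is 50-100 points per view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import EllipseObservation

__all__ = [
    "WorkingImage",
    "RelevantPointList",
    "PreprocessError",
    "block_downsample",
    "make_working_image",
    "select_relevant_points",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class WorkingImage:
    """Signed high-pass image at reduced resolution.

    ``center`` is the source view's ellipse centre divided by ``factor``
    (kept here so matching code never mixes resolutions by accident).
    """

    grid: np.ndarray
    factor: int
    center: tuple[float, float] | None = None


@dataclass(frozen=True)
class RelevantPointList:
    """High-|texture| pixels used to score candidate rotations.

    ``points`` is ``(N, 2)`` integer ``(x, y)`` in reduced-resolution
    coordinates; ``scores`` the corresponding ``|high-pass|`` values.
    """

    points: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return int(self.points.shape[0])


def block_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased integer downsample: each output pixel is the mean of the
    corresponding ``factor x factor`` block.  Trailing partial blocks (when
    a dimension is not divisible by ``factor``) average over the available
    pixels."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D array")
    h, w = img.shape
    if h < 1 or w < 1:
        raise PreprocessError("empty image")
    ri = np.arange(0, h, factor)
    ci = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(img, ri, axis=0), ci, axis=1)
    rcounts = np.minimum(ri + factor, h) - ri
    ccounts = np.minimum(ci + factor, w) - ci
    return sums / np.outer(rcounts, ccounts)


def make_working_image(
    rgb_view: np.ndarray,
    factor: int = 4,
    sigma: float = 1.25,
    mask: np.ndarray | None = None,
    center: tuple[float, float] | None = None,
) -> WorkingImage:
    """Green channel -> block-average downsample -> subtract Gaussian blur.

    Parameters
    ----------
    rgb_view : (H, W, 3) or (H, W) array
        Input view; for RGB input the green channel is used (cheapest
        luminance proxy).
    factor : int
        Downsampling factor in both axes.
    sigma : float
        Gaussian blur width in *reduced-resolution* pixels; the high-pass
        is ``downsampled - blur(downsampled)``.  Reflect padding at the
        borders; kernel truncated at 4 sigma.
    mask : optional boolean (H, W) array
        Pixels outside the mask are zeroed before downsampling so the
        limb produces a clean edge (relevant-point selection later
        excludes the limb region anyway).
    center : optional (cx, cy)
        Full-resolution ellipse centre; stored divided by ``factor``.
    """
    rgb_view = np.asarray(rgb_view)
    if rgb_view.size == 0:
        raise PreprocessError("empty image")
    if rgb_view.ndim == 3:
        green = rgb_view[:, :, 1].astype(np.float64)
    elif rgb_view.ndim == 2:
        green = rgb_view.astype(np.float64)
    else:
        raise ValueError("expected (H, W) or (H, W, 3) input")
    h, w = green.shape
    if h < factor or w < factor:
        raise PreprocessError(
            f"view of shape {(h, w)} smaller than downsampling factor {factor}"
        )
    if mask is not None:
        green = np.where(np.asarray(mask, dtype=bool), green, 0.0)
    ds = block_downsample(green, factor)
    hp = ds - gaussian_filter(ds, sigma=sigma, mode="reflect", truncate=4.0)
    red_center = None if center is None else (center[0] / factor, center[1] / factor)
    return WorkingImage(grid=hp, factor=factor, center=red_center)


def select_relevant_points(
    img: WorkingImage,
    ellipse: EllipseObservation,
    shrink: float = 0.85,
    percentile: float = 97.0,
) -> RelevantPointList:
    """Keep pixels well inside the silhouette whose ``|high-pass|`` exceeds
    the nearest-rank percentile over that region.

    ``ellipse`` must be expressed in the reduced-resolution frame (use
    :meth:`EllipseObservation.scaled`).  The candidate region is the
    ellipse with both semi-axes multiplied by ``shrink`` — points nearer
    the limb may not survive the expected rotations.  The percentile
    threshold uses the nearest-rank definition on sorted ``|values|`` and
    selection is *strictly* above it, so a constant region yields an
    empty list.
    """
    if not (0.0 < shrink <= 1.0):
        raise ValueError(f"shrink must be in (0, 1], got {shrink}")
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    grid = img.grid
    h, w = grid.shape
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dx = X - ellipse.cx
    dy = Y - ellipse.cy
    u = dx * ellipse.v1[0] + dy * ellipse.v1[1]
    v = dx * ellipse.v2[0] + dy * ellipse.v2[1]
    sa = shrink * ellipse.a
    sb = shrink * ellipse.b
    inside = (u / sa) ** 2 + (v / sb) ** 2 <= 1.0
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise PreprocessError(
            "no candidate pixels: shrunken ellipse does not cover the image"
        )
    absvals = np.abs(grid[inside])
    # nearest-rank percentile: k-th smallest with k = ceil(p/100 * n)
    k = int(np.ceil(percentile / 100.0 * n_inside))
    threshold = np.sort(absvals)[k - 1]
    keep = inside & (np.abs(grid) > threshold)
    ys, xs = np.nonzero(keep)
    order = np.lexsort((xs, ys))  # deterministic row-major ordering
    xs, ys = xs[order], ys[order]
    return RelevantPointList(
        points=np.column_stack([xs, ys]).astype(np.int64),
        scores=np.abs(grid[ys, xs]),
    )
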