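"""Inter-view 3-D rotation estimation by exhaustive rotation-vector search.

A candidate rotation R is scored by lifting the source view's relevant
points to 3-D, rotating them, dropping points that land on the hidden
hemisphere (z < 0), and comparing the source and target high-pass images
at the matched pixels:

    eps(R) = (1/|S|) * sum_S | Im_s(x_s, y_s) - Im_t(x_t, y_t) |

Rotations are parameterised as rotation vectors v = k*theta.  A roller
conveyor forces the dominant rotation about the image x-axis with a small
ry component and negligible rz, so the search space is a 2-D grid:
rx in [0, beta_max], ry in [-alpha, +alpha], step gamma (degrees).  The
coarse argmin is refined on a 5x5 half-step subgrid and then by separable
three-point parabolic interpolation along each axis, giving sub-grid
accuracy.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RelevantPointList, WorkingImage

logger = logging.getLogger(__name__)

__all__ = [
    "SearchGrid",
    "ErrorMap",
    "RotationEstimate",
    "AllInvalidGridError",
    "rodrigues",
    "score_rotation",
    "estimate_rotation",
]


class AllInvalidGridError(RuntimeError):
    """Every grid node lost all points to occlusion/out-of-bounds."""


def rodrigues(v) -> np.ndarray:
    """Rotation matrix from a rotation vector ``v = k*theta`` (radians).

    ``R = I + sin(theta) K + (1 - cos(theta)) K^2`` with K the
    cross-product matrix of the unit axis; the zero vector maps to the
    identity.
    """
    v = np.asarray(v, dtype=float).reshape(3)
    theta = float(np.linalg.norm(v))
    if theta < 1e-12:
        return np.eye(3)
    kx, ky, kz = v / theta
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


@dataclass(frozen=True)
class SearchGrid:
    """Rotation-vector search grid, all in degrees.

    ``rx`` spans ``[0, beta_max]`` (beta_max is the largest rotation the
    mechanical setup can produce), ``ry`` spans ``[-alpha, +alpha]``,
    both with step ``gamma``; ``rz`` is fixed at zero.
    """

    beta_max: float = 35.0
    alpha: float = 10.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0 or self.beta_max < 0 or self.alpha < 0:
            raise ValueError("invalid search-grid parameters")

    @property
    def rx_values_deg(self) -> np.ndarray:
        n = int(round(self.beta_max / self.gamma))
        return np.arange(n + 1) * self.gamma

    @property
    def ry_values_deg(self) -> np.ndarray:
        n = int(round(self.alpha / self.gamma))
        return (np.arange(2 * n + 1) - n) * self.gamma


@dataclass(frozen=True)
class ErrorMap:
    """eps over the (rx, ry) grid; NaN where no point survived.

    ``counts`` records |S| per node.
    """

    values: np.ndarray
    counts: np.ndarray
    rx_deg: np.ndarray
    ry_deg: np.ndarray


@dataclass(frozen=True)
class RotationEstimate:
    """Refined inter-view rotation.

    ``vector`` is the rotation vector in radians (rz = 0); ``error`` is
    eps at the refined vector — interpolated from the local parabola fit
    when ``error_interpolated`` is True, otherwise the value at the best
    subgrid node.  ``coarse_vector`` keeps the unrefined grid argmin for
    diagnostics.
    """

    vector: np.ndarray
    matrix: np.ndarray
    error: float
    error_map: ErrorMap
    n_points: int
    coarse_vector: np.ndarray
    subgrid_vector: np.ndarray | None = None
    refined: bool = True
    error_interpolated: bool = False

    @property
    def rx_deg(self) -> float:
        return float(np.degrees(self.vector[0]))

    @property
    def ry_deg(self) -> float:
        return float(np.degrees(self.vector[1]))

    @property
    def angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(np.degrees(np.linalg.norm(self.vector)))


def score_rotation(
    R: np.ndarray,
    src_values: np.ndarray,
    pts3d: np.ndarray,
    tgt: WorkingImage,
    tgt_center: tuple[float, float],
) -> tuple[float, int]:
    """Matching error of one candidate rotation.

    Parameters
    ----------
    R : (3, 3) rotation matrix.
    src_values : (N,) working-image values at the source relevant points.
    pts3d : (N, 3) lifted source points, centred camera frame, reduced
        resolution.
    tgt : target working image.
    tgt_center : target ellipse centre in the reduced frame.

    Returns
    -------
    (eps, n_valid) — mean absolute working-image difference over the
    surviving points and their count.  Points rotated onto the hidden
    hemisphere (z < 0) or mapped outside the target image are skipped;
    ``(nan, 0)`` signals that no point survived.

    The arithmetic is kept in elementwise form (no BLAS matmul) so a
    per-point reference loop reproduces it bit for bit.
    """
    x, y, z = pts3d[:, 0], pts3d[:, 1], pts3d[:, 2]
    xt = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
    yt = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
    zt = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z
    col = np.rint(xt + tgt_center[0]).astype(np.int64)
    row = np.rint(yt + tgt_center[1]).astype(np.int64)
    h, w = tgt.grid.shape
    ok = (zt >= 0.0) & (col >= 0) & (col < w) & (row >= 0) & (row < h)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    diff = np.abs(src_values[ok] - tgt.grid[row[ok], col[ok]])
    return float(np.sum(diff) / n), n


def _parabola_vertex(e_minus: float, e0: float, e_plus: float, h: float):
    """Vertex of the parabola through three equispaced samples.

    Returns ``(offset, value)`` relative to the centre sample, with the
    offset clamped to ``[-h, +h]``; ``(0, e0)`` when the samples are not
    convex (degenerate/tied minimum).
    """
    denom = e_minus - 2.0 * e0 + e_plus
    if denom <= 0.0:
        return 0.0, e0
    offset = h * (e_minus - e_plus) / (2.0 * denom)
    offset = float(np.clip(offset, -h, h))
    value = e0 - (e_minus - e_plus) ** 2 / (8.0 * denom)
    return offset, float(value)


def estimate_rotation(
    src_image: WorkingImage,
    src_points: RelevantPointList,
    src_points3d: np.ndarray,
    tgt_image: WorkingImage,
    grid: SearchGrid | None = None,
    tgt_center: tuple[float, float] | None = None,
) -> RotationEstimate:
    """Estimate the rotation from the source to the target view.

    1. Evaluate eps on the coarse (rx, ry) grid (Rodrigues per node; each
       node is one 3x3-by-3xN product over the relevant points).
    2. Take the argmin (ties resolved first-in-row-major, rx then ry).
    3. Densify: a 5x5 subgrid at step gamma/2 centred on the argmin,
       reusing the 9 coarse nodes it overlaps; nodes outside the search
       ranges are not evaluated.
    4. Take the subgrid argmin and refine with two independent 1-D
       three-point parabola fits (offsets clamped to +-gamma/2).  If the
       minimum sits on the subgrid boundary along an axis, refinement on
       that axis is skipped with a warning.

    ``src_points3d`` must be aligned row-for-row with
    ``src_points.points`` and lifted in the reduced-resolution frame.
    """
    if grid is None:
        grid = SearchGrid()
    if tgt_center is None:
        tgt_center = tgt_image.center
    if tgt_center is None:
        raise ValueError("target centre unknown: pass tgt_center or a WorkingImage with one")
    if len(src_points) == 0:
        raise AllInvalidGridError("no relevant points in the source view")

    pts = src_points.points
    src_values = src_image.grid[pts[:, 1], pts[:, 0]]
    pts3d = np.asarray(src_points3d, dtype=float)
    if pts3d.shape != (len(src_points), 3):
        raise ValueError("src_points3d must be (N, 3) aligned with src_points")

    def evaluate(rx_deg: float, ry_deg: float) -> tuple[float, int]:
        R = rodrigues(np.radians([rx_deg, ry_deg, 0.0]))
        return score_rotation(R, src_values, pts3d, tgt_image, tgt_center)

    rxs = grid.rx_values_deg
    rys = grid.ry_values_deg
    values = np.full((rxs.size, rys.size), np.nan)
    counts = np.zeros((rxs.size, rys.size), dtype=np.int64)
    for i, rx in enumerate(rxs):
        for j, ry in enumerate(rys):
            eps, n = evaluate(rx, ry)
            counts[i, j] = n
            if n > 0:
                values[i, j] = eps
    error_map = ErrorMap(values=values, counts=counts, rx_deg=rxs, ry_deg=rys)

    valid = counts > 0
    if not valid.any():
        raise AllInvalidGridError("every grid node lost all relevant points")
    masked = np.where(valid, values, np.inf)
    i0, j0 = np.unravel_index(int(np.argmin(masked)), masked.shape)
    rx0, ry0 = float(rxs[i0]), float(rys[j0])
    coarse_vec = np.radians([rx0, ry0, 0.0])

    # 5x5 subgrid at half step around the coarse minimum
    h = grid.gamma / 2.0
    offsets = (-2, -1, 0, 1, 2)
    sub = np.full((5, 5), np.inf)
    sub_counts = np.zeros((5, 5), dtype=np.int64)
    tol = 1e-9 * max(grid.gamma, 1.0)
    for oi, di in enumerate(offsets):
        rx = rx0 + di * h
        if rx < rxs[0] - tol or rx > rxs[-1] + tol:
            continue
        for oj, dj in enumerate(offsets):
            ry = ry0 + dj * h
            if ry < rys[0] - tol or ry > rys[-1] + tol:
                continue
            if di % 2 == 0 and dj % 2 == 0:  # coincides with a coarse node
                ii, jj = i0 + di // 2, j0 + dj // 2
                sub[oi, oj] = masked[ii, jj]
                sub_counts[oi, oj] = counts[ii, jj]
            else:
                eps, n = evaluate(rx, ry)
                sub_counts[oi, oj] = n
                if n > 0:
                    sub[oi, oj] = eps

    # Sub-pixel displacements on the reduced grid often round to the same
    # target pixels, so exact eps ties between neighbouring subgrid nodes
    # are common; among tied minima prefer the node closest to the window
    # centre (then row-major) so plateaus do not drag the minimum to the
    # window boundary and needlessly cancel the parabolic refinement.
    m = np.min(sub)
    ti, tj = np.nonzero(sub == m)
    order = np.lexsort((tj, ti, np.abs(ti - 2) + np.abs(tj - 2),
                        np.maximum(np.abs(ti - 2), np.abs(tj - 2))))
    si, sj = int(ti[order[0]]), int(tj[order[0]])
    e0 = float(sub[si, sj])
    rx_ref = rx0 + offsets[si] * h
    ry_ref = ry0 + offsets[sj] * h

    dx = dy = 0.0
    err = e0
    interpolated = False
    if 1 <= si <= 3 and np.isfinite(sub[si - 1, sj]) and np.isfinite(sub[si + 1, sj]):
        dx, vx = _parabola_vertex(float(sub[si - 1, sj]), e0, float(sub[si + 1, sj]), h)
        err += vx - e0
        interpolated = True
    else:
        logger.warning("rx refinement skipped: subgrid minimum on the boundary")
    if 1 <= sj <= 3 and np.isfinite(sub[si, sj - 1]) and np.isfinite(sub[si, sj + 1]):
        dy, vy = _parabola_vertex(float(sub[si, sj - 1]), e0, float(sub[si, sj + 1]), h)
        err += vy - e0
        interpolated = True
    else:
        logger.warning("ry refinement skipped: subgrid minimum on the boundary")

    vec = np.radians([rx_ref + dx, ry_ref + dy, 0.0])
    return RotationEstimate(
        vector=vec,
        matrix=rodrigues(vec),
        error=float(err),
        error_map=error_map,
        n_points=int(sub_counts[si, sj]),
        coarse_vector=coarse_vec,
        subgrid_vector=np.radians([rx_ref, ry_ref, 0.0]),
        refined=True,
        error_interpolated=interpolated,
    )
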