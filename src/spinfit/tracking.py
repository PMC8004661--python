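"""Surface-point tracking across a sequence of views.

Once the inter-view rotations are known, a pixel selected in one view can
be propagated to every other view: lift it to 3-D on the fitted spheroid,
concatenate the rotation matrices forwards (inverses backwards), and
re-project using each destination view's centre.  The point stays on the
spheroid by construction (rotations are orthonormal), and its z sign says
whether it lies on the visible or hidden hemisphere — the basis for
de-duplicating surface defects across overlapping views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, SpheroidShape, ViewPose, lift_to_3d

__all__ = ["TrackedPoint", "LiftError", "track"]


class LiftError(GeometryError):
    """Origin pixel does not lie on the model silhouette."""


@dataclass(frozen=True)
class TrackedPoint:
    """Predicted positions of one surface point in every view.

    ``positions[j]`` is the predicted pixel (x, y) in view j (same
    resolution as the supplied geometry), ``visible[j]`` is True iff the
    point's z is positive there, ``points3d[j]`` the centred camera-frame
    coordinates, and ``matrices[j]`` the cumulative rotation taking the
    origin view's 3-D point to view j.
    """

    origin_view: int
    origin_xy: tuple[float, float]
    positions: np.ndarray
    visible: np.ndarray
    points3d: np.ndarray
    matrices: list


def track(
    point_xy,
    view_index: int,
    rotations,
    shape: SpheroidShape,
    poses: list[ViewPose],
    centers=None,
) -> TrackedPoint:
    """Propagate a pixel of view ``view_index`` across the whole sequence.

    Parameters
    ----------
    point_xy : (x, y) pixel position in the origin view.
    view_index : index of the origin view.
    rotations : sequence of length ``n_views - 1`` of RotationEstimate
        objects or plain 3x3 matrices; ``rotations[i]`` maps view i to
        view i+1.
    shape, poses : fitted spheroid and per-view poses (same resolution as
        ``point_xy``).
    centers : optional per-view (cx, cy); defaults to the pose centres.

    Raises
    ------
    LiftError if the origin pixel is off the model silhouette.
    """
    mats = [r.matrix if hasattr(r, "matrix") else np.asarray(r, dtype=float)
            for r in rotations]
    n_views = len(mats) + 1
    if not (0 <= view_index < n_views):
        raise IndexError(f"view_index {view_index} outside 0..{n_views - 1}")
    if centers is None:
        centers = [p.center for p in poses]
    if len(poses) != n_views or len(centers) != n_views:
        raise ValueError("poses/centers length must be n_rotations + 1")

    origin = lift_to_3d(point_xy[0], point_xy[1], shape, poses[view_index])
    if origin is None:
        raise LiftError(
            f"pixel {tuple(point_xy)} does not lift onto the spheroid in view {view_index}"
        )
    p0 = origin.as_array()

    pts = np.empty((n_views, 3))
    cum = [None] * n_views
    pts[view_index] = p0
    cum[view_index] = np.eye(3)
    for j in range(view_index + 1, n_views):
        cum[j] = mats[j - 1] @ cum[j - 1]
        pts[j] = mats[j - 1] @ pts[j - 1]
    for j in range(view_index - 1, -1, -1):
        cum[j] = mats[j].T @ cum[j + 1]
        pts[j] = mats[j].T @ pts[j + 1]

    centers_arr = np.asarray(centers, dtype=float)
    positions = pts[:, :2] + centers_arr
    visible = pts[:, 2] > 0.0
    visible[view_index] = True  # origin is visible by definition
    return TrackedPoint(
        origin_view=view_index,
        origin_xy=(float(point_xy[0]), float(point_xy[1])),
        positions=positions,
        visible=visible,
        points3d=pts,
        matrices=cum,
    )
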