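"""Spheroid geometry recovered from object silhouettes.

A quasi-spheroidal object (an orange, a tomato, a kiwi...) viewed by a
distant camera projects orthographically to an ellipse, and one principal
axis of that ellipse always equals one of the spheroid's two equal
principal axes.  This module implements the geometric half of the
rotation-estimation pipeline:

* :func:`fit_ellipse` — projected-ellipse centre and semi-axes from the
  second-order moments of a binary silhouette mask;
* :func:`fit_spheroid` — the spheroid semi-axes ``A >= B`` pooled over
  all views of one rotating object;
* :func:`elevation_angle_magnitude` / :func:`assign_elevation_signs` —
  the signed tilt of the symmetry axis in each view, the sign resolved
  from the known rotation direction of the conveyor;
* :func:`pose_matrix` — the 3x3 orthonormal pose whose rows are the
  spheroid principal axes expressed in the camera frame;
* :func:`lift_to_3d` / :func:`lift_points` — per-pixel 3-D coordinates
  on the fitted surface (the visible-hemisphere root of a quadratic).

Coordinate conventions: ``x`` is the column index increasing rightwards,
``y`` the row index increasing downwards, ``z`` points from the object
towards the camera.  A surface point is *visible* iff ``z > 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelType",
    "EllipseObservation",
    "SpheroidShape",
    "ViewPose",
    "Point3D",
    "GeometryError",
    "TooFewPixelsError",
    "DegenerateCovarianceError",
    "DegenerateShapeError",
    "fit_ellipse",
    "fit_spheroid",
    "elevation_angle_magnitude",
    "assign_elevation_signs",
    "pose_matrix",
    "quadric_matrix",
    "lift_to_3d",
    "lift_points",
]


class ModelType(str, Enum):
    """Geometric model of the object: sphere, oblate or prolate spheroid."""

    SPHERE = "sphere"
    OBLATE = "oblate"
    PROLATE = "prolate"


class GeometryError(ValueError):
    """Base class for geometry-fitting failures."""


class TooFewPixelsError(GeometryError):
    """Mask has too few foreground pixels (after striding) to fit moments."""


class DegenerateCovarianceError(GeometryError):
    """Silhouette covariance is rank deficient (lambda2 <= 0)."""


class DegenerateShapeError(GeometryError):
    """Spheroid semi-axes too close to equal for elevation recovery."""


# --------------------------------------------------------------------------
# Projected-ellipse moments
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseObservation:
    """Second-order-moment summary of one silhouette.

    For a uniformly filled ellipse the pixel-coordinate covariance
    eigenvalues relate to the semi-axes as ``a = 2 sqrt(lambda1)``,
    ``b = 2 sqrt(lambda2)`` (variance of a uniform ellipse along a
    principal direction is ``(semi-axis)^2 / 4``).

    Attributes
    ----------
    cx, cy : float
        Centroid in pixels.
    sigma_xx, sigma_yy, sigma_xy : float
        Second central moments (pixels^2).
    lambda1, lambda2 : float
        Covariance eigenvalues, ``lambda1 >= lambda2 > 0``.
    a, b : float
        Semi-major / semi-minor axis lengths in pixels.
    v1, v2 : ndarray, shape (2,)
        Unit eigenvectors for ``lambda1`` / ``lambda2``.  ``v1`` is
        sign-fixed to have a non-negative x component (ties broken by
        ``v1y >= 0``) and ``v2`` is ``v1`` rotated by +90 degrees, so the
        pose construction is reproducible.
    n_pixels : int
        Number of (strided) mask pixels used.
    """

    cx: float
    cy: float
    sigma_xx: float
    sigma_yy: float
    sigma_xy: float
    lambda1: float
    lambda2: float
    a: float
    b: float
    v1: np.ndarray
    v2: np.ndarray
    n_pixels: int

    def scaled(self, s: float) -> "EllipseObservation":
        """Return the observation rescaled by factor ``s`` (e.g. 1/4 for the
        reduced-resolution matching frame).  Lengths scale by ``s``,
        moments by ``s**2``, directions are unchanged."""
        return replace(
            self,
            cx=self.cx * s,
            cy=self.cy * s,
            sigma_xx=self.sigma_xx * s * s,
            sigma_yy=self.sigma_yy * s * s,
            sigma_xy=self.sigma_xy * s * s,
            lambda1=self.lambda1 * s * s,
            lambda2=self.lambda2 * s * s,
            a=self.a * s,
            b=self.b * s,
        )

    @property
    def orientation_deg(self) -> float:
        """Angle of the major-axis direction ``v1`` in degrees, in (-90, 90]."""
        ang = np.degrees(np.arctan2(self.v1[1], self.v1[0]))
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        return float(ang)


def fit_ellipse(mask: np.ndarray, stride: int = 4) -> EllipseObservation:
    """Fit the projected ellipse of a silhouette from pixel-coordinate moments.

    Parameters
    ----------
    mask : 2-D boolean array
        Silhouette mask (rows = y, columns = x).
    stride : int
        Subsample rows and columns every ``stride`` pixels when
        accumulating the moment sums.  A stride of 4 cuts the cost by a
        factor 16 with negligible effect on the recovered axes.

    Returns
    -------
    EllipseObservation

    Raises
    ------
    TooFewPixelsError
        If fewer than 3 foreground pixels survive the striding.
    DegenerateCovarianceError
        If the covariance is rank deficient (collinear pixels).
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    mask = mask.astype(bool, copy=False)

    sub = mask[::stride, ::stride]
    ys, xs = np.nonzero(sub)
    n = xs.size
    if n < 3:
        raise TooFewPixelsError(
            f"strided mask has {n} foreground pixels, need at least 3"
        )
    x = xs.astype(np.float64) * stride
    y = ys.astype(np.float64) * stride

    sx = x.sum()
    sy = y.sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    sxy = (x * y).sum()
    cx = sx / n
    cy = sy / n
    sigma_xx = sxx / n - cx * cx
    sigma_yy = syy / n - cy * cy
    sigma_xy = sxy / n - cx * cy

    cov = np.array([[sigma_xx, sigma_xy], [sigma_xy, sigma_yy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lambda2, lambda1 = float(evals[0]), float(evals[1])
    if lambda2 <= 0.0:
        raise DegenerateCovarianceError(
            f"covariance is degenerate (lambda2 = {lambda2:g})"
        )

    v1 = evecs[:, 1].copy()
    if v1[0] < 0.0 or (v1[0] == 0.0 and v1[1] < 0.0):
        v1 = -v1
    v2 = np.array([-v1[1], v1[0]])

    return EllipseObservation(
        cx=float(cx),
        cy=float(cy),
        sigma_xx=float(sigma_xx),
        sigma_yy=float(sigma_yy),
        sigma_xy=float(sigma_xy),
        lambda1=lambda1,
        lambda2=lambda2,
        a=2.0 * np.sqrt(lambda1),
        b=2.0 * np.sqrt(lambda2),
        v1=v1,
        v2=v2,
        n_pixels=int(n),
    )


# --------------------------------------------------------------------------
# Spheroid semi-axes from all views
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpheroidShape:
    """Fitted spheroid: ``A`` the longest semi-axis, ``B`` the shortest.

    For a sphere ``A == B``; an oblate spheroid has one short (unique)
    axis of semi-length ``B`` and two equal long axes ``A``; a prolate
    spheroid has one long unique axis ``A`` and two equal short axes
    ``B``.
    """

    model_type: ModelType
    A: float
    B: float

    def __post_init__(self):
        if not (self.A > 0.0 and self.B > 0.0):
            raise GeometryError(f"semi-axes must be positive, got A={self.A}, B={self.B}")

    def scaled(self, s: float) -> "SpheroidShape":
        return SpheroidShape(self.model_type, self.A * s, self.B * s)

    @property
    def semi_axes_body(self) -> np.ndarray:
        """Semi-axis lengths along the body axes in pose-row order
        (first row of the pose matrix is the unique axis)."""
        if self.model_type is ModelType.OBLATE:
            return np.array([self.B, self.A, self.A])
        if self.model_type is ModelType.PROLATE:
            return np.array([self.A, self.B, self.B])
        return np.array([self.A, self.A, self.A])


def fit_spheroid(
    observations: list[EllipseObservation] | tuple[EllipseObservation, ...],
    model_type: ModelType | str,
    *,
    atol: float = 1e-6,
) -> SpheroidShape:
    """Pool per-view ellipse axes into the spheroid semi-axes ``A >= B``.

    sphere
        ``A = B =`` mean over views of ``(a_i + b_i)/2``.
    oblate
        The equal (long) axes are visible in every view, so
        ``A = mean(a_i)``; the unique short axis is only seen edge-on, so
        ``B = min(b_i)``.
    prolate
        Mirror situation: ``A = max(a_i)``, ``B = mean(b_i)``.

    The model type comes from configuration; it is not auto-detected.
    """
    if len(observations) == 0:
        raise GeometryError("need at least one ellipse observation")
    model_type = ModelType(model_type)
    a = np.array([o.a for o in observations])
    b = np.array([o.b for o in observations])
    if model_type is ModelType.SPHERE:
        r = float(np.mean((a + b) / 2.0))
        return SpheroidShape(model_type, r, r)
    if model_type is ModelType.OBLATE:
        A, B = float(np.mean(a)), float(np.min(b))
    else:  # prolate
        A, B = float(np.max(a)), float(np.mean(b))
    if A - B < atol:
        warnings.warn(
            f"{model_type.value} fit yields A - B = {A - B:.3g}; "
            "the object is effectively spherical",
            stacklevel=2,
        )
    return SpheroidShape(model_type, A, B)


# --------------------------------------------------------------------------
# Elevation angle
# --------------------------------------------------------------------------


def elevation_angle_magnitude(
    b: float,
    shape: SpheroidShape,
    *,
    clamp_warn: float = 0.05,
) -> float:
    """Unsigned elevation angle from one view's observed varying semi-axis.

    The projected varying semi-axis satisfies
    ``b^2 = A^2 cos^2(theta) + B^2 sin^2(theta)``, hence
    ``cos(theta) = sqrt((b^2 - B^2) / (A^2 - B^2))``.  For an oblate model
    the varying axis is the per-view semi-minor axis; for a prolate model
    it is the semi-major axis (the equal axes then fix ``b_i ~ B``).

    Measurement noise can push the observed axis slightly outside
    ``[B, A]``; the ratio is clamped to [0, 1] and a warning is logged
    when the clamp moves it by more than ``clamp_warn``.
    """
    if shape.model_type is ModelType.SPHERE:
        raise DegenerateShapeError("elevation angle is undefined for a sphere")
    if shape.A - shape.B < 1e-9 * max(shape.A, 1.0):
        raise DegenerateShapeError(
            f"A - B = {shape.A - shape.B:.3g} too small to resolve elevation"
        )
    ratio = (b * b - shape.B * shape.B) / (shape.A * shape.A - shape.B * shape.B)
    clamped = min(max(ratio, 0.0), 1.0)
    if abs(clamped - ratio) > clamp_warn:
        logger.warning(
            "elevation ratio clamped from %.3f to %.1f (observed axis %.2f "
            "outside [B=%.2f, A=%.2f])",
            ratio, clamped, b, shape.B, shape.A,
        )
    return float(np.arccos(np.sqrt(clamped)))


def assign_elevation_signs(
    b_sequence,
    magnitudes,
    rotation_direction: str = "down",
) -> np.ndarray:
    """Resolve the sign of each view's elevation angle from the rotation sense.

    The magnitude of theta leaves a two-fold ambiguity per view.  With the
    object rotating in a known direction the monotonicity of the
    varying-axis sequence ``{b_i}`` resolves it: for a downward-rotating
    object, ``b`` locally increasing implies ``theta > 0`` and decreasing
    implies ``theta < 0`` (flipped for upward rotation).  At local extrema
    of ``{b_i}`` (theta near 0 or near +-pi/2) the sign is chosen to make
    the theta sequence smoothest, i.e. the candidate among ``{+|theta|,
    -|theta|}`` closest to the mean of the already-signed neighbours.
    Endpoints use their single neighbouring pair.

    Parameters
    ----------
    b_sequence : sequence of float
        Observed varying semi-axis per view.
    magnitudes : sequence of float
        Unsigned elevation angles (radians) per view.
    rotation_direction : {"down", "up"}
        Rotation sense of the object as seen by the camera.

    Returns
    -------
    ndarray of signed elevation angles (radians), same length as input.
    """
    b = np.asarray(b_sequence, dtype=float)
    m = np.asarray(magnitudes, dtype=float)
    if b.shape != m.shape or b.ndim != 1:
        raise ValueError("b_sequence and magnitudes must be 1-D of equal length")
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 views to resolve elevation signs")
    direction = rotation_direction.lower()
    if direction in ("down", "downwards"):
        flip = 1.0
    elif direction in ("up", "upwards"):
        flip = -1.0
    else:
        raise ValueError(f"unknown rotation direction {rotation_direction!r}")

    signs = np.zeros(n)
    decided = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        if b[i - 1] < b[i] < b[i + 1]:
            signs[i], decided[i] = flip, True
        elif b[i - 1] > b[i] > b[i + 1]:
            signs[i], decided[i] = -flip, True
    # endpoints inherit the monotonicity of their single neighbour pair
    if b[0] < b[1]:
        signs[0], decided[0] = flip, True
    elif b[0] > b[1]:
        signs[0], decided[0] = -flip, True
    if b[-2] < b[-1]:
        signs[-1], decided[-1] = flip, True
    elif b[-2] > b[-1]:
        signs[-1], decided[-1] = -flip, True

    # extrema: pick the smoother branch against signed neighbours
    changed = True
    while changed and not decided.all():
        changed = False
        for i in np.flatnonzero(~decided):
            refs = [signs[j] * m[j] for j in (i - 1, i + 1) if 0 <= j < n and decided[j]]
            if not refs:
                continue
            ref = float(np.mean(refs))
            signs[i] = 1.0 if abs(m[i] - ref) <= abs(-m[i] - ref) else -1.0
            decided[i] = True
            changed = True
    signs[~decided] = flip  # flat sequence: no information, default
    return signs * m


# --------------------------------------------------------------------------
# Pose and lifting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewPose:
    """Per-view orientation of the spheroid.

    ``P`` is orthonormal with det +1; its rows are the spheroid principal
    axes expressed in the camera frame, the unique axis first.  For a
    sphere the pose is the identity by convention (any orthonormal P is
    equivalent under rotational symmetry).
    """

    theta: float
    P: np.ndarray
    center: tuple[float, float]

    def scaled(self, s: float) -> "ViewPose":
        """Same orientation with the centre rescaled (e.g. to the reduced
        matching frame).  ``P`` and ``theta`` are dimensionless."""
        return ViewPose(self.theta, self.P, (self.center[0] * s, self.center[1] * s))


@dataclass(frozen=True)
class Point3D:
    """Camera-frame coordinates centred on the object centroid (pixels);
    ``z > 0`` lies on the visible hemisphere."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _pose_rows(v1: np.ndarray, v2: np.ndarray, theta: float,
               model_type: ModelType) -> np.ndarray:
    """Rows of the pose matrix for a non-spherical model.

    Oblate: the unique (short) axis projects along v2, so the first row is
    ``(v2x sin t, v2y sin t, cos t)``; the second axis lies in the image
    plane along v1.  Prolate mirrors the construction: the unique (long)
    axis projects along v1, first row ``(v1x cos t, v1y cos t, sin t)``,
    with the in-plane equal axis along v2.  The third row is the cross
    product of the first two, making det(P) = +1.
    """
    st, ct = np.sin(theta), np.cos(theta)
    if model_type is ModelType.OBLATE:
        r1 = np.array([v2[0] * st, v2[1] * st, ct])
        r2 = np.array([v1[0], v1[1], 0.0])
    elif model_type is ModelType.PROLATE:
        r1 = np.array([v1[0] * ct, v1[1] * ct, st])
        r2 = np.array([v2[0], v2[1], 0.0])
    else:  # pragma: no cover - callers special-case the sphere
        return np.eye(3)
    r3 = np.cross(r1, r2)
    return np.vstack([r1, r2, r3])


def pose_matrix(
    obs: EllipseObservation,
    theta: float,
    model_type: ModelType | str,
) -> ViewPose:
    """Build the per-view pose from the ellipse eigenvectors and the signed
    elevation angle.  For the sphere model returns the identity pose with
    ``theta = 0``."""
    model_type = ModelType(model_type)
    if model_type is ModelType.SPHERE:
        return ViewPose(0.0, np.eye(3), (obs.cx, obs.cy))
    P = _pose_rows(obs.v1, obs.v2, theta, model_type)
    return ViewPose(float(theta), P, (obs.cx, obs.cy))


def quadric_matrix(shape: SpheroidShape, pose: ViewPose) -> np.ndarray:
    """Camera-frame quadric matrix ``A = P^T D P`` of the posed spheroid,
    with D the diagonal of inverse squared semi-axes in body order
    (unique axis first).  Surface points satisfy ``x^T A x = 1``."""
    s = shape.semi_axes_body
    D = np.diag(1.0 / s**2)
    return pose.P.T @ D @ pose.P


def _solve_surface_z(amat: np.ndarray, xp, yp):
    """Visible-hemisphere root of the surface quadratic in z.

    For centred coordinates (x', y') the quadric gives
    ``a33 z^2 + 2 (a13 x' + a23 y') z + (a11 x'^2 + 2 a12 x' y' + a22 y'^2 - 1) = 0``;
    the larger root is the surface point facing the camera.  Returns
    ``(z, valid)`` where ``valid`` is False for pixels off the model
    silhouette (negative discriminant).
    """
    xp = np.asarray(xp, dtype=float)
    yp = np.asarray(yp, dtype=float)
    a = amat[2, 2]
    bq = 2.0 * (amat[0, 2] * xp + amat[1, 2] * yp)
    c = amat[0, 0] * xp * xp + 2.0 * amat[0, 1] * xp * yp + amat[1, 1] * yp * yp - 1.0
    disc = bq * bq - 4.0 * a * c
    valid = disc >= 0.0
    z = (-bq + np.sqrt(np.where(valid, disc, 0.0))) / (2.0 * a)
    return z, valid


def lift_to_3d(
    x: float,
    y: float,
    shape: SpheroidShape,
    pose: ViewPose,
) -> Point3D | None:
    """Lift an image pixel to a 3-D point on the fitted spheroid surface.

    Coordinates are centred on the view's ellipse centre.  For a sphere
    this is ``z = sqrt(A^2 - x'^2 - y'^2)`` directly; otherwise the
    larger root of the posed-quadric equation in ``z``.  Returns ``None``
    when the pixel lies outside the model silhouette.
    """
    xp = float(x) - pose.center[0]
    yp = float(y) - pose.center[1]
    if shape.model_type is ModelType.SPHERE:
        zsq = shape.A * shape.A - xp * xp - yp * yp
        if zsq < 0.0:
            return None
        return Point3D(xp, yp, float(np.sqrt(zsq)))
    amat = quadric_matrix(shape, pose)
    z, valid = _solve_surface_z(amat, xp, yp)
    if not valid:
        return None
    return Point3D(xp, yp, float(z))


def lift_points(xy: np.ndarray, shape: SpheroidShape, pose: ViewPose):
    """Vectorised lift of ``(N, 2)`` pixel coordinates.

    Returns ``(points, valid)`` where ``points`` is ``(N, 3)`` centred
    camera-frame coordinates (rows with ``valid == False`` are
    meaningless) — the workhorse behind relevant-point lifting and the
    synthetic renderer.
    """
    xy = np.asarray(xy, dtype=float)
    xp = xy[:, 0] - pose.center[0]
    yp = xy[:, 1] - pose.center[1]
    amat = quadric_matrix(shape, pose)
    z, valid = _solve_surface_z(amat, xp, yp)
    return np.column_stack([xp, yp, z]), valid
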