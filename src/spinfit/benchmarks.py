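"""Synthetic validation experiments for the whole pipeline.

Each function here sets up a seeded ground-truthed experiment on
synthetic data (rasterized ellipses or rendered rotating spheroids),
runs the relevant part of the pipeline, and returns a dictionary of
scalar quality metrics.  They are used both by the test suite and by
``scripts/acceptance.py``; the experiment sizes follow the operating
conditions the method is designed for (object diameters of a few
hundred pixels, rotations of 10-30 degrees per transition).
"""

from __future__ import annotations

import numpy as np

from . import geometry
from .geometry import (
    ModelType,
    SpheroidShape,
    ViewPose,
    _pose_rows,
    elevation_angle_magnitude,
    fit_ellipse,
    lift_to_3d,
    quadric_matrix,
)
from .model import SpheroidRotationModel
from .rotation import SearchGrid, _parabola_vertex, rodrigues
from .synthetic import SyntheticConfig, rasterize_ellipse, render_sequence

__all__ = [
    "ellipse_recovery",
    "elevation_round_trip",
    "lifting_cross_check",
    "grid_reference_check",
    "rotation_recovery",
    "constant_speed",
    "closure_experiment",
    "parabola_refinement_check",
    "reference_error_map",
]


def _angle_diff_deg(x: float, y: float) -> float:
    """Absolute difference of two axial directions in degrees, modulo 180."""
    return abs((x - y + 90.0) % 180.0 - 90.0)


def ellipse_recovery(seed: int, n_ellipses: int = 50) -> dict:
    """Moment-based ellipse fitting on rasterized ground-truth ellipses.

    Draws ``n_ellipses`` filled ellipses with semi-axes 20-150 px (axis
    ratio at least 1.1 so the orientation is well defined) at random
    orientations and sub-pixel centre offsets, and measures worst-case
    recovery of the semi-axes and orientation at stride 1 plus the
    worst-case stride-4 vs stride-1 semi-axis discrepancy.  The stride
    discrepancy is also measured on a fruit-scale ensemble (semi-axes
    125-175 px, the diameters typical of inspection imagery) where the
    strided lattice is dense relative to the shape.
    """
    rng = np.random.default_rng(seed)
    axis_err = orient_err = stride_diff = 0.0
    for _ in range(n_ellipses):
        a, b = rng.uniform(20.0, 150.0, size=2)
        if max(a, b) / min(a, b) < 1.1:
            b = a / 1.2
        a, b = float(max(a, b)), float(min(a, b))
        phi = float(rng.uniform(0.0, 180.0))
        h = w = int(2 * a + 20)
        cx = w / 2 + rng.uniform(-2, 2)
        cy = h / 2 + rng.uniform(-2, 2)
        mask = rasterize_ellipse(a, b, phi, cx, cy, (h, w))
        e1 = fit_ellipse(mask, stride=1)
        e4 = fit_ellipse(mask, stride=4)
        axis_err = max(axis_err, abs(e1.a - a) / a * 100, abs(e1.b - b) / b * 100)
        orient_err = max(orient_err, _angle_diff_deg(e1.orientation_deg, phi))
        stride_diff = max(
            stride_diff, abs(e4.a - e1.a) / e1.a * 100, abs(e4.b - e1.b) / e1.b * 100
        )

    fruit_stride = 0.0
    for _ in range(20):
        a, b = rng.uniform(125.0, 175.0, size=2)
        a, b = float(max(a, b)), float(min(a, b))
        phi = float(rng.uniform(0.0, 180.0))
        h = w = int(2 * a + 20)
        mask = rasterize_ellipse(a, b, phi, w / 2 + rng.uniform(-2, 2),
                                 h / 2 + rng.uniform(-2, 2), (h, w))
        e1 = fit_ellipse(mask, stride=1)
        e4 = fit_ellipse(mask, stride=4)
        fruit_stride = max(
            fruit_stride, abs(e4.a - e1.a) / e1.a * 100, abs(e4.b - e1.b) / e1.b * 100
        )
    return {
        "axis_err_pct_max": axis_err,
        "orientation_err_deg_max": orient_err,
        "stride_diff_pct_max": stride_diff,
        "stride_diff_pct_max_fruit_scale": fruit_stride,
        "n": n_ellipses,
    }


def elevation_round_trip(seed: int, angles_deg=(15.0, 30.0, 45.0, 60.0, 75.0),
                         A: float = 120.0, B: float = 70.0) -> dict:
    """Render an oblate spheroid at known elevations, measure the projected
    minor axis from the silhouette moments, invert the axis/elevation
    relation with the true semi-axes, and compare to the ground truth."""
    shape = SpheroidShape(ModelType.OBLATE, A, B)
    size = int(2 * A + 40)
    worst = 0.0
    for i, theta in enumerate(angles_deg):
        cfg = SyntheticConfig(
            model_type="oblate", A=A, B=B, image_size=(size, size), n_views=1,
            initial_elevation_deg=float(theta), seed=seed + i,
        )
        seq = render_sequence(cfg)
        obs = fit_ellipse(seq.masks[0], stride=1)
        theta_hat = np.degrees(elevation_angle_magnitude(obs.b, shape))
        worst = max(worst, abs(theta_hat - theta))
    return {"elevation_err_deg_max": worst, "n": len(angles_deg)}


def _random_pose(rng: np.random.Generator, model_type: ModelType):
    psi = rng.uniform(0.0, np.pi)
    v1 = np.array([np.cos(psi), np.sin(psi)])
    v2 = np.array([-v1[1], v1[0]])
    theta = rng.uniform(-np.pi / 2, np.pi / 2)
    if model_type is ModelType.SPHERE:
        return ViewPose(0.0, np.eye(3), (0.0, 0.0))
    return ViewPose(theta, _pose_rows(v1, v2, theta, model_type), (0.0, 0.0))


def lifting_cross_check(seed: int, n_instances: int = 100,
                        scan_step: float = 1e-4) -> dict:
    """Closed-form pixel lifting vs a brute-force root scan.

    For randomized (shape, pose, pixel) instances the closed-form larger
    quadratic root is compared against a dense scan of the surface
    quadratic over z in [-A, A] (sign-change bracketing at ``scan_step``
    resolution, linearly interpolated).  Also verifies that every lifted
    point satisfies the quadric equation.
    """
    rng = np.random.default_rng(seed)
    max_diff = max_resid = 0.0
    models = [ModelType.SPHERE, ModelType.OBLATE, ModelType.PROLATE]
    for i in range(n_instances):
        model = models[i % 3]
        A = float(rng.uniform(40.0, 100.0))
        B = A if model is ModelType.SPHERE else A * float(rng.uniform(0.55, 0.9))
        shape = SpheroidShape(model, A, B)
        pose = _random_pose(rng, model)
        r = 0.9 * B * np.sqrt(rng.uniform(0.0, 1.0))
        ang = rng.uniform(0.0, 2 * np.pi)
        x, y = r * np.cos(ang), r * np.sin(ang)  # always inside the silhouette
        pt = lift_to_3d(x, y, shape, pose)
        assert pt is not None

        amat = quadric_matrix(shape, pose)
        a33 = amat[2, 2]
        bq = 2.0 * (amat[0, 2] * x + amat[1, 2] * y)
        c = amat[0, 0] * x * x + 2.0 * amat[0, 1] * x * y + amat[1, 1] * y * y - 1.0
        zs = np.arange(-A, A + scan_step, scan_step)
        q = a33 * zs * zs + bq * zs + c
        crossings = np.flatnonzero(q[:-1] * q[1:] <= 0.0)
        k = crossings[-1]  # largest root
        z0, z1, q0, q1 = zs[k], zs[k + 1], q[k], q[k + 1]
        z_scan = z0 if q0 == q1 else z0 + (z1 - z0) * (-q0) / (q1 - q0)
        max_diff = max(max_diff, abs(pt.z - z_scan))

        p = pt.as_array()
        max_resid = max(max_resid, abs(p @ amat @ p - 1.0))
    return {
        "scan_diff_px_max": max_diff,
        "quadric_residual_max": max_resid,
        "n": n_instances,
    }


# --------------------------------------------------------------------------
# Grid-search reference implementation
# --------------------------------------------------------------------------


def reference_error_map(src_values, pts3d, tgt_grid, tgt_center, grid: SearchGrid):
    """Naive per-node, per-point evaluation of the error map.

    Pure-Python double loop over grid nodes and points, written with the
    same elementary float operations as the production path so the two
    must agree bit for bit.  Returns ``(values, argmin_index)`` with the
    first-in-row-major tie rule.
    """
    h, w = tgt_grid.shape
    rxs, rys = grid.rx_values_deg, grid.ry_values_deg
    values = np.full((rxs.size, rys.size), np.nan)
    best = None
    best_val = np.inf
    for i, rx in enumerate(rxs):
        for j, ry in enumerate(rys):
            R = rodrigues(np.radians([rx, ry, 0.0]))
            diffs = []
            for k in range(len(src_values)):
                x, y, z = pts3d[k, 0], pts3d[k, 1], pts3d[k, 2]
                xt = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
                yt = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
                zt = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z
                if zt < 0.0:
                    continue
                col = int(np.rint(xt + tgt_center[0]))
                row = int(np.rint(yt + tgt_center[1]))
                if 0 <= col < w and 0 <= row < h:
                    diffs.append(abs(src_values[k] - tgt_grid[row, col]))
            if diffs:
                eps = float(np.sum(np.asarray(diffs)) / len(diffs))
                values[i, j] = eps
                if eps < best_val:
                    best_val, best = eps, (i, j)
    return values, best


def grid_reference_check(seed: int, n_instances: int = 10) -> dict:
    """Exact agreement of the vectorised error-map evaluation with the
    naive reference on rendered sphere pairs (values and argmin,
    including tie behaviour)."""
    rng = np.random.default_rng(seed)
    agree = 0
    max_eps_diff = 0.0
    for _ in range(n_instances):
        A = float(rng.uniform(55.0, 75.0))
        cfg = SyntheticConfig(
            model_type="sphere", A=A, B=A,
            image_size=(int(2 * A + 20), int(2 * A + 20)), n_views=2,
            rotation_deg=(float(rng.uniform(10, 30)), float(rng.uniform(-5, 5))),
            seed=int(rng.integers(2**31)),
        )
        seq = render_sequence(cfg)
        res = SpheroidRotationModel.from_synthetic(seq).fit()
        est = res.rotations[0]
        emap = est.error_map

        pts = res.relevant_points[0].points
        src_img = res.working_images[0]
        src_values = src_img.grid[pts[:, 1], pts[:, 0]]
        red = 1.0 / res.config.factor
        pts3d, _ = geometry.lift_points(
            pts, res.shape.scaled(red), res.poses[0].scaled(red)
        )
        ref_values, ref_argmin = reference_error_map(
            src_values, pts3d, res.working_images[1].grid,
            res.working_images[1].center, res.config.grid,
        )

        same_nan = np.array_equal(np.isnan(ref_values), np.isnan(emap.values))
        same_vals = np.array_equal(
            np.nan_to_num(ref_values, nan=-1.0), np.nan_to_num(emap.values, nan=-1.0)
        )
        masked = np.where(np.isnan(emap.values), np.inf, emap.values)
        impl_argmin = tuple(np.unravel_index(int(np.argmin(masked)), masked.shape))
        if same_nan and same_vals and impl_argmin == ref_argmin:
            agree += 1
        finite = ~np.isnan(ref_values)
        if finite.any():
            max_eps_diff = max(
                max_eps_diff,
                float(np.max(np.abs(ref_values[finite] - emap.values[finite]))),
            )
    return {
        "agreement_frac": agree / n_instances,
        "eps_max_abs_diff": max_eps_diff,
        "n": n_instances,
    }


# --------------------------------------------------------------------------
# End-to-end rotation recovery
# --------------------------------------------------------------------------


def rotation_recovery(seed: int, n_pairs: int = 20) -> dict:
    """Recovery of known inter-view rotations on rendered sequences.

    Alternates sphere and oblate objects with true rx uniform in
    [10, 30] degrees and ry in [-5, 5].  Sphere instances are plain
    2-view pairs.  Oblate instances evaluate the first transition of a
    longer constant-rotation sequence: the spheroid fit pools all views
    and needs at least one near-edge-on view to expose the short axis,
    so the sequence length is chosen to sweep the elevation past 90
    degrees (mirroring the 13-16-view sequences of real machines).
    Initial elevations are drawn from [35, 55] degrees so a transition
    never straddles elevation zero, which a short sequence cannot
    disambiguate.
    """
    rng = np.random.default_rng(seed)
    rx_err, ry_err, coarse_err, refine_off = [], [], [], []
    for k in range(n_pairs):
        rx_t = float(rng.uniform(10.0, 30.0))
        ry_t = float(rng.uniform(-5.0, 5.0))
        inst_seed = int(rng.integers(2**31))
        if k % 2 == 0:
            A = float(rng.uniform(130.0, 170.0))
            size = int(2 * A + 30)
            cfg = SyntheticConfig(
                model_type="sphere", A=A, B=A, image_size=(size, size),
                n_views=2, rotation_deg=(rx_t, ry_t), seed=inst_seed,
            )
        else:
            A = float(rng.uniform(130.0, 160.0))
            B = A * float(rng.uniform(0.58, 0.72))
            theta0 = float(rng.uniform(35.0, 55.0))
            n_views = int(np.ceil((theta0 + 95.0) / rx_t)) + 1
            size = int(2 * A + 30)
            cfg = SyntheticConfig(
                model_type="oblate", A=A, B=B, image_size=(size, size),
                n_views=n_views, rotation_deg=(rx_t, ry_t),
                initial_elevation_deg=theta0, seed=inst_seed,
            )
        seq = render_sequence(cfg)
        res = SpheroidRotationModel.from_synthetic(seq).fit()
        est = res.rotations[0]
        truth = seq.rotations_deg[0]
        rx_err.append(abs(est.rx_deg - truth[0]))
        ry_err.append(abs(est.ry_deg - truth[1]))
        coarse = np.degrees(est.coarse_vector)
        coarse_err.append(max(abs(coarse[0] - truth[0]), abs(coarse[1] - truth[1])))
        off = np.degrees(np.abs(est.vector - est.subgrid_vector))
        refine_off.append(float(off.max()))
    return {
        "rx_median_err_deg": float(np.median(rx_err)),
        "ry_median_err_deg": float(np.median(ry_err)),
        "coarse_max_err_deg": float(np.max(coarse_err)),
        "refine_offset_max_deg": float(np.max(refine_off)),
        "n": n_pairs,
    }


def constant_speed(seed: int, n_views: int = 15, step_deg: float = 18.0,
                   slip_sigma_deg: float = 2.0) -> dict:
    """Constant-rotation-speed consistency.

    A sequence rotated at exactly ``step_deg`` per transition should
    produce estimated magnitudes with small scatter and no trend; with
    slip jitter the estimates should track the jittered truth
    per transition.
    """
    A = 150.0
    size = int(2 * A + 30)
    cfg = SyntheticConfig(model_type="sphere", A=A, B=A, image_size=(size, size),
                          n_views=n_views, rotation_deg=(step_deg, 0.0), seed=seed)
    res = SpheroidRotationModel.from_synthetic(render_sequence(cfg)).fit()
    mags = res.rotation_magnitudes_deg
    trend = float(np.polyfit(np.arange(mags.size), mags, 1)[0])

    cfg_j = SyntheticConfig(model_type="sphere", A=A, B=A, image_size=(size, size),
                            n_views=n_views, rotation_deg=(step_deg, 0.0),
                            slip_sigma_deg=slip_sigma_deg, seed=seed + 1)
    seq_j = render_sequence(cfg_j)
    res_j = SpheroidRotationModel.from_synthetic(seq_j).fit()
    true_mags = np.linalg.norm(seq_j.rotations_deg[:, :2], axis=1)
    slip_err = float(np.max(np.abs(res_j.rotation_magnitudes_deg - true_mags)))
    return {
        "magnitude_std_deg": float(np.std(mags)),
        "magnitude_trend_deg_per_transition": trend,
        "slip_tracking_max_err_deg": slip_err,
        "n": int(mags.size),
    }


def closure_experiment(seed: int, n_steps: int = 20, step_deg: float = 18.0) -> dict:
    """Full-revolution tracking closure.

    Renders ``n_steps`` x ``step_deg`` = 360 degrees of rotation, runs
    the full pipeline, and tracks the centre pixel of the first view
    through the estimated rotations.  The point should disappear behind
    the object for about half the revolution and return to its origin in
    the final view; forward-then-backward propagation through the same
    matrices must be an exact identity.
    """
    A = 150.0
    size = int(2 * A + 30)
    cfg = SyntheticConfig(model_type="sphere", A=A, B=A, image_size=(size, size),
                          n_views=n_steps + 1, rotation_deg=(step_deg, 0.0), seed=seed)
    res = SpheroidRotationModel.from_synthetic(render_sequence(cfg)).fit()
    origin = res.poses[0].center
    tracked = res.track(origin, view=0)
    closure = float(np.linalg.norm(tracked.positions[-1] - tracked.positions[0]))
    occluded = int((~tracked.visible).sum())

    p0 = tracked.points3d[0]
    p = p0.copy()
    for r in res.rotations:
        p = r.matrix @ p
    for r in reversed(res.rotations):
        p = r.matrix.T @ p
    backforth = float(np.linalg.norm(p - p0))
    return {
        "closure_err_px": closure,
        "occluded_views": occluded,
        "occluded_frac": occluded / (n_steps + 1),
        "backforth_err": backforth,
        "n": n_steps + 1,
    }


def parabola_refinement_check(seed: int, n_trials: int = 200) -> dict:
    """The three-point parabola vertex must reproduce the exact minimum of
    any sampled quadratic to machine precision (offsets within the
    half-step by construction)."""
    rng = np.random.default_rng(seed)
    h = 0.5
    worst = 0.0
    for _ in range(n_trials):
        u0 = float(rng.uniform(-h, h))
        a = float(rng.uniform(0.1, 5.0))
        c = float(rng.uniform(0.0, 10.0))
        f = lambda u: a * (u - u0) ** 2 + c
        off, val = _parabola_vertex(f(-h), f(0.0), f(h), h)
        worst = max(worst, abs(off - u0), abs(val - c))
    return {"vertex_err_max": worst, "n": n_trials}
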