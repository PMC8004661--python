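"""Shared test helpers."""

import numpy as np

from spinfit.geometry import EllipseObservation


def make_observation(a, b, v1=(1.0, 0.0), cx=0.0, cy=0.0):
    """Minimal ellipse observation with consistent moments, for tests that
    exercise shape pooling, pose construction and point selection."""
    v1 = np.asarray(v1, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    return EllipseObservation(
        cx=float(cx), cy=float(cy),
        sigma_xx=a * a / 4, sigma_yy=b * b / 4, sigma_xy=0.0,
        lambda1=a * a / 4, lambda2=b * b / 4, a=float(a), b=float(b),
        v1=v1, v2=np.array([-v1[1], v1[0]]), n_pixels=1000,
    )
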