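"""Analytic potential of point current electrodes on a homogeneous
conducting sphere.

For a current I injected at a point on the surface of an insulated,
homogeneous sphere of radius R and conductivity sigma, the interior
potential admits the Legendre series

    V(r, gamma) = I / (4 pi sigma R) * sum_{n>=1} (2n+1)/n (r/R)^n P_n(cos gamma)

with gamma the angle between the observation point and the injection
point.  A source/sink pair superposes two such series.  This closed-form
solution serves as the independent reference for validating the FEM pair
solve; it is written and tested against basic physics (superposition,
1/sigma scaling) independently of the solver.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

from .errors import ValidationError


def point_source_potential(
    points: np.ndarray,
    source_dir: np.ndarray,
    radius: float,
    sigma: float,
    current: float = 1.0,
    n_terms: int = 200,
) -> np.ndarray:
    """Potential at interior ``points`` (same length unit as ``radius``)
    for ``current`` (A) injected at the surface point ``radius *
    source_dir``; ``sigma`` in S/(length unit).  Converges for r < R; keep
    observation points a few percent inside the surface.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = np.asarray(source_dir, dtype=float)
    u = u / np.linalg.norm(u)
    r = np.linalg.norm(pts, axis=1)
    if np.any(r >= radius):
        raise ValidationError("series valid strictly inside the sphere")
    with np.errstate(invalid="ignore"):
        cosg = np.where(r > 0, (pts @ u) / np.where(r > 0, r, 1.0), 1.0)
    cosg = np.clip(cosg, -1.0, 1.0)
    x = r / radius
    n = np.arange(1, n_terms + 1)
    # terms: (2n+1)/n * x^n * P_n(cos gamma)
    xn = x[:, None] ** n[None, :]
    pn = eval_legendre(n[None, :], cosg[:, None])
    series = ((2 * n + 1) / n)[None, :] * xn * pn
    return current / (4.0 * np.pi * sigma * radius) * series.sum(axis=1)


def pair_potential(
    points: np.ndarray,
    source_dir: np.ndarray,
    sink_dir: np.ndarray,
    radius: float,
    sigma: float,
    current: float = 1.0,
    n_terms: int = 200,
) -> np.ndarray:
    """Superposed potential of a surface source/sink pair carrying
    ``current`` (defined up to an additive constant)."""
    return point_source_potential(
        points, source_dir, radius, sigma, current, n_terms
    ) - point_source_potential(points, sink_dir, radius, sigma, current, n_terms)
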