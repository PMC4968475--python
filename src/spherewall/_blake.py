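"""Stokeslet and wall (image-system) Green's functions.

The no-slip lower wall at y = 0 is represented exactly through the
classical image system for a point force above a plane: the image
Stokeslet, a potential dipole and a Stokeslet doublet placed at the
mirror point.  With this kernel the velocity vanishes identically on
the wall, so only the sphere surface needs to be discretized.

Conventions: a point force F at x0 (with y0 > 0) induces

    u_i(x) = (1 / (8 pi mu)) * G_ij(x, x0) F_j
    p(x)   = (1 / (8 pi))    * P_j(x, x0) F_j

``oseen_core``/``image_core`` operate on precomputed difference vectors
with arbitrary leading shape; the ``stokeslet``/``wall_image`` wrappers
produce dense (n_targets, n_sources, 3, 3) blocks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "oseen_core",
    "image_core",
    "stokeslet",
    "wall_image",
    "wall_green",
    "pressure_vector_wall",
]

#: sign of the mirror operator per component (parallel, normal, parallel)
_BETA = np.array([1.0, -1.0, 1.0])
_MIRROR = np.array([1.0, -1.0, 1.0])


def oseen_core(r: np.ndarray) -> np.ndarray:
    """Free-space Oseen tensor delta_ij/r + r_i r_j/r^3 for difference
    vectors ``r`` of shape (..., 3); zero vectors map to zero blocks."""
    d = np.linalg.norm(r, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    inv3 = inv ** 3
    G = np.einsum("...i,...j->...ij", r, r) * inv3[..., None, None]
    G += np.eye(3) * inv[..., None, None]
    return G


def image_core(R: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Image-system blocks G^W - G^S.

    ``R = x - mirror(x0)`` with shape (..., 3); ``h`` the source heights
    (broadcastable to the leading shape).  Regular for targets in the
    upper half space.
    """
    R = np.asarray(R, dtype=float)
    h = np.asarray(h, dtype=float)
    d = np.linalg.norm(R, axis=-1)
    inv = 1.0 / d
    inv3 = inv ** 3
    inv5 = inv ** 5

    RR = np.einsum("...i,...j->...ij", R, R)
    # image Stokeslet
    G = -(RR * inv3[..., None, None] + np.eye(3) * inv[..., None, None])

    # potential dipole: +2 h^2 beta_j d/dR_j (R_i / R^3)
    dip = np.eye(3) * inv3[..., None, None] - 3.0 * RR * inv5[..., None, None]
    G += 2.0 * (h ** 2)[..., None, None] * _BETA * dip

    # Stokeslet doublet: -2 h beta_j d/dR_j S_iy(R)
    Ry = R[..., 1]
    sd = np.zeros_like(dip)
    sd[..., 1, :] += -R * inv3[..., None]
    sd += np.eye(3) * (Ry * inv3)[..., None, None]
    sd[..., :, 1] += R * inv3[..., None]
    sd -= 3.0 * RR * (Ry * inv5)[..., None, None]
    G += -2.0 * h[..., None, None] * _BETA * sd
    return G


def stokeslet(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Free-space Oseen blocks, shape (n, m, 3, 3)."""
    x = np.atleast_2d(x)
    x0 = np.atleast_2d(x0)
    return oseen_core(x[:, None, :] - x0[None, :, :])


def wall_image(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Image correction blocks, shape (n, m, 3, 3)."""
    x = np.atleast_2d(x)
    x0 = np.atleast_2d(x0)
    R = x[:, None, :] - (x0 * _MIRROR)[None, :, :]
    return image_core(R, np.broadcast_to(x0[:, 1], (x.shape[0], x0.shape[0])))


def wall_green(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Full wall-bounded Green's function blocks (vanishes at y = 0)."""
    return stokeslet(x, x0) + wall_image(x, x0)


def pressure_vector_wall(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Pressure vector P_j(x, x0) of the wall-bounded Stokeslet, (n, m, 3).

    The potential-dipole image carries no pressure; the image Stokeslet
    and the Stokeslet doublet do.
    """
    x = np.atleast_2d(x)
    x0 = np.atleast_2d(x0)
    r = x[:, None, :] - x0[None, :, :]
    dr = np.linalg.norm(r, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv3r = np.where(dr > 0, dr ** -3, 0.0)
    P = 2.0 * r * inv3r[..., None]

    h = x0[:, 1]
    R = x[:, None, :] - (x0 * _MIRROR)[None, :, :]
    d = np.linalg.norm(R, axis=-1)
    inv3 = d ** -3
    inv5 = d ** -5
    P -= 2.0 * R * inv3[..., None]
    # doublet pressure: -2 h beta_j d/dR_j (2 R_y / R^3)
    Ry = R[..., 1]
    grad = -3.0 * R * (Ry * inv5)[..., None]
    grad[..., 1] += inv3
    P += -2.0 * h[None, :, None] * _BETA[None, None, :] * 2.0 * grad
    return P
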