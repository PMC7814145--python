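"""Feedback (penalty) immersed-boundary exchange on a lattice block.

Markers form a closed polygon on the body surface.  The no-slip condition is
imposed by a penalty force proportional to the velocity mismatch between the
boundary and the kernel-interpolated fluid velocity; the force is spread back
with the same 4-point cosine kernel, which is an exact partition of unity on
the lattice (so spreading conserves the total force to round-off).

Surface loads are available through two routes: interpolating the viscous
stress tensor and pressure to the markers and integrating the traction
(primary), or summing the penalty-force reaction (cross-check).
"""

from __future__ import annotations

import numpy as np

from . import kernels
from .lattice import CS2, equilibrium, forcing_term, M, MINV

__all__ = [
    "kernel_phi",
    "polygon_weights",
    "interpolate_velocity",
    "penalty_force",
    "spread_force",
    "surface_loads",
]


def kernel_phi(r):
    """Cosine kernel phi(r) = 1/4 (1 + cos(pi r / 2)) on support |r| <= 2."""
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r < 2.0, 0.25 * (1.0 + np.cos(np.pi * r / 2.0)), 0.0)


def polygon_weights(X):
    """Per-marker arc-length weights and outward unit normals of a closed
    marker polygon (orientation detected from the signed area)."""
    nxt = np.roll(X, -1, axis=0)
    prv = np.roll(X, 1, axis=0)
    e_next = nxt - X
    e_prev = X - prv
    ds0 = 0.5 * (np.linalg.norm(e_next, axis=1) + np.linalg.norm(e_prev, axis=1))
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    area2 = np.sum(X[:, 0] * nxt[:, 1] - nxt[:, 0] * X[:, 1])
    sign = 1.0 if area2 > 0 else -1.0  # CCW polygon -> outward = (ty, -tx)
    normals = sign * np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    return ds0, normals


def interpolate_velocity(block, X_lat, window_pad=4):
    """Fluid velocity at marker positions (block lattice units).

    Velocity is computed from the distributions alone (no half-force shift:
    the immersed-boundary force of the upcoming step is not yet known).
    A macroscopic window around the marker cloud keeps the cost local.
    """
    i0, i1, j0, j1 = _window(block, X_lat, window_pad)
    fw = block.f[:, j0:j1, i0:i1]
    rho = fw.sum(axis=0)
    ux = (fw[1] - fw[3] + fw[5] - fw[6] - fw[7] + fw[8]) / rho
    uy = (fw[2] - fw[4] + fw[5] + fw[6] - fw[7] - fw[8]) / rho
    Xs = X_lat - np.array([i0, j0], dtype=float)
    out = np.empty_like(Xs)
    kernels.interpolate_velocity(
        np.ascontiguousarray(ux), np.ascontiguousarray(uy), Xs, out
    )
    return out


def _window(block, X_lat, pad):
    i0 = max(int(np.floor(X_lat[:, 0].min())) - pad, 0)
    i1 = min(int(np.ceil(X_lat[:, 0].max())) + pad + 1, block.nx)
    j0 = max(int(np.floor(X_lat[:, 1].min())) - pad, 0)
    j1 = min(int(np.ceil(X_lat[:, 1].max())) + pad + 1, block.ny)
    if i0 >= i1 or j0 >= j1:
        raise ValueError("markers outside the block")
    if (X_lat[:, 0].min() < 2 or X_lat[:, 1].min() < 2
            or X_lat[:, 0].max() > block.nx - 3 or X_lat[:, 1].max() > block.ny - 3):
        raise ValueError("marker too close to the block edge for the 4-point kernel")
    return i0, i1, j0, j1


def penalty_force(u_boundary, u_interp, eta):
    """Feedback penalty force per unit arc length: eta (u_B - u)."""
    return eta * (np.asarray(u_boundary) - np.asarray(u_interp))


def spread_force(block, X_lat, F, ds0):
    """Spread marker forces into the block's body-force field (accumulates)."""
    kernels.spread_force(block.gx, block.gy, X_lat, F, ds0)


def surface_loads(block, X_lat, ds0, normals, rc_lat, rho_ref=1.0, window_pad=4):
    """Integrated surface loads from the stress/pressure route.

    Interpolates ``sigma_xx, sigma_xy, sigma_yy`` and gauge pressure
    ``p - rho_ref c_s^2`` to the markers and integrates the traction
    ``(sigma - p I) n`` over the closed surface.  Returns
    ``(F (2,), M_z, traction (n, 2))`` in block lattice units, with the
    moment taken about ``rc_lat``.
    """
    i0, i1, j0, j1 = _window(block, X_lat, window_pad)
    fw = block.f[:, j0:j1, i0:i1]
    gxw = block.gx[j0:j1, i0:i1]
    gyw = block.gy[j0:j1, i0:i1]
    rho = fw.sum(axis=0)
    ux = (fw[1] - fw[3] + fw[5] - fw[6] - fw[7] + fw[8] + 0.5 * gxw) / rho
    uy = (fw[2] - fw[4] + fw[5] + fw[6] - fw[7] - fw[8] + 0.5 * gyw) / rho
    psi = fw - equilibrium(rho, ux, uy) + forcing_term(ux, uy, gxw, gyw)
    m = (M @ psi.reshape(9, -1)) * (1.0 - 0.5 * block.s)[:, None]
    trace = (m[0] * 4.0 + m[1]) / 3.0
    shp = rho.shape
    fields = np.ascontiguousarray(
        np.stack(
            [
                (-0.5 * (trace + m[7])).reshape(shp),  # sxx
                (-m[8]).reshape(shp),                  # sxy
                (-0.5 * (trace - m[7])).reshape(shp),  # syy
                rho * CS2 - rho_ref * CS2,             # gauge pressure
            ]
        )
    )
    Xs = X_lat - np.array([i0, j0], dtype=float)
    vals = np.empty((len(X_lat), 4))
    kernels.interpolate_fields(fields, Xs, vals)
    sxx, sxy, syy, p = vals.T
    tx = (sxx - p) * normals[:, 0] + sxy * normals[:, 1]
    ty = sxy * normals[:, 0] + (syy - p) * normals[:, 1]
    traction = np.stack([tx, ty], axis=1)
    F = (traction * ds0[:, None]).sum(axis=0)
    rel = X_lat - rc_lat
    Mz = np.sum((rel[:, 0] * ty - rel[:, 1] * tx) * ds0)
    return F, Mz, traction
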