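"""D2Q9 multiple-relaxation-time lattice Boltzmann model.

Moment set and transform follow the standard Lallemand–Luo ordering
(rho, e, eps, j_x, q_x, j_y, q_y, p_xx, p_xy).  The body force enters through
the Guo forcing term: the source is ``M^{-1} (I - S/2) M F`` and the
macroscopic velocity carries the half-force shift ``u = (sum f c + g/2)/rho``
(lattice units, ``dt = dx = 1`` per block).

All reference operations here are plain vectorized numpy and accept either
single states or fields; the hot collide–stream loop lives in
:mod:`swimrl.kernels` (numba) and is checked against these in the test suite.
"""

from __future__ import annotations

import numpy as np

CS2 = 1.0 / 3.0  # lattice sound speed squared

CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
W = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)

M = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1, 1, 1],
        [-4, -1, -1, -1, -1, 2, 2, 2, 2],
        [4, -2, -2, -2, -2, 1, 1, 1, 1],
        [0, 1, 0, -1, 0, 1, -1, -1, 1],
        [0, -2, 0, 2, 0, 1, -1, -1, 1],
        [0, 0, 1, 0, -1, 1, 1, -1, -1],
        [0, 0, -2, 0, 2, 1, 1, -1, -1],
        [0, 1, -1, 1, -1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, -1, 1, -1],
    ],
    dtype=float,
)
MINV = np.linalg.inv(M)


def relaxation_rates(nu_lat, s_e=1.1, s_eps=1.1, s_q=1.1):
    """Diagonal of S for kinematic lattice viscosity ``nu_lat``.

    Conserved moments (rho, j) are not relaxed (rate 0).  The shear rate
    follows from ``nu = c_s^2 (1/s_nu - 1/2)``.
    """
    s_nu = 1.0 / (3.0 * nu_lat + 0.5)
    if not 0.0 < s_nu < 2.0:
        raise ValueError(f"shear relaxation rate {s_nu} outside (0, 2)")
    return np.array([0.0, s_e, s_eps, 0.0, s_q, 0.0, s_q, s_nu, s_nu])


def equilibrium(rho, ux, uy):
    """Equilibrium distributions; returns shape (9,) + shape(rho)."""
    rho = np.asarray(rho, dtype=float)
    ux = np.asarray(ux, dtype=float)
    uy = np.asarray(uy, dtype=float)
    sh = (9,) + (1,) * rho.ndim
    cx = CX.reshape(sh)
    cy = CY.reshape(sh)
    w = W.reshape(sh)
    cu = cx * ux + cy * uy
    u2 = ux * ux + uy * uy
    return w * rho * (1.0 + cu / CS2 + cu**2 / (2 * CS2**2) - u2 / (2 * CS2))


def forcing_term(ux, uy, gx, gy):
    """Guo forcing populations F_i; moments are (0, 6 u.g, -6 u.g, g, -g, ...)."""
    ux, uy, gx, gy = (np.asarray(a, dtype=float) for a in (ux, uy, gx, gy))
    sh = (9,) + (1,) * ux.ndim
    cx = CX.reshape(sh)
    cy = CY.reshape(sh)
    w = W.reshape(sh)
    return w * (
        ((cx - ux) * gx + (cy - uy) * gy) / CS2
        + (cx * ux + cy * uy) * (cx * gx + cy * gy) / CS2**2
    )


def macroscopic(f, gx=0.0, gy=0.0):
    """Density, half-force-shifted velocity and pressure from distributions.

    ``f`` has shape (9, ...).  Raises on non-positive density.
    """
    f = np.asarray(f, dtype=float)
    rho = f.sum(axis=0)
    if np.any(rho <= 0):
        raise FloatingPointError("non-positive density encountered")
    sh = (9,) + (1,) * (f.ndim - 1)
    jx = (f * CX.reshape(sh)).sum(axis=0)
    jy = (f * CY.reshape(sh)).sum(axis=0)
    ux = (jx + 0.5 * np.asarray(gx)) / rho
    uy = (jy + 0.5 * np.asarray(gy)) / rho
    return rho, ux, uy, rho * CS2


def viscous_stress(f, s_rates, gx=0.0, gy=0.0):
    """Deviatoric (viscous) stress tensor from the non-equilibrium moments.

    ``sigma_ab = -sum_i [M^-1 (I-S/2) M (f - f_eq + F)]_i c_ia c_ib``
    evaluated consistently with the half-force-shifted velocity.  Returns
    (sxx, sxy, syy) with the same trailing shape as the field.
    """
    rho, ux, uy, _ = macroscopic(f, gx, gy)
    psi = f - equilibrium(rho, ux, uy) + forcing_term(ux, uy, gx, gy)
    flat = psi.reshape(9, -1)
    m = M @ flat
    m *= (1.0 - 0.5 * s_rates)[:, None]
    # cc moments expressed through (rho, e, pxx, pxy) rows
    trace = (m[0] * 4.0 + m[1]) / 3.0
    sxx = -0.5 * (trace + m[7])
    syy = -0.5 * (trace - m[7])
    sxy = -m[8]
    shp = psi.shape[1:]
    return sxx.reshape(shp), sxy.reshape(shp), syy.reshape(shp)
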