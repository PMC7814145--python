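"""Numba kernels: fused MRT collide–stream and the IB transfer stencils.

Everything operates in block-local lattice units (dx = dt = 1).  The moment
transform is hard-coded (verified against the matrix route in the tests).
Streaming wraps periodically; outer boundary conditions overwrite the wrapped
nodes afterwards (wet-node approach).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def collide_stream(f, fn, gx, gy, s_e, s_eps, s_q, s_nu):
    """One MRT collide + stream step with Guo forcing; writes into fn."""
    ny, nx = f.shape[1], f.shape[2]
    for j in range(ny):
        for i in range(nx):
            f0 = f[0, j, i]; f1 = f[1, j, i]; f2 = f[2, j, i]
            f3 = f[3, j, i]; f4 = f[4, j, i]; f5 = f[5, j, i]
            f6 = f[6, j, i]; f7 = f[7, j, i]; f8 = f[8, j, i]
            rho = f0 + f1 + f2 + f3 + f4 + f5 + f6 + f7 + f8
            gxl = gx[j, i]; gyl = gy[j, i]
            ux = (f1 - f3 + f5 - f6 - f7 + f8 + 0.5 * gxl) / rho
            uy = (f2 - f4 + f5 + f6 - f7 - f8 + 0.5 * gyl) / rho
            e = -4*f0 - f1 - f2 - f3 - f4 + 2*(f5 + f6 + f7 + f8)
            eps = 4*f0 - 2*(f1 + f2 + f3 + f4) + (f5 + f6 + f7 + f8)
            jx = f1 - f3 + f5 - f6 - f7 + f8
            jy = f2 - f4 + f5 + f6 - f7 - f8
            qx = -2*(f1 - f3) + (f5 - f6 - f7 + f8)
            qy = -2*(f2 - f4) + (f5 + f6 - f7 - f8)
            pxx = f1 - f2 + f3 - f4
            pxy = f5 - f6 + f7 - f8
            u2 = ux*ux + uy*uy
            ug = ux*gxl + uy*gyl
            e += -s_e*(e - rho*(-2.0 + 3.0*u2)) + (1.0 - 0.5*s_e)*6.0*ug
            eps += -s_eps*(eps - rho*(1.0 - 3.0*u2)) - (1.0 - 0.5*s_eps)*6.0*ug
            jx += gxl
            jy += gyl
            qx += -s_q*(qx + rho*ux) - (1.0 - 0.5*s_q)*gxl
            qy += -s_q*(qy + rho*uy) - (1.0 - 0.5*s_q)*gyl
            pxx += -s_nu*(pxx - rho*(ux*ux - uy*uy)) \
                + (1.0 - 0.5*s_nu)*2.0*(ux*gxl - uy*gyl)
            pxy += -s_nu*(pxy - rho*ux*uy) + (1.0 - 0.5*s_nu)*(ux*gyl + uy*gxl)
            t0 = (4.0*rho - 4.0*e + 4.0*eps) / 36.0
            axb = 4.0*rho - e - 2.0*eps
            g0 = (axb + 6.0*jx - 6.0*qx + 9.0*pxx) / 36.0
            g1 = (axb + 6.0*jy - 6.0*qy - 9.0*pxx) / 36.0
            g2 = (axb - 6.0*jx + 6.0*qx + 9.0*pxx) / 36.0
            g3 = (axb - 6.0*jy + 6.0*qy - 9.0*pxx) / 36.0
            d = 4.0*rho + 2.0*e + eps
            h0 = (d + 6.0*jx + 3.0*qx + 6.0*jy + 3.0*qy + 9.0*pxy) / 36.0
            h1 = (d - 6.0*jx - 3.0*qx + 6.0*jy + 3.0*qy - 9.0*pxy) / 36.0
            h2 = (d - 6.0*jx - 3.0*qx - 6.0*jy - 3.0*qy + 9.0*pxy) / 36.0
            h3 = (d + 6.0*jx + 3.0*qx - 6.0*jy - 3.0*qy - 9.0*pxy) / 36.0
            ip = i + 1 if i + 1 < nx else 0
            im = i - 1 if i > 0 else nx - 1
            jp = j + 1 if j + 1 < ny else 0
            jm = j - 1 if j > 0 else ny - 1
            fn[0, j, i] = t0
            fn[1, j, ip] = g0
            fn[2, jp, i] = g1
            fn[3, j, im] = g2
            fn[4, jm, i] = g3
            fn[5, jp, ip] = h0
            fn[6, jp, im] = h1
            fn[7, jm, im] = h2
            fn[8, jm, ip] = h3


@njit(cache=True, fastmath=True, inline="always")
def _eq9(rho, ux, uy, out, k):
    """Equilibrium populations for one node into out[:, k]."""
    u2 = ux * ux + uy * uy
    c0 = 1.0 - 1.5 * u2
    out[0, k] = (4.0 / 9.0) * rho * c0
    for (i, cx, cy, w) in ((1, 1.0, 0.0, 1.0 / 9.0), (2, 0.0, 1.0, 1.0 / 9.0),
                           (3, -1.0, 0.0, 1.0 / 9.0), (4, 0.0, -1.0, 1.0 / 9.0),
                           (5, 1.0, 1.0, 1.0 / 36.0), (6, -1.0, 1.0, 1.0 / 36.0),
                           (7, -1.0, -1.0, 1.0 / 36.0), (8, 1.0, -1.0, 1.0 / 36.0)):
        cu = cx * ux + cy * uy
        out[i, k] = w * rho * (c0 + 3.0 * cu + 4.5 * cu * cu)


@njit(cache=True, fastmath=True)
def equilibrium_points(rho, ux, uy, out):
    """Equilibrium populations at a list of points -> out (9, N)."""
    for k in range(rho.shape[0]):
        _eq9(rho[k], ux[k], uy[k], out, k)


@njit(cache=True, fastmath=True)
def reconstruct_points(rho, ux, uy, fneq, K, out):
    """f = f_eq(rho, u) + K @ f_neq per point (ghost-band reconstruction)."""
    n = rho.shape[0]
    for k in range(n):
        _eq9(rho[k], ux[k], uy[k], out, k)
        for i in range(9):
            acc = 0.0
            for j in range(9):
                acc += K[i, j] * fneq[j, k]
            out[i, k] += acc


@njit(cache=True, fastmath=True)
def restrict_block(f, gx, gy, jf, iif, K, out):
    """Coarsen selected fine nodes: out[:, a, b] = f_eq + K @ f_neq at
    fine node (jf[a], iif[b]) with the half-force velocity shift."""
    feq = np.empty((9, 1))
    for a in range(jf.shape[0]):
        j = jf[a]
        for b in range(iif.shape[0]):
            i = iif[b]
            rho = 0.0
            for q in range(9):
                rho += f[q, j, i]
            jx = f[1, j, i] - f[3, j, i] + f[5, j, i] - f[6, j, i] \
                - f[7, j, i] + f[8, j, i]
            jy = f[2, j, i] - f[4, j, i] + f[5, j, i] + f[6, j, i] \
                - f[7, j, i] - f[8, j, i]
            ux = (jx + 0.5 * gx[j, i]) / rho
            uy = (jy + 0.5 * gy[j, i]) / rho
            _eq9(rho, ux, uy, feq, 0)
            for q in range(9):
                acc = 0.0
                for r in range(9):
                    acc += K[q, r] * (f[r, j, i] - feq[r, 0])
                out[q, a, b] = feq[q, 0] + acc


@njit(cache=True, fastmath=True, inline="always")
def _phi(r):
    """Peskin 4-point cosine kernel (partition of unity on the lattice)."""
    a = abs(r)
    if a >= 2.0:
        return 0.0
    return 0.25 * (1.0 + np.cos(np.pi * a / 2.0))


@njit(cache=True, fastmath=True)
def interpolate_velocity(ux, uy, X, out):
    """Kernel-weighted velocity at marker positions (block lattice coords)."""
    ny, nx = ux.shape
    n = X.shape[0]
    for k in range(n):
        xm = X[k, 0]; ym = X[k, 1]
        i0 = int(np.floor(xm)) - 1
        j0 = int(np.floor(ym)) - 1
        sx = 0.0; sy = 0.0
        for dj in range(4):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            wy = _phi(ym - j)
            if wy == 0.0:
                continue
            for di in range(4):
                i = i0 + di
                if i < 0 or i >= nx:
                    continue
                w = wy * _phi(xm - i)
                sx += w * ux[j, i]
                sy += w * uy[j, i]
        out[k, 0] = sx
        out[k, 1] = sy


@njit(cache=True, fastmath=True)
def spread_force(gx, gy, X, F, ds0):
    """Accumulate marker forces onto the lattice body-force field."""
    ny, nx = gx.shape
    n = X.shape[0]
    for k in range(n):
        xm = X[k, 0]; ym = X[k, 1]
        fx = F[k, 0] * ds0[k]
        fy = F[k, 1] * ds0[k]
        i0 = int(np.floor(xm)) - 1
        j0 = int(np.floor(ym)) - 1
        for dj in range(4):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            wy = _phi(ym - j)
            if wy == 0.0:
                continue
            for di in range(4):
                i = i0 + di
                if i < 0 or i >= nx:
                    continue
                w = wy * _phi(xm - i)
                gx[j, i] += w * fx
                gy[j, i] += w * fy


@njit(cache=True, fastmath=True)
def interpolate_fields(fields, X, out):
    """Interpolate a stack of scalar fields (m, ny, nx) at markers -> (n, m)."""
    m = fields.shape[0]
    ny, nx = fields.shape[1], fields.shape[2]
    n = X.shape[0]
    for k in range(n):
        xm = X[k, 0]; ym = X[k, 1]
        i0 = int(np.floor(xm)) - 1
        j0 = int(np.floor(ym)) - 1
        for q in range(m):
            out[k, q] = 0.0
        for dj in range(4):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            wy = _phi(ym - j)
            if wy == 0.0:
                continue
            for di in range(4):
                i = i0 + di
                if i < 0 or i >= nx:
                    continue
                w = wy * _phi(xm - i)
                for q in range(m):
                    out[k, q] += w * fields[q, j, i]
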