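"""Static nested block refinement for the D2Q9 MRT solver.

The flow domain is covered by a coarse block; optional nested blocks refine
the region around immersed bodies by a factor 2 per level (acoustic scaling:
dt halves with dx, so the lattice Mach number is level-independent while the
lattice viscosity doubles on each finer level).

Coupling between levels follows the classic two-way scheme for nested LB
grids: fine-block ghost bands are reconstructed from spatially (bilinear) and
temporally (linear) interpolated coarse fields as
``f = f_eq(rho, u) + rescaled f_neq``, where each non-conserved moment of
``f_neq`` is rescaled by ``(1/s_f - 1/2)/(1/s_c - 1/2) * dt_f/dt_c`` (the
Chapman–Enskog scaling of the non-equilibrium part); coarse nodes covered by
the fine block are overwritten by the inverse operation after every coarse
step.  Immersed-boundary forces act on the finest block only, which must
therefore contain the bodies with a clearance of a few cells.

A single-entry ``blocks`` list gives a plain uniform-grid solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .lattice import CS2, M, MINV, equilibrium, macroscopic, relaxation_rates

GHOST = 2  # fine-side ghost band width (nodes overwritten from the parent)
RESTRICT_MARGIN = 6  # fine nodes ignored near the edge when restricting


@dataclass(frozen=True)
class Scaling:
    """Physical <-> lattice conversion for the coarsest block.

    ``dx0`` is the coarse grid spacing and ``u_lat`` the lattice-units value
    of the physical velocity scale ``u_ref`` (so dt0 = dx0 * u_lat / u_ref).
    ``nu_phys`` is the kinematic viscosity in physical units.
    """

    dx0: float
    u_lat: float
    u_ref: float
    nu_phys: float

    @property
    def dt0(self):
        return self.dx0 * self.u_lat / self.u_ref

    @property
    def nu_lat0(self):
        return self.nu_phys * self.dt0 / self.dx0**2

    def to_lat_velocity(self, u_phys):
        return np.asarray(u_phys) * self.u_lat / self.u_ref


class Block:
    """One uniform D2Q9 block (lattice units internally, dx = dt = 1)."""

    def __init__(self, origin, shape, dx, nu_lat, s_e=1.1, s_eps=1.1, s_q=1.1):
        self.x0, self.y0 = origin  # physical coordinates of node (0, 0)
        self.ny, self.nx = shape
        self.dx = dx
        self.nu_lat = nu_lat
        self.s = relaxation_rates(nu_lat, s_e, s_eps, s_q)
        self.f = np.empty((9, self.ny, self.nx))
        self.fn = np.empty_like(self.f)
        self.gx = np.zeros((self.ny, self.nx))
        self.gy = np.zeros((self.ny, self.nx))
        self.set_uniform(1.0, 0.0, 0.0)

    def set_uniform(self, rho, ux, uy):
        self.f[:] = equilibrium(
            np.full((self.ny, self.nx), float(rho)),
            np.full((self.ny, self.nx), float(ux)),
            np.full((self.ny, self.nx), float(uy)),
        )

    def to_local(self, xy_phys):
        """Physical coordinates -> block-local lattice coordinates."""
        xy = np.atleast_2d(np.asarray(xy_phys, dtype=float))
        out = np.empty_like(xy)
        out[:, 0] = (xy[:, 0] - self.x0) / self.dx
        out[:, 1] = (xy[:, 1] - self.y0) / self.dx
        return out

    def macroscopic(self):
        return macroscopic(self.f, self.gx, self.gy)

    def step(self):
        kernels.collide_stream(
            self.f, self.fn, self.gx, self.gy,
            self.s[1], self.s[2], self.s[4], self.s[7],
        )
        self.f, self.fn = self.fn, self.f


def _bilinear_setup(fine: Block, coarse: Block, idx_fine):
    """Parent gather indices/weights for fine nodes (flat) into coarse flat."""
    jj, ii = np.unravel_index(idx_fine, (fine.ny, fine.nx))
    xc = (fine.x0 + ii * fine.dx - coarse.x0) / coarse.dx
    yc = (fine.y0 + jj * fine.dx - coarse.y0) / coarse.dx
    i0 = np.floor(xc + 1e-9).astype(np.int64)
    j0 = np.floor(yc + 1e-9).astype(np.int64)
    i0 = np.clip(i0, 0, coarse.nx - 2)
    j0 = np.clip(j0, 0, coarse.ny - 2)
    fx = xc - i0
    fy = yc - j0
    par = np.stack(
        [
            j0 * coarse.nx + i0,
            j0 * coarse.nx + i0 + 1,
            (j0 + 1) * coarse.nx + i0,
            (j0 + 1) * coarse.nx + i0 + 1,
        ]
    )
    wgt = np.stack([(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy])
    return par, wgt


class NestedLattice:
    """A chain of nested blocks advanced with recursive sub-cycling.

    ``pre_collide_hook(t_phys)`` is called before every collide–stream of the
    finest block; the immersed-boundary coupling uses it to deposit forces.
    ``bc`` is a callable applied to the coarsest block after each of its
    steps (see :func:`make_outer_bc`); ``None`` leaves the domain periodic.
    """

    def __init__(self, blocks, bc=None, pre_collide_hook=None,
                 post_collide_hook=None):
        self.levels: list[Block] = list(blocks)
        for c, f in zip(self.levels, self.levels[1:]):
            if abs(c.dx / f.dx - 2.0) > 1e-9:
                raise ValueError("refinement ratio between levels must be 2")
        self.bc = bc
        self.pre_collide_hook = pre_collide_hook
        self.post_collide_hook = post_collide_hook
        self.time = 0.0
        self.dt = [None] * len(self.levels)
        self._pair = []
        for l, (coarse, fine) in enumerate(zip(self.levels, self.levels[1:])):
            self._pair.append(self._setup_pair(coarse, fine))

    def set_scaling(self, scaling: Scaling):
        self.scaling = scaling
        for l in range(len(self.levels)):
            self.dt[l] = scaling.dt0 / 2**l

    def _setup_pair(self, coarse: Block, fine: Block):
        ny, nx = fine.ny, fine.nx
        mask = np.zeros((ny, nx), dtype=bool)
        mask[:GHOST, :] = True
        mask[-GHOST:, :] = True
        mask[:, :GHOST] = True
        mask[:, -GHOST:] = True
        ghost_idx = np.flatnonzero(mask.ravel())
        par, wgt = _bilinear_setup(fine, coarse, ghost_idx)
        ring = np.unique(par.ravel())
        remap = np.searchsorted(ring, par)
        # restriction: fine nodes coincident with coarse nodes, away from edges
        off_i = round((fine.x0 - coarse.x0) / coarse.dx * 2) % 2
        off_j = round((fine.y0 - coarse.y0) / coarse.dx * 2) % 2
        i_f = np.arange(RESTRICT_MARGIN, nx - RESTRICT_MARGIN)
        i_f = i_f[(i_f + off_i) % 2 == 0]
        j_f = np.arange(RESTRICT_MARGIN, ny - RESTRICT_MARGIN)
        j_f = j_f[(j_f + off_j) % 2 == 0]
        xi = np.round((fine.x0 + i_f * fine.dx - coarse.x0) / coarse.dx).astype(int)
        yj = np.round((fine.y0 + j_f * fine.dx - coarse.y0) / coarse.dx).astype(int)
        # non-equilibrium moment rescaling coarse -> fine: the leading-order
        # Chapman-Enskog term scales as dt/s per moment
        kap = np.ones(9)
        nz = coarse.s > 0
        kap[nz] = coarse.s[nz] / fine.s[nz] * 0.5
        K_down = MINV @ np.diag(kap) @ M
        K_up = MINV @ np.diag(1.0 / kap) @ M
        return dict(
            ghost_idx=ghost_idx, remap=remap, wgt=wgt, ring=ring,
            i_f=i_f, j_f=j_f, xi=xi, yj=yj, K_down=K_down, K_up=K_up,
        )

    # -- interface data ---------------------------------------------------
    def _sample_ring(self, l):
        blk = self.levels[l]
        p = self._pair[l]
        fr = blk.f.reshape(9, -1)[:, p["ring"]]
        rho = fr.sum(axis=0)
        jx = fr[1] - fr[3] + fr[5] - fr[6] - fr[7] + fr[8]
        jy = fr[2] - fr[4] + fr[5] + fr[6] - fr[7] - fr[8]
        ux = jx / rho
        uy = jy / rho
        feq = np.empty_like(fr)
        kernels.equilibrium_points(rho, ux, uy, feq)
        return rho, ux, uy, fr - feq

    def _fill_ghosts(self, l, old, new, frac):
        fine = self.levels[l + 1]
        p = self._pair[l]
        w = p["wgt"]
        rm = p["remap"]

        def mix(a, b):
            return a if frac == 0.0 else (1.0 - frac) * a + frac * b

        rho = (w * mix(old[0], new[0])[rm]).sum(axis=0)
        ux = (w * mix(old[1], new[1])[rm]).sum(axis=0)
        uy = (w * mix(old[2], new[2])[rm]).sum(axis=0)
        fneq_c = mix(old[3], new[3])[:, rm]
        fneq = np.ascontiguousarray((fneq_c * w[None]).sum(axis=1))
        fg = np.empty_like(fneq)
        kernels.reconstruct_points(rho, ux, uy, fneq, p["K_down"], fg)
        fine.f.reshape(9, -1)[:, p["ghost_idx"]] = fg

    def _restrict(self, l):
        coarse = self.levels[l]
        fine = self.levels[l + 1]
        p = self._pair[l]
        out = np.empty((9, len(p["j_f"]), len(p["i_f"])))
        kernels.restrict_block(fine.f, fine.gx, fine.gy, p["j_f"], p["i_f"],
                               p["K_up"], out)
        coarse.f[:, p["yj"][:, None], p["xi"][None, :]] = out

    # -- time stepping ----------------------------------------------------
    def step(self):
        """Advance the whole hierarchy by one coarse time step."""
        self._advance(0, self.time)
        self.time += self.dt[0] if self.dt[0] else 1.0

    def _advance(self, l, t):
        blk = self.levels[l]
        finest = l == len(self.levels) - 1
        has_child = not finest
        if has_child:
            old = self._sample_ring(l)
        if finest and self.pre_collide_hook is not None:
            self.pre_collide_hook(t)
        blk.step()
        if l == 0 and self.bc is not None:
            self.bc(blk)
        if finest and self.post_collide_hook is not None:
            dt_self = self.dt[l] if self.dt[l] is not None else 1.0
            self.post_collide_hook(t + dt_self)
        if has_child:
            new = self._sample_ring(l)
            dt_child = (self.dt[l + 1] if self.dt[l + 1] is not None else 0.5)
            self._fill_ghosts(l, old, new, 0.0)
            self._advance(l + 1, t)
            self._fill_ghosts(l, old, new, 0.5)
            self._advance(l + 1, t + dt_child)
            self._restrict(l)

    @property
    def finest(self) -> Block:
        return self.levels[-1]


def channel_wall_bc():
    """No-slip walls on the south/north rows by halfway bounce-back.

    Works with the periodic streaming kernel: the post-collision populations
    that left through a wall are recovered from the wrapped rows and sent
    back.  The walls sit half a cell outside the first/last row, so a channel
    of ``ny`` rows has width ``ny`` lattice units.
    """

    def bc(blk: Block):
        f = blk.f
        s4 = f[4, -1, :].copy()
        s7 = f[7, -1, :].copy()
        s8 = f[8, -1, :].copy()
        n2 = f[2, 0, :].copy()
        n5 = f[5, 0, :].copy()
        n6 = f[6, 0, :].copy()
        # south wall unknowns (c_y > 0)
        f[2, 0, :] = s4
        f[5, 0, :] = np.roll(s7, 1)
        f[6, 0, :] = np.roll(s8, -1)
        # north wall unknowns (c_y < 0)
        f[4, -1, :] = n2
        f[7, -1, :] = np.roll(n5, -1)
        f[8, -1, :] = np.roll(n6, 1)

    return bc


def make_outer_bc(u_inflow_lat, rho0=1.0, sides=("west", "east", "north", "south"),
                  outlet="east"):
    """Outer boundary closure for the coarsest block.

    Inflow/far-field sides are pinned to the free-stream equilibrium
    (``rho0``, ``u_inflow_lat``); the ``outlet`` side copies the neighbouring
    column (zero-gradient extrapolation).  With ``u_inflow_lat = 0`` this is a
    quiescent far field.
    """
    ux, uy = float(u_inflow_lat), 0.0
    cache = {}

    def bc(blk: Block):
        if "col" not in cache:
            cache["col"] = equilibrium(np.full(blk.ny, rho0),
                                       np.full(blk.ny, ux),
                                       np.full(blk.ny, uy))
            cache["row"] = equilibrium(np.full(blk.nx, rho0),
                                       np.full(blk.nx, ux),
                                       np.full(blk.nx, uy))
        feq_col = cache["col"]
        feq_row = cache["row"]
        if "west" in sides:
            blk.f[:, :, 0] = feq_col
        if "east" in sides:
            if outlet == "east":
                blk.f[:, :, -1] = blk.f[:, :, -2]
            else:
                blk.f[:, :, -1] = feq_col
        if "south" in sides:
            blk.f[:, 0, :] = feq_row
        if "north" in sides:
            blk.f[:, -1, :] = feq_row

    return bc
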