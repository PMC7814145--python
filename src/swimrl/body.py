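"""Swimmer geometry, undulation kinematics and rigid-body mass properties.

The swimmer is a 2D slender body: a midline of length ``L`` dressed with a
half-thickness envelope ``d(s_l)``.  Two profiles are provided:

* ``trout`` — a quartic-in-arc-length fit (with a sqrt leading term) to the
  cross-section of a rainbow trout,
* ``anguilliform`` — the classic three-piece eel profile (circular head,
  parabolic taper, linear tail).

Undulation is prescribed as a chain of half-cycle waves travelling from head
to tail.  Each half cycle carries its own period ``T_n``, wavelength
``lambda_n`` and trailing-edge amplitude ``theta_lmax``; consecutive waves are
blended by a quintic whose value, slope and curvature match at the junction,
so the swimmer can retune its gait every half period without kinks.  In the
constant-parameter limit the chain degenerates to the usual
``theta_l = theta_lmax (s/L)^2 cos(2*pi*(t/T - s/(lambda)))`` travelling wave.

Translation and rotation of the body frame are *not* prescribed here: they
are driven by fluid forces (see :mod:`swimrl.fsi`).  To keep that split
honest, the prescribed deformation velocity field is projected to zero net
linear and angular momentum (:func:`momentum_correct`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

__all__ = [
    "BodyGeometry",
    "HalfCycleSpec",
    "MidlinePose",
    "SwimmerState",
    "half_thickness",
    "solve_waveform",
    "blend_poly",
    "make_halfcycle_chain",
    "extend_chain",
    "midline_pose",
    "mass_properties",
    "momentum_correct",
    "build_markers",
]

# trout half-thickness polynomial: d/L = a0*sqrt(s) + a1*s + a2*s^2 + a3*s^3 + a4*s^4
_TROUT_COEF = np.array([0.2610, -0.3112, 0.1371, -0.0791, -0.0078])


@dataclass(frozen=True)
class BodyGeometry:
    """Shape of the swimmer (or of a rigid obstacle realised as a body).

    Parameters are in units of the body length ``L`` except ``L`` itself.
    ``w_b``, ``s_b``, ``s_t``, ``w_t`` only matter for the anguilliform
    profile (head half-width, head extent, tail-taper start, tail half-width).
    """

    kind: str = "trout"  # "trout" | "anguilliform"
    L: float = 1.0
    w_b: float = 0.04
    s_b: float = 0.04
    s_t: float = 0.95
    w_t: float = 0.01
    n_markers: int = 0  # 0 -> choose from lattice spacing at marker build time

    def __post_init__(self):
        if self.kind not in ("trout", "anguilliform"):
            raise ValueError(f"unknown body kind {self.kind!r}")
        if self.L <= 0:
            raise ValueError("body length must be positive")


def half_thickness(s_rel, geom: BodyGeometry):
    """Half thickness d/L of the body at relative arc length ``s_rel``.

    ``s_rel`` may be a scalar or array in [0, 1].
    """
    s = np.asarray(s_rel, dtype=float)
    if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
        raise ValueError("arc fraction outside [0, 1]")
    s = np.clip(s, 0.0, 1.0)
    if geom.kind == "trout":
        a = _TROUT_COEF
        d = a[0] * np.sqrt(s) + a[1] * s + a[2] * s**2 + a[3] * s**3 + a[4] * s**4
        # the printed coefficients sum to zero at s=1 only to 4 decimals
        return np.maximum(d, 0.0)
    wb, sb, st, wt = geom.w_b, geom.s_b, geom.s_t, geom.w_t
    d = np.empty_like(s)
    head = s < sb
    mid = (s >= sb) & (s < st)
    tail = s >= st
    d[head] = np.sqrt(np.maximum(2 * wb * s[head] - s[head] ** 2, 0.0))
    # note: the taper is anchored at s_b so that d(s_b)=w_b and d(s_t)=w_t
    d[mid] = wb - (wb - wt) * ((s[mid] - sb) / (st - sb)) ** 2
    d[tail] = wt * (1.0 - s[tail]) / (1.0 - st)
    return np.maximum(d, 0.0)


def _quintic_endpoint_solve(length, v0, d0, k0, v1, d1, k1):
    """Coefficients c0..c5 of the quintic w with
    w(0)=v0, w'(0)=d0, w''(0)=k0, w(length)=v1, w'(length)=d1, w''(length)=k1."""
    X = length
    A = np.array(
        [
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [0, 0, 2, 0, 0, 0],
            [1, X, X**2, X**3, X**4, X**5],
            [0, 1, 2 * X, 3 * X**2, 4 * X**3, 5 * X**4],
            [0, 0, 2, 6 * X, 12 * X**2, 20 * X**3],
        ],
        dtype=float,
    )
    b = np.array([v0, d0, k0, v1, d1, k1], dtype=float)
    return np.linalg.solve(A, b)


def blend_poly(lam_prev, lam_n, amp_prev=1.0, amp_new=1.0, literal=False):
    """Quintic half-cycle waveform coefficients on ``zeta in [0, lam_n/2]``.

    The wave starts at the previous half-cycle's extremum (+amp_prev, zero
    slope, cosine curvature of the previous wavelength) and ends at the new
    extremum on the opposite side (-amp_new).  ``literal=True`` reproduces the
    same-side endpoint conditions as printed in the source kinematics
    (h(lam/2)=+1, negative end curvature), kept for comparison; it cannot
    alternate sides and is not used by the engine.
    """
    if lam_prev <= 0 or lam_n <= 0:
        raise ValueError("wavelengths must be positive")
    half = lam_n / 2.0
    k0 = -amp_prev * (2 * np.pi / lam_prev) ** 2
    if literal:
        return _quintic_endpoint_solve(
            half, amp_prev, 0.0, k0, amp_new, 0.0, -amp_new * (2 * np.pi / lam_n) ** 2
        )
    return _quintic_endpoint_solve(
        half, amp_prev, 0.0, k0, -amp_new, 0.0, amp_new * (2 * np.pi / lam_n) ** 2
    )


def solve_waveform(lam_prev, lam_n, literal=False):
    """Normalized (unit-amplitude) half-cycle waveform coefficients c0..c5."""
    return blend_poly(lam_prev, lam_n, 1.0, 1.0, literal=literal)


@dataclass(frozen=True)
class HalfCycleSpec:
    """One half cycle of undulation.

    ``c`` are the coefficients of the *signed, dimensional* deflection wave
    ``w(zeta)`` (units of rad at the trailing edge), i.e. the alternation sign
    and the amplitude are already folded in.  ``t0`` is the emission time of
    the wave at the head; the wave front travels at phase speed
    ``lam/T`` (arc fractions per unit time, ``lam`` in units of L).
    """

    T: float
    lam: float
    theta_lmax: float
    t0: float
    sign: float
    lam_prev: float
    c: np.ndarray = field(repr=False, default=None)

    @property
    def t_end(self):
        return self.t0 + self.T / 2.0

    def w(self, zeta):
        return np.polyval(self.c[::-1], zeta)

    def dw(self, zeta):
        dc = self.c[1:] * np.arange(1, 6)
        return np.polyval(dc[::-1], zeta)


def _make_spec(T, theta_lmax, lam, t0, sign, prev: HalfCycleSpec | None):
    lam_prev = prev.lam if prev is not None else lam
    amp_prev = prev.theta_lmax if prev is not None else theta_lmax
    c = sign * blend_poly(lam_prev, lam, amp_prev, theta_lmax)
    return HalfCycleSpec(T=T, lam=lam, theta_lmax=theta_lmax, t0=t0, sign=sign,
                         lam_prev=lam_prev, c=c)


def make_halfcycle_chain(actions, t_start=0.0):
    """Build a chain of half-cycle specs from an iterable of
    ``(T, theta_lmax, lam)`` triples.  Emission times accumulate in steps of
    ``T_k/2`` (each wave lasts half its period at the head) and the side sign
    alternates."""
    specs: list[HalfCycleSpec] = []
    t0 = t_start
    sign = 1.0
    prev = None
    for (T, th, lam) in actions:
        spec = _make_spec(T, th, lam, t0, sign, prev)
        specs.append(spec)
        t0 += T / 2.0
        sign = -sign
        prev = spec
    return specs


def extend_chain(specs, action):
    """Append one half cycle (an RL action) to an existing chain."""
    T, th, lam = action
    if specs:
        prev = specs[-1]
        spec = _make_spec(T, th, lam, prev.t0 + prev.T / 2.0, -prev.sign, prev)
    else:
        spec = _make_spec(T, th, lam, 0.0, 1.0, None)
    return specs + [spec]


@dataclass
class MidlinePose:
    """Deformed midline in the body (local) frame.

    Arrays over the arc-length grid ``s`` (uniform, head at origin).
    Velocities are the prescribed deformation rates (before or after the
    momentum projection, see ``momentum_corrected``)."""

    s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta_l: np.ndarray
    u: np.ndarray
    v: np.ndarray
    theta_dot: np.ndarray
    momentum_corrected: bool = False


def midline_pose(t, specs, geom: BodyGeometry, n_s: int = 201) -> MidlinePose:
    """Evaluate the midline shape and deformation velocity at time ``t``.

    For each arc position the most recent wave whose front has passed is
    active; its phase is clamped to the half-cycle span so that the deflection
    between waves (if a slower wave has not yet arrived) is frozen at the
    junction extremum.
    """
    if not specs:
        raise ValueError("empty half-cycle chain")
    if t < specs[0].t0 - 1e-12 or t > specs[-1].t_end + 1e-12:
        raise ValueError(f"t={t} outside span of the half-cycle chain")
    L = geom.L
    s = np.linspace(0.0, L, n_s)
    srel = s / L
    theta = np.zeros(n_s)
    theta_dot = np.zeros(n_s)
    remaining = np.ones(n_s, dtype=bool)
    # newest wave first; assign each arc position to the most recent arrived wave
    for spec in reversed(specs):
        if t < spec.t0:
            continue
        front = (spec.lam / spec.T) * (t - spec.t0)  # arc fractions travelled
        sel = remaining & (srel <= front + 1e-15)
        if not np.any(sel):
            continue
        zeta = front - srel[sel]
        half = spec.lam / 2.0
        active = zeta <= half
        zc = np.minimum(zeta, half)
        amp = srel[sel] ** 2
        theta[sel] = amp * spec.w(zc)
        theta_dot[sel] = np.where(active, amp * spec.dw(zc) * (spec.lam / spec.T), 0.0)
        remaining[sel] = False
        if not np.any(remaining):
            break
    if np.any(remaining):
        # ahead of the first wave front: undisturbed straight section
        theta[remaining] = 0.0
        theta_dot[remaining] = 0.0

    ct, st_ = np.cos(theta), np.sin(theta)
    x = cumulative_simpson(ct, x=s, initial=0.0)
    y = cumulative_simpson(st_, x=s, initial=0.0)
    u = cumulative_simpson(-st_ * theta_dot, x=s, initial=0.0)
    v = cumulative_simpson(ct * theta_dot, x=s, initial=0.0)
    return MidlinePose(s=s, x=x, y=y, theta_l=theta, u=u, v=v, theta_dot=theta_dot)


def mass_properties(pose: MidlinePose, geom: BodyGeometry, rho: float = 1.0):
    """Mass, body-frame mass center and yaw moment of inertia.

    Thin-strip quadrature: the body is the envelope of strips of width
    ``2 d(s)`` normal to the midline at uniform density ``rho`` (defaults to
    the fluid density: neutral buoyancy).  ``I_z`` includes the strips' own
    transverse second moment and is taken about the instantaneous mass center.
    """
    w = 2.0 * half_thickness(pose.s / geom.L, geom) * geom.L
    m = rho * simpson(w, x=pose.s)
    if m <= 0:
        raise ValueError("degenerate geometry: zero area")
    xc = rho * simpson(w * pose.x, x=pose.s) / m
    yc = rho * simpson(w * pose.y, x=pose.s) / m
    r2 = (pose.x - xc) ** 2 + (pose.y - yc) ** 2
    I_z = rho * simpson(w * r2 + w**3 / 12.0, x=pose.s)
    return m, np.array([xc, yc]), I_z


def momentum_correct(pose: MidlinePose, geom: BodyGeometry, rho: float = 1.0) -> MidlinePose:
    """Remove the net linear and angular momentum of the deformation field.

    Subtracts the rigid translation + rotation (about the instantaneous mass
    center) carried by the prescribed velocities, so that translation and
    rotation of the swimmer are driven exclusively by fluid forces.
    """
    w = 2.0 * half_thickness(pose.s / geom.L, geom) * geom.L
    m, rc, _ = mass_properties(pose, geom, rho)
    dx = pose.x - rc[0]
    dy = pose.y - rc[1]
    px = rho * simpson(w * pose.u, x=pose.s)
    py = rho * simpson(w * pose.v, x=pose.s)
    # planar part only: the rigid rotation field sampled on the midline
    I_planar = rho * simpson(w * (dx**2 + dy**2), x=pose.s)
    l_ang = rho * simpson(w * (dx * pose.v - dy * pose.u), x=pose.s)
    v0x, v0y = px / m, py / m
    om = l_ang / I_planar if I_planar > 0 else 0.0
    return replace(
        pose,
        u=pose.u - v0x + om * dy,
        v=pose.v - v0y - om * dx,
        momentum_corrected=True,
    )


def deformation_momentum(pose: MidlinePose, geom: BodyGeometry, rho: float = 1.0):
    """Net linear and angular momentum of the midline deformation field
    (diagnostic used by tests and by the FSI bookkeeping)."""
    w = 2.0 * half_thickness(pose.s / geom.L, geom) * geom.L
    m, rc, _ = mass_properties(pose, geom, rho)
    px = rho * simpson(w * pose.u, x=pose.s)
    py = rho * simpson(w * pose.v, x=pose.s)
    l_ang = rho * simpson(
        w * ((pose.x - rc[0]) * pose.v - (pose.y - rc[1]) * pose.u), x=pose.s
    )
    return np.array([px, py]), l_ang


def marker_arc_grid(pose: MidlinePose, geom: BodyGeometry, ds_target: float):
    """Midline arc positions whose surface points are ~ds_target apart
    (used to pin material markers for the integral feedback force)."""
    dense = np.linspace(0.0, geom.L, 8 * max(int(np.ceil(geom.L / ds_target)), 8))
    xd = np.interp(dense, pose.s, pose.x)
    yd = np.interp(dense, pose.s, pose.y)
    dd = half_thickness(dense / geom.L, geom) * geom.L
    thd_ = np.interp(dense, pose.s, pose.theta_l)
    sx = xd - dd * np.sin(thd_)
    sy = yd + dd * np.cos(thd_)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(sx), np.diff(sy)))])
    per_half = max(int(np.ceil(arc[-1] / ds_target)) + 1, 8)
    return np.interp(np.linspace(0.0, arc[-1], per_half), arc, dense)


def build_markers(pose: MidlinePose, geom: BodyGeometry, ds_target: float,
                  s_grid=None):
    """Closed surface marker loop (positions, velocities, arc weights).

    Markers are laid on both sides of the midline at offset ``±d(s)`` along
    the midline normal, ordered head -> tail on the +side then tail -> head on
    the -side, forming a counterclockwise closed polygon for a straight body.
    ``ds_target`` is the desired marker spacing (the fluid grid spacing of the
    finest block).  Returns ``(X, U, ds0)`` with X, U of shape (n, 2).
    """
    # sample so that spacing is ~ ds_target along the *surface* (the blunt
    # head needs denser midline sampling than the straight flanks); a fixed
    # s_grid keeps the markers material across time steps
    si = marker_arc_grid(pose, geom, ds_target) if s_grid is None else s_grid
    x = np.interp(si, pose.s, pose.x)
    y = np.interp(si, pose.s, pose.y)
    th = np.interp(si, pose.s, pose.theta_l)
    u = np.interp(si, pose.s, pose.u)
    v = np.interp(si, pose.s, pose.v)
    thd = np.interp(si, pose.s, pose.theta_dot)
    d = half_thickness(si / geom.L, geom) * geom.L
    nx, ny = -np.sin(th), np.cos(th)
    # normal rotates with theta_l: d/dt (n) = theta_dot * (-cos, -sin)
    ndx, ndy = -np.cos(th) * thd, -np.sin(th) * thd
    xp = np.stack([x + d * nx, y + d * ny], axis=1)
    up = np.stack([u + d * ndx, v + d * ndy], axis=1)
    xm = np.stack([x - d * nx, y - d * ny], axis=1)
    um = np.stack([u - d * ndx, v - d * ndy], axis=1)
    # drop duplicated head/tail points (d=0 there for both profiles)
    X = np.concatenate([xp, xm[::-1][1:-1]], axis=0)
    U = np.concatenate([up, um[::-1][1:-1]], axis=0)
    return X, U


@dataclass
class SwimmerState:
    """Rigid-frame state of the swimmer in the global frame."""

    r_c: np.ndarray
    theta: float
    u_c: np.ndarray
    omega: float
    m: float
    I_z: float

    def to_global(self, X_local, rc_body):
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        return self.r_c + (X_local - rc_body) @ R.T

    def marker_velocity(self, X_global, U_local_def):
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        rel = X_global - self.r_c
        spin = self.omega * np.stack([-rel[:, 1], rel[:, 0]], axis=1)
        return self.u_c + spin + U_local_def @ R.T
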