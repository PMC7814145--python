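"""Behavioural tasks for the learning swimmer.

Three environments over the FSI simulator — prey capture (point-to-point
swimming in quiescent water), rheotaxis (station holding in a uniform
current) and Karman-street station holding behind a D-shaped cylinder — plus
closed-form kinematic surrogates with the same state/action/reward
interfaces for desk-scale reinforcement-learning studies.

Common structure
----------------
* An action is one half-cycle of undulation, a (T, theta_lmax, lambda)
  triple drawn from a small task-specific base; the gait can be retuned
  every half period.
* The state fed to the recurrent Q-network is a window of the last 9
  half-period summaries (sensed features plus the one-hot of the action
  taken then; the newest row has no action yet).  Missing history at the
  start of an episode is padded by repeating the first real row.
* Rewards are non-positive: -r_tip/R for point-to-point, -|u_mean| for
  rheotaxis, -|u_x,mean| for Karman station holding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyGeometry, mass_properties, momentum_correct
from .fsi import (FlowSolver, HalfCycleKinematics, RigidObstacle, Swimmer,
                  dshape_markers, SimulationDiverged)
from .grid import NestedLattice, Scaling, make_outer_bc
from .fsi import build_blocks

WINDOW = 9  # rows in the state window

# action bases: lists of (T, theta_lmax_deg, lambda) in L/U units
ACTION_BASE = {
    "p2p": [(1.0, th, 1.0) for th in (0, 20, 40, 60, 80, 100, 120, 140, 160)],
    "rheotaxis": [(T, th, 1.0) for T in (0.3, 0.4, 0.5) for th in (18, 35, 55)],
    "karman": [(T, th, 1.5) for T in (1.2, 1.4, 1.6, 1.8, 2.0)
               for th in (16, 34, 51, 72, 97)],
}


def reward(task, sensed):
    """Task reward from the completed half-period summaries (always <= 0)."""
    if task == "p2p":
        return -sensed["r_tip"] / sensed["R"]
    if task == "rheotaxis":
        return -float(np.hypot(sensed["u_cx"], sensed["u_cy"]))
    if task == "karman":
        return -abs(sensed["u_cx"])
    raise ValueError(f"unknown task {task!r}")


class HistoryBuffer:
    """Rolling buffer of (features, action) half-period rows assembling the
    9-row state window, oldest first; start-of-episode rows repeat the first
    real row (with an all-zero action slot)."""

    def __init__(self, n_features, n_actions):
        self.n_features = n_features
        self.n_actions = n_actions
        self.rows = []  # (features, action index or None)

    @property
    def row_dim(self):
        return self.n_features + self.n_actions

    def start(self, features):
        self.rows = [(np.asarray(features, dtype=float), None)]

    def record_action(self, action):
        f, _ = self.rows[-1]
        self.rows[-1] = (f, int(action))

    def push(self, features):
        self.rows.append((np.asarray(features, dtype=float), None))
        if len(self.rows) > WINDOW + 1:
            self.rows.pop(0)

    def state(self):
        rows = self.rows[-WINDOW:]
        pad = WINDOW - len(rows)
        rows = [rows[0]] * pad + rows
        out = np.zeros((WINDOW, self.row_dim))
        for k, (f, a) in enumerate(rows):
            out[k, : self.n_features] = f
            if a is not None and k < WINDOW - 1:
                out[k, self.n_features + a] = 1.0
        return out


def assemble_state(history: HistoryBuffer):
    """The 9-row window (oldest first) currently held by the buffer."""
    return history.state()


# ---------------------------------------------------------------------------
# kinematic surrogate environments
# ---------------------------------------------------------------------------

@dataclass
class SurrogateParams:
    """Closed-form point-swimmer dynamics used by the surrogate tasks.

    Cruise speed is proportional to tail amplitude and wave rate (about
    0.4 L/T at the largest point-to-point amplitude, matching the paper-scale
    transit of a few body lengths in ~10 periods); speed relaxes toward it on
    a one-period hydrodynamic time scale; yaw follows the amplitude asymmetry
    of consecutive half strokes.  Small Gaussian noise mimics flow
    variability.
    """

    v_max: float = 0.4        # cruise speed at theta_ref [L/T]
    theta_ref: float = 160.0  # deg
    tau_v: float = 1.0        # speed relaxation time [T]
    k_turn: float = 0.45      # rad yaw per rad amplitude asymmetry
    noise_pos: float = 0.004  # L per half step
    noise_head: float = 0.02  # rad per half step


class SurrogatePointToPoint:
    """Point-to-point task with closed-form kinematics (<1 ms per step).

    The swimmer must bring its head to the arena centre; an episode ends on
    goal capture, arena exit (radius R) or the 200-period cap.
    """

    task = "p2p"

    def __init__(self, params: SurrogateParams = None, R=5.0, L=1.0,
                 goal_radius=0.25, period_cap=200, noise=True):
        self.p = params or SurrogateParams()
        if not noise:
            self.p = SurrogateParams(**{**self.p.__dict__,
                                        "noise_pos": 0.0, "noise_head": 0.0})
        self.R = R
        self.L = L
        self.goal_radius = goal_radius
        self.cap = period_cap
        self.actions = ACTION_BASE["p2p"]
        self.n_actions = len(self.actions)
        self.hist = HistoryBuffer(5, self.n_actions)
        self.rng = None

    # dynamics state: pos (2,), heading psi, speed v, stroke side, prev amp
    def reset(self, rng):
        self.rng = rng
        r0 = rng.uniform(1.0, 5.0) * self.L
        ang = rng.uniform(0, 2 * np.pi)
        self.pos = r0 * np.array([np.cos(ang), np.sin(ang)])
        theta_tip0 = rng.uniform(-np.pi / 2, np.pi / 2)
        to_center = np.arctan2(-self.pos[1], -self.pos[0])
        self.psi = to_center + theta_tip0
        self.v = 0.0
        self.omega = 0.0
        self.side = 1.0
        self.prev_amp = 0.0
        self.n_half = 0
        self.hist.start(self._features())
        return self.hist.state()

    def _features(self):
        r_tip = float(np.linalg.norm(self.pos))
        to_center = np.arctan2(-self.pos[1], -self.pos[0])
        theta_tip = (self.psi - to_center + np.pi) % (2 * np.pi) - np.pi
        # local-frame velocities: forward and lateral
        return np.array([r_tip / self.R, theta_tip / np.pi,
                         self.v, 0.0, self.omega])

    def step(self, action):
        T, th_deg, _lam = self.actions[action]
        self.hist.record_action(action)
        p = self.p
        th = np.deg2rad(th_deg)
        dt = T / 2.0
        v_c = p.v_max * th_deg / p.theta_ref
        self.v += (v_c - self.v) * (1.0 - np.exp(-dt / p.tau_v))
        dpsi = p.k_turn * self.side * (th - self.prev_amp)
        if p.noise_head:
            dpsi += self.rng.normal(0.0, p.noise_head)
        self.psi += dpsi
        self.omega = dpsi / dt
        self.pos += self.v * dt * np.array([np.cos(self.psi), np.sin(self.psi)])
        if p.noise_pos:
            self.pos += self.rng.normal(0.0, p.noise_pos, size=2)
        self.prev_amp = th
        self.side = -self.side
        self.n_half += 1
        feats = self._features()
        self.hist.push(feats)
        r_tip = float(np.linalg.norm(self.pos))
        rew = reward("p2p", {"r_tip": r_tip, "R": self.R})
        done = False
        info = {}
        if r_tip <= self.goal_radius:
            done = True
            info["outcome"] = "goal"
        elif r_tip > self.R:
            done = True
            info["outcome"] = "exit"
        elif self.n_half >= 2 * self.cap:
            done = True
            info["outcome"] = "cap"
        return self.hist.state(), rew, done, info


class SurrogateRheotaxis:
    """Station holding in a uniform current with closed-form kinematics.

    Facing into the stream (+x flow) is an unstable equilibrium: misalignment
    is amplified, and the swimmer is washed out unless it balances thrust
    against the current."""

    task = "rheotaxis"

    def __init__(self, params: SurrogateParams = None, R=5.0, U=1.0,
                 period_cap=200, k_instab=0.35):
        self.p = params or SurrogateParams(v_max=1.55, theta_ref=55.0,
                                           tau_v=0.6)
        self.R = R
        self.U = U
        self.cap = period_cap
        self.k_instab = k_instab
        self.actions = ACTION_BASE["rheotaxis"]
        self.n_actions = len(self.actions)
        self.hist = HistoryBuffer(3, self.n_actions)

    def reset(self, rng):
        self.rng = rng
        self.pos = np.zeros(2)
        # heading measured from -x (upstream); 0 = facing the current
        self.psi = np.deg2rad(rng.uniform(-45.0, 45.0))
        self.v = 0.0
        self.side = 1.0
        self.prev_amp = 0.0
        self.t = 0.0
        self.n_half = 0
        self.u_mean = np.zeros(2)
        self.omega = 0.0
        self.hist.start(self._features())
        return self.hist.state()

    def _features(self):
        return np.array([self.u_mean[0], self.u_mean[1], self.omega])

    def step(self, action):
        T, th_deg, _lam = self.actions[action]
        self.hist.record_action(action)
        p = self.p
        th = np.deg2rad(th_deg)
        dt = T / 2.0
        v_c = p.v_max * (th_deg / p.theta_ref) * (0.4 / T)
        self.v += (v_c - self.v) * (1.0 - np.exp(-dt / p.tau_v))
        dpsi = p.k_turn * self.side * (th - self.prev_amp) \
            + self.k_instab * np.sin(self.psi) * dt \
            + self.rng.normal(0.0, p.noise_head)
        self.psi += dpsi
        self.omega = dpsi / dt
        head = np.array([-np.cos(self.psi), np.sin(self.psi)])  # upstream-ish
        u_ground = self.v * head + np.array([self.U, 0.0])
        old = self.pos.copy()
        self.pos += u_ground * dt + self.rng.normal(0.0, p.noise_pos, size=2)
        self.u_mean = (self.pos - old) / dt
        self.prev_amp = th
        self.side = -self.side
        self.t += dt
        self.n_half += 1
        self.hist.push(self._features())
        rew = reward("rheotaxis",
                     {"u_cx": self.u_mean[0], "u_cy": self.u_mean[1]})
        done = False
        info = {}
        if np.linalg.norm(self.pos) > self.R:
            done, info["outcome"] = True, "exit"
        elif self.n_half >= 2 * self.cap:
            done, info["outcome"] = True, "cap"
        info["psi"] = self.psi
        return self.hist.state(), rew, done, info


class SurrogateKarman:
    """Karman-street station holding with closed-form wake kinematics.

    The swimmer drifts in a wake with a velocity deficit behind the cylinder
    and a travelling lateral oscillation (the vortex street); it must match
    its thrust to the local mean flow to hold its streamwise station inside
    the 8L x 4L arena."""

    task = "karman"

    def __init__(self, params: SurrogateParams = None, U=1.0, period_cap=200,
                 st=0.1875, D=0.3, wake_deficit=0.45):
        self.p = params or SurrogateParams(v_max=1.1, theta_ref=97.0, tau_v=1.0)
        self.U = U
        self.D = D
        self.T_v = self.D / (st * U)  # vortex period = 1.6 L/U
        self.lam_v = 1.0              # wake wavelength ~ 1 L
        self.deficit = wake_deficit
        self.cap = period_cap
        self.actions = ACTION_BASE["karman"]
        self.n_actions = len(self.actions)
        self.hist = HistoryBuffer(6, self.n_actions)

    def reset(self, rng):
        self.rng = rng
        x0 = rng.uniform(1.5, 2.5)
        self.pos = np.array([x0, 0.0])
        self.psi = 0.0  # facing upstream
        self.v = 0.0
        self.side = 1.0
        self.prev_amp = 0.0
        self.t = 0.0
        self.n_half = 0
        self.u_mean = np.zeros(2)
        self.F = np.zeros(2)
        self.hist.start(self._features())
        return self.hist.state()

    def _local_flow(self, x, y, t):
        core = np.exp(-(y / (0.6 * self.D)) ** 2)
        ux = self.U * (1.0 - self.deficit * core * np.exp(-x / 6.0))
        uy = 0.25 * self.U * core * np.sin(
            2 * np.pi * (t / self.T_v - x / self.lam_v))
        return np.array([ux, uy])

    def _features(self):
        return np.array([self.pos[0], self.pos[1], self.u_mean[0],
                         self.u_mean[1], self.F[0], self.F[1]])

    def step(self, action):
        T, th_deg, _lam = self.actions[action]
        self.hist.record_action(action)
        p = self.p
        th = np.deg2rad(th_deg)
        dt = T / 2.0
        v_c = p.v_max * (th_deg / p.theta_ref) * (1.6 / T)
        self.v += (v_c - self.v) * (1.0 - np.exp(-dt / p.tau_v))
        dpsi = p.k_turn * self.side * (th - self.prev_amp) * 0.5 \
            + self.rng.normal(0.0, p.noise_head)
        self.psi += dpsi
        flow = self._local_flow(self.pos[0], self.pos[1], self.t)
        head = np.array([-np.cos(self.psi), np.sin(self.psi)])
        u_ground = self.v * head + flow
        old = self.pos.copy()
        self.pos += u_ground * dt + self.rng.normal(0.0, p.noise_pos, size=2)
        self.u_mean = (self.pos - old) / dt
        rel = flow - self.v * head
        self.F = rel * np.linalg.norm(rel)  # quadratic drag proxy
        self.prev_amp = th
        self.side = -self.side
        self.t += dt
        self.n_half += 1
        self.hist.push(self._features())
        rew = reward("karman", {"u_cx": self.u_mean[0]})
        done = False
        info = {}
        if not (0.0 <= self.pos[0] <= 8.0 and abs(self.pos[1]) <= 2.0):
            done, info["outcome"] = True, "exit"
        elif self.n_half >= 2 * self.cap:
            done, info["outcome"] = True, "cap"
        return self.hist.state(), rew, done, info


def surrogate_env(task, **kw):
    """Factory for the kinematic surrogate of a task."""
    return {"p2p": SurrogatePointToPoint, "rheotaxis": SurrogateRheotaxis,
            "karman": SurrogateKarman}[task](**kw)


# ---------------------------------------------------------------------------
# CFD-backed environments
# ---------------------------------------------------------------------------

@dataclass
class CFDEnvConfig:
    """Numerical configuration of the CFD task environments.

    The reference setup uses near-body spacing 0.01 L on a 50L domain; the
    defaults here are scaled down so that an episode is tractable on one
    core.  ``dx0`` is the coarse spacing; two nested levels refine by 4x."""

    re: float = 1000.0
    domain: tuple = (12.0, 12.0)
    dx0: float = 0.08
    n_levels: int = 2
    u_lat: float = 0.05
    eta_lat: float = 2.0
    n_s: int = 121
    period_cap: int = 200


class CFDSwimmerEnv:
    """Base class: a deforming swimmer advanced one half cycle per action."""

    task = None

    def __init__(self, config: CFDEnvConfig = None):
        self.cfg = config or CFDEnvConfig()
        self.actions = ACTION_BASE[self.task]
        self.n_actions = len(self.actions)

    # subclasses implement _build(rng) -> (solver, swimmer) and _features()

    def reset(self, rng):
        self.rng = rng
        self.solver, self.swimmer = self._build(rng)
        self.kin: HalfCycleKinematics = self.swimmer.kinematics
        self.n_half = 0
        self.t_periods = 0.0
        self._sum = None
        self.hist.start(self._features(empty=True))
        return self.hist.state()

    def _advance_half_cycle(self, action):
        """Install the action's half-cycle wave and advance the FSI by T/2,
        accumulating the half-period means of the sensed quantities."""
        T, th_deg, lam = self.actions[action]
        self.kin.append((T, np.deg2rad(th_deg), lam))
        sol = self.solver
        sw = self.swimmer
        t_end = self.kin.t_end
        acc = dict(u=np.zeros(2), om=0.0, F=np.zeros(2), n=0)

        n = int(round((t_end - sol.nested.time) / sol.nested.dt[0]))
        for _ in range(n):
            sol.nested.step()
            acc["u"] += sw.state.u_c
            acc["om"] += sw.state.omega
            acc["F"] += sw.F
            acc["n"] += 1
        k = max(acc["n"], 1)
        self._sum = dict(u=acc["u"] / k, om=acc["om"] / k, F=acc["F"] / k)
        self.t_periods += 0.5 * T / self.actions[0][0] if False else 0.5
        self.n_half += 1

    def step(self, action):
        self.hist.record_action(action)
        try:
            self._advance_half_cycle(action)
        except SimulationDiverged as exc:
            raise RuntimeError(
                f"{self.task} episode aborted at half-cycle {self.n_half}: {exc}"
            ) from exc
        feats = self._features()
        self.hist.push(feats)
        rew, done, info = self._outcome()
        return self.hist.state(), rew, done, info


class PointToPointEnv(CFDSwimmerEnv):
    """Prey capture: reach the centre of a circular arena of radius R = 5L
    from a random initial range (1-5 L) and bearing (+-90 deg)."""

    task = "p2p"

    def __init__(self, config=None, R=5.0, goal_radius=0.25):
        super().__init__(config)
        self.R = R
        self.goal_radius = goal_radius
        self.hist = HistoryBuffer(5, self.n_actions)

    def _build(self, rng):
        cfg = self.cfg
        geom = BodyGeometry(kind="trout")
        kin = HalfCycleKinematics(geom, actions=[(1.0, 0.0, 1.0)], n_s=cfg.n_s)
        r0 = rng.uniform(1.0, 5.0)
        ang = rng.uniform(0.0, 2 * np.pi)
        head = np.array([cfg.domain[0] / 2 + r0 * np.cos(ang),
                         cfg.domain[1] / 2 + r0 * np.sin(ang)])
        theta_tip0 = rng.uniform(-np.pi / 2, np.pi / 2)
        to_center = np.arctan2(cfg.domain[1] / 2 - head[1],
                               cfg.domain[0] / 2 - head[0])
        theta = to_center + theta_tip0 + np.pi  # body +x_l points backwards
        sc = Scaling(dx0=cfg.dx0, u_lat=cfg.u_lat, u_ref=1.0,
                     nu_phys=1.0 / cfg.re)
        boxes = []
        dx = cfg.dx0
        for _ in range(cfg.n_levels - 1):
            dx /= 2
            boxes.append((0.5, cfg.domain[0] - 0.5, 0.5, cfg.domain[1] - 0.5))
        blocks = build_blocks(cfg.domain, cfg.dx0, boxes, sc.nu_lat0)
        nested = NestedLattice(blocks, bc=make_outer_bc(0.0))
        pose0 = momentum_correct(kin(0.0), geom)
        _, rcb, _ = mass_properties(pose0, geom)
        c, s = np.cos(theta), np.sin(theta)
        R2 = np.array([[c, -s], [s, c]])
        rc = head - (R2 @ (np.array([pose0.x[0], pose0.y[0]]) - rcb))
        sw = Swimmer(geom, kin, r_c=rc, theta=theta)
        solver = FlowSolver(nested, sc, [sw], eta_lat=cfg.eta_lat,
                            record_every=10**9)
        return solver, sw

    def _features(self, empty=False):
        cfg = self.cfg
        center = np.array(cfg.domain) / 2
        head = self.swimmer.head_position()
        rel = head - center
        r_tip = float(np.linalg.norm(rel))
        heading = self.swimmer.state.theta + np.pi
        to_center = np.arctan2(-rel[1], -rel[0])
        theta_tip = (heading - to_center + np.pi) % (2 * np.pi) - np.pi
        if empty or self._sum is None:
            u_loc = np.zeros(2)
            om = 0.0
        else:
            th = self.swimmer.state.theta
            c, s = np.cos(th), np.sin(th)
            u = self._sum["u"]
            u_loc = np.array([c * u[0] + s * u[1], -s * u[0] + c * u[1]])
            om = self._sum["om"]
        return np.array([r_tip / self.R, theta_tip / np.pi,
                         u_loc[0], u_loc[1], om])

    def _outcome(self):
        center = np.array(self.cfg.domain) / 2
        r_tip = float(np.linalg.norm(self.swimmer.head_position() - center))
        rew = reward("p2p", {"r_tip": r_tip, "R": self.R})
        if r_tip <= self.goal_radius:
            return rew, True, {"outcome": "goal"}
        if r_tip > self.R:
            return rew, True, {"outcome": "exit"}
        if self.n_half >= 2 * self.cfg.period_cap:
            return rew, True, {"outcome": "cap"}
        return rew, False, {}


class RheotaxisEnv(CFDSwimmerEnv):
    """Station holding in a uniform current (circular arena R = 5L); the
    state deliberately carries only velocities (position and orientation are
    implied in them), making the task partially observed."""

    task = "rheotaxis"

    def __init__(self, config=None, R=5.0):
        super().__init__(config)
        self.R = R
        self.hist = HistoryBuffer(3, self.n_actions)

    def _build(self, rng):
        cfg = self.cfg
        geom = BodyGeometry(kind="trout")
        kin = HalfCycleKinematics(geom, actions=[(0.4, 0.0, 1.0)], n_s=cfg.n_s)
        theta0 = np.deg2rad(rng.uniform(-45.0, 45.0))
        center = np.array(cfg.domain) / 2
        sc = Scaling(dx0=cfg.dx0, u_lat=cfg.u_lat, u_ref=1.0,
                     nu_phys=1.0 / cfg.re)
        boxes = []
        dx = cfg.dx0
        for _ in range(cfg.n_levels - 1):
            dx /= 2
            boxes.append((0.5, cfg.domain[0] - 0.5, 0.5, cfg.domain[1] - 0.5))
        blocks = build_blocks(cfg.domain, cfg.dx0, boxes, sc.nu_lat0)
        for b in blocks:
            b.set_uniform(1.0, cfg.u_lat, 0.0)
        nested = NestedLattice(blocks, bc=make_outer_bc(cfg.u_lat))
        pose0 = momentum_correct(kin(0.0), geom)
        _, rcb, _ = mass_properties(pose0, geom)
        # head into the current (+x inflow): body axis +x_l downstream
        theta = theta0
        sw = Swimmer(geom, kin, r_c=center, theta=theta)
        solver = FlowSolver(nested, sc, [sw], eta_lat=cfg.eta_lat,
                            record_every=10**9)
        self.center = center
        return solver, sw

    def _features(self, empty=False):
        if empty or self._sum is None:
            return np.zeros(3)
        return np.array([self._sum["u"][0], self._sum["u"][1],
                         self._sum["om"]])

    def _outcome(self):
        u = self._sum["u"] if self._sum is not None else np.zeros(2)
        rew = reward("rheotaxis", {"u_cx": u[0], "u_cy": u[1]})
        off = float(np.linalg.norm(self.swimmer.state.r_c - self.center))
        if off > self.R:
            return rew, True, {"outcome": "exit"}
        if self.n_half >= 2 * self.cfg.period_cap:
            return rew, True, {"outcome": "cap"}
        return rew, False, {}


class KarmanEnv(CFDSwimmerEnv):
    """Station holding in the vortex street of a D-shaped cylinder
    (D = 0.3 L, flat face downstream, Re_cyl = 300); the episode starts from
    a stored fully developed wake and a random head-cylinder distance."""

    task = "karman"

    def __init__(self, config=None, arena=(8.0, 4.0), develop_time=40.0):
        cfg = config or CFDEnvConfig(domain=(14.0, 8.0))
        super().__init__(cfg)
        self.arena = arena
        self.develop_time = develop_time
        self.hist = HistoryBuffer(6, self.n_actions)
        self._wake_checkpoint = None

    def _base_solver(self):
        cfg = self.cfg
        D = 0.3
        sc = Scaling(dx0=cfg.dx0, u_lat=cfg.u_lat, u_ref=1.0,
                     nu_phys=1.0 * D / 300.0)
        boxes = []
        dx = cfg.dx0
        for _ in range(cfg.n_levels - 1):
            dx /= 2
            boxes.append((0.5, cfg.domain[0] - 0.5, 0.5, cfg.domain[1] - 0.5))
        blocks = build_blocks(cfg.domain, cfg.dx0, boxes, sc.nu_lat0)
        for b in blocks:
            b.set_uniform(1.0, cfg.u_lat, 0.0)
        nested = NestedLattice(blocks, bc=make_outer_bc(cfg.u_lat))
        self.cyl_pos = np.array([2.0, cfg.domain[1] / 2])
        X = dshape_markers(self.cyl_pos, D, blocks[-1].dx)
        return nested, sc, RigidObstacle(X, name="cylinder")

    def _ensure_wake(self):
        if self._wake_checkpoint is not None:
            return
        nested, sc, cyl = self._base_solver()
        solver = FlowSolver(nested, sc, [cyl], eta_lat=self.cfg.eta_lat,
                            record_every=10**9)
        solver.run(self.develop_time)
        self._wake_checkpoint = [blk.f.copy() for blk in nested.levels]

    def _build(self, rng):
        self._ensure_wake()
        nested, sc, cyl = self._base_solver()
        for blk, f in zip(nested.levels, self._wake_checkpoint):
            blk.f[:] = f
        geom = BodyGeometry(kind="trout")
        kin = HalfCycleKinematics(geom, actions=[(1.6, 0.0, 1.5)],
                                  n_s=self.cfg.n_s)
        gap = rng.uniform(1.5, 2.5)
        head = self.cyl_pos + np.array([gap + 0.15, 0.0])
        pose0 = momentum_correct(kin(0.0), geom)
        _, rcb, _ = mass_properties(pose0, geom)
        rc = head - (np.array([pose0.x[0], pose0.y[0]]) - rcb)
        sw = Swimmer(geom, kin, r_c=rc, theta=0.0)
        solver = FlowSolver(nested, sc, [cyl, sw], eta_lat=self.cfg.eta_lat,
                            record_every=10**9)
        return solver, sw

    def _features(self, empty=False):
        rel = self.swimmer.state.r_c - self.cyl_pos
        if empty or self._sum is None:
            u = np.zeros(2)
            F = np.zeros(2)
        else:
            u = self._sum["u"]
            F = self._sum["F"]
        return np.array([rel[0], rel[1], u[0], u[1], F[0], F[1]])

    def _outcome(self):
        u = self._sum["u"] if self._sum is not None else np.zeros(2)
        rew = reward("karman", {"u_cx": u[0]})
        rel = self.swimmer.state.r_c - self.cyl_pos
        if not (0.0 <= rel[0] <= self.arena[0]
                and abs(rel[1]) <= self.arena[1] / 2):
            return rew, True, {"outcome": "exit"}
        if self.n_half >= 2 * self.cfg.period_cap:
            return rew, True, {"outcome": "cap"}
        return rew, False, {}


def make_env(task, surrogate=False, **kw):
    """Environment factory: CFD-backed or kinematic surrogate."""
    if surrogate:
        return surrogate_env(task, **kw)
    return {"p2p": PointToPointEnv, "rheotaxis": RheotaxisEnv,
            "karman": KarmanEnv}[task](**kw)
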