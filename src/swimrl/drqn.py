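"""Deep recurrent Q-learning with an LSTM action-value network.

One-step Q-learning on a recurrent approximator: the state is a short
temporal window of sensed rows (oldest first) fed through stacked LSTM
layers; the last hidden state feeds a linear head with one output per
action.  Training uses uniform experience replay, a periodically synchronised
target network, an epsilon-greedy behaviour policy and Adam on the mean
squared temporal-difference error

    TD = r_{n+1} + gamma * max_a Q_target(s_{n+1}, a) - Q(s_n, a_n)

(the bootstrap term is dropped on terminal transitions).

The network, backpropagation-through-time and Adam are implemented directly
in numpy; the analytic gradients are verified against finite differences in
the test suite.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RLConfig",
    "Transition",
    "ReplayMemory",
    "LSTMQNetwork",
    "Adam",
    "DRQNAgent",
    "td_error",
]


@dataclass
class RLConfig:
    """Hyperparameters of the learning loop.

    Defaults follow the study settings: discount 0.99, Adam rate 1e-3,
    replay capacity 5000, batch 100, target sync every 100 action steps,
    epsilon decaying from 1 to 0.05.
    """

    gamma: float = 0.99
    alpha: float = 0.001
    replay_capacity: int = 5000
    batch_size: int = 100
    target_sync: int = 100
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay_steps: int = 6000  # action steps over which epsilon anneals
    hidden_size: int = 64
    n_layers: int = 3
    grad_clip: float = 10.0
    update_every: int = 1
    warmup: int | None = None  # defaults to batch_size

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.eps_end <= self.eps_start <= 1.0:
            raise ValueError("epsilon schedule must stay within [0, 1]")

    def epsilon(self, step):
        """Linear decay from eps_start to eps_end over eps_decay_steps."""
        frac = min(step / max(self.eps_decay_steps, 1), 1.0)
        return self.eps_start + (self.eps_end - self.eps_start) * frac


@dataclass
class Transition:
    s: np.ndarray  # (T, D) state window
    a: int
    r: float
    s_next: np.ndarray
    terminal: bool = False

    def __post_init__(self):
        if not np.isfinite(self.r):
            raise ValueError("non-finite reward")


class ReplayMemory:
    """Uniform-replay ring buffer of transitions."""

    def __init__(self, capacity):
        self.capacity = capacity
        self._buf: list[Transition] = []
        self._pos = 0

    def push(self, tr: Transition):
        if tr.a < 0:
            raise ValueError("action index out of range")
        if len(self._buf) < self.capacity:
            self._buf.append(tr)
        else:
            self._buf[self._pos] = tr
        self._pos = (self._pos + 1) % self.capacity

    def __len__(self):
        return len(self._buf)

    def __contains__(self, tr):
        return any(t is tr for t in self._buf)

    def sample(self, n, rng):
        idx = rng.choice(len(self._buf), size=n, replace=False)
        return [self._buf[i] for i in idx]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMQNetwork:
    """Stacked LSTM layers plus a linear output head (one unit per action).

    Weights per layer: ``W`` of shape (input+hidden, 4*hidden) with gate
    order (input, forget, cell, output) and bias with forget gate offset +1.
    Hidden state is reset at the start of every forward pass (episode
    histories live in the state window itself).
    """

    def __init__(self, input_dim, n_actions, hidden=64, layers=3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.n_actions = n_actions
        self.hidden = hidden
        self.layers = layers
        self.W = []
        self.b = []
        d = input_dim
        for _ in range(layers):
            k = 1.0 / np.sqrt(d + hidden)
            self.W.append(rng.uniform(-k, k, size=(d + hidden, 4 * hidden)))
            bb = np.zeros(4 * hidden)
            bb[hidden:2 * hidden] = 1.0  # forget-gate bias
            self.b.append(bb)
            d = hidden
        k = 1.0 / np.sqrt(hidden)
        self.Wo = rng.uniform(-k, k, size=(hidden, n_actions))
        self.bo = np.zeros(n_actions)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        return self.W + self.b + [self.Wo, self.bo]

    def set_parameters(self, params):
        L = self.layers
        for l in range(L):
            self.W[l][...] = params[l]
            self.b[l][...] = params[L + l]
        self.Wo[...] = params[2 * L]
        self.bo[...] = params[2 * L + 1]

    def copy_from(self, other):
        self.set_parameters(other.parameters())

    # -- forward / backward ------------------------------------------------
    def forward(self, x, cache=None):
        """Q-values for a batch of state windows x of shape (B, T, D)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        B, T, D = x.shape
        H = self.hidden
        inp = x
        if cache is not None:
            cache["x"] = x
            cache["layers"] = []
        for l in range(self.layers):
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            steps = []
            for t in range(T):
                a_in = np.concatenate([inp[:, t, :], h], axis=1)
                z = a_in @ self.W[l] + self.b[l]
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_prev = c
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[:, t, :] = h
                if cache is not None:
                    steps.append((a_in, i, f, g, o, c_prev, c, tc))
            if cache is not None:
                cache["layers"].append(steps)
            inp = hs
        if cache is not None:
            cache["top_h"] = inp
        return inp[:, -1, :] @ self.Wo + self.bo

    def backward(self, cache, dq):
        """Gradients of a scalar loss with dLoss/dQ = dq (B, A)."""
        B, T, _ = cache["x"].shape
        H = self.hidden
        h_last = cache["top_h"][:, -1, :]
        grads = {"Wo": h_last.T @ dq, "bo": dq.sum(axis=0),
                 "W": [None] * self.layers, "b": [None] * self.layers}
        dinp = np.zeros((B, T, H))
        dinp[:, -1, :] = dq @ self.Wo.T
        for l in range(self.layers - 1, -1, -1):
            steps = cache["layers"][l]
            dW = np.zeros_like(self.W[l])
            db = np.zeros_like(self.b[l])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            din_l = self.W[l].shape[0] - H
            dx_out = np.zeros((B, T, din_l))
            for t in range(T - 1, -1, -1):
                a_in, i, f, g, o, c_prev, c, tc = steps[t]
                dh = dinp[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1 - tc**2) + dc_next
                df = dc * c_prev
                di = dc * g
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dg * (1 - g**2), do * o * (1 - o)], axis=1)
                dW += a_in.T @ dz
                db += dz.sum(axis=0)
                da_in = dz @ self.W[l].T
                dx_out[:, t, :] = da_in[:, :din_l]
                dh_next = da_in[:, din_l:]
            grads["W"][l] = dW
            grads["b"][l] = db
            dinp = dx_out
        return grads


class Adam:
    """Adam optimizer over a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def td_error(tr: Transition, q: LSTMQNetwork, q_target: LSTMQNetwork, gamma):
    """Temporal-difference error of a single transition."""
    qsa = q.forward(tr.s[None])[0, tr.a]
    boot = 0.0 if tr.terminal else gamma * q_target.forward(tr.s_next[None])[0].max()
    return float(tr.r + boot - qsa)


@dataclass
class EpisodeRecord:
    episode: int
    length: int
    ret: float
    eps: float
    info: dict = field(default_factory=dict)


class DRQNAgent:
    """Deep recurrent Q-learning agent (replay, target network, Adam)."""

    def __init__(self, input_dim, n_actions, config: RLConfig = None, seed=0):
        self.cfg = config or RLConfig()
        self.rng = np.random.default_rng(seed)
        self.q = LSTMQNetwork(input_dim, n_actions, self.cfg.hidden_size,
                              self.cfg.n_layers, self.rng)
        self.q_target = LSTMQNetwork(input_dim, n_actions, self.cfg.hidden_size,
                                     self.cfg.n_layers, self.rng)
        self.q_target.copy_from(self.q)
        self.replay = ReplayMemory(self.cfg.replay_capacity)
        self.opt = Adam(self.q.parameters(), lr=self.cfg.alpha)
        self.action_steps = 0
        self.n_actions = n_actions

    # -- policy ------------------------------------------------------------
    def select_action(self, state, eps=None):
        """Epsilon-greedy action; greedy ties broken toward the lowest index."""
        if eps is None:
            eps = self.cfg.epsilon(self.action_steps)
        if self.rng.random() < eps:
            return int(self.rng.integers(self.n_actions))
        qv = self.q.forward(np.asarray(state)[None])[0]
        return int(np.argmax(qv))

    # -- learning ----------------------------------------------------------
    def _batch_arrays(self, batch):
        s = np.stack([tr.s for tr in batch])
        a = np.array([tr.a for tr in batch])
        r = np.array([tr.r for tr in batch])
        s2 = np.stack([tr.s_next for tr in batch])
        term = np.array([tr.terminal for tr in batch], dtype=bool)
        return s, a, r, s2, term

    def update_step(self, batch=None):
        """One Adam step on the mean squared TD error of a minibatch."""
        if batch is None:
            batch = self.replay.sample(self.cfg.batch_size, self.rng)
        s, a, r, s2, term = self._batch_arrays(batch)
        B = len(a)
        q_next = self.q_target.forward(s2).max(axis=1)
        y = r + self.cfg.gamma * q_next * (~term)
        cache = {}
        qv = self.q.forward(s, cache=cache)
        qsa = qv[np.arange(B), a]
        delta = qsa - y
        loss = float(np.mean(delta**2))
        dq = np.zeros_like(qv)
        dq[np.arange(B), a] = 2.0 * delta / B
        grads = self.q.backward(cache, dq)
        flat = grads["W"] + grads["b"] + [grads["Wo"], grads["bo"]]
        if not all(np.all(np.isfinite(g)) for g in flat):
            raise FloatingPointError("non-finite gradients in DRQN update")
        gn = np.sqrt(sum(float(np.sum(g * g)) for g in flat))
        if self.cfg.grad_clip and gn > self.cfg.grad_clip:
            flat = [g * (self.cfg.grad_clip / gn) for g in flat]
        self.opt.step(flat)
        return loss

    def sync_target(self, force=False):
        if force or (self.action_steps % self.cfg.target_sync == 0):
            self.q_target.copy_from(self.q)

    def observe(self, transition: Transition):
        """Store a transition, count the action step, train and sync."""
        self.replay.push(transition)
        self.action_steps += 1
        loss = None
        warm = self.cfg.warmup if self.cfg.warmup is not None else self.cfg.batch_size
        if (len(self.replay) >= max(warm, self.cfg.batch_size)
                and self.action_steps % self.cfg.update_every == 0):
            loss = self.update_step()
        if self.action_steps % self.cfg.target_sync == 0:
            self.q_target.copy_from(self.q)
        return loss

    def train(self, env, n_episodes, max_steps=None, callback=None):
        """Episodic interaction loop; returns per-episode records."""
        log: list[EpisodeRecord] = []
        for ep in range(n_episodes):
            s = env.reset(self.rng)
            done = False
            ret = 0.0
            length = 0
            eps = self.cfg.epsilon(self.action_steps)
            while not done:
                eps = self.cfg.epsilon(self.action_steps)
                a = self.select_action(s, eps)
                s2, r, done, info = env.step(a)
                self.observe(Transition(s, a, r, s2, terminal=done))
                s = s2
                ret += r
                length += 1
                if max_steps is not None and length >= max_steps:
                    break
            log.append(EpisodeRecord(ep, length, ret, eps,
                                     info if isinstance(info, dict) else {}))
            if callback is not None:
                callback(log[-1])
        return log
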