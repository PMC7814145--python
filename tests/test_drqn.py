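"""Deep recurrent Q-learning: gradients, policy, replay, convergence."""

import numpy as np
import pytest

from swimrl.drqn import (Adam, DRQNAgent, LSTMQNetwork, ReplayMemory,
                         RLConfig, Transition, td_error)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        net = LSTMQNetwork(5, 4, hidden=8, layers=2,
                           rng=np.random.default_rng(3))
        x = rng.standard_normal((3, 6, 5))
        a = np.array([0, 2, 3])
        y = rng.standard_normal(3)

        def loss():
            q = net.forward(x)
            d = q[np.arange(3), a] - y
            return np.mean(d**2)

        cache = {}
        q = net.forward(x, cache=cache)
        d = q[np.arange(3), a] - y
        dq = np.zeros_like(q)
        dq[np.arange(3), a] = 2 * d / 3
        g = net.backward(cache, dq)
        flat = g["W"] + g["b"] + [g["Wo"], g["bo"]]
        params = net.parameters()
        eps = 1e-6
        check = np.random.default_rng(0)
        for pi, p in enumerate(params):
            # spot-check a handful of entries per tensor
            for _ in range(12):
                idx = tuple(check.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert flat[pi][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_forward_deterministic(self, rng):
        net = LSTMQNetwork(4, 3, hidden=6, layers=1,
                           rng=np.random.default_rng(1))
        x = rng.standard_normal((2, 9, 4))
        assert np.array_equal(net.forward(x), net.forward(x))


class TestTDError:
    def _nets(self):
        q = LSTMQNetwork(3, 2, hidden=4, layers=1,
                         rng=np.random.default_rng(0))
        qt = LSTMQNetwork(3, 2, hidden=4, layers=1,
                          rng=np.random.default_rng(1))
        return q, qt

    def test_arithmetic(self):
        # r=1, gamma=0.99, max Q_target=2, Q(s,a)=1.5 -> TD = 1.48
        class Const:
            def __init__(self, vals):
                self.vals = np.asarray(vals, dtype=float)

            def forward(self, x):
                return np.tile(self.vals, (len(x), 1))

        tr = Transition(np.zeros((9, 3)), 0, 1.0, np.zeros((9, 3)))
        td = td_error(tr, Const([1.5, -5.0]), Const([2.0, 0.0]), 0.99)
        assert td == pytest.approx(1.48)

    def test_myopic_limit(self):
        q, qt = self._nets()
        tr = Transition(np.zeros((9, 3)), 1, 0.7, np.ones((9, 3)))
        qsa = q.forward(tr.s[None])[0, 1]
        assert td_error(tr, q, qt, 0.0) == pytest.approx(0.7 - qsa)

    def test_terminal_drops_bootstrap(self):
        class Const:
            def forward(self, x):
                return np.full((len(x), 2), -1.0)

        tr = Transition(np.zeros((9, 3)), 0, -1.0, np.zeros((9, 3)),
                        terminal=True)
        assert td_error(tr, Const(), Const(), 0.99) == pytest.approx(0.0)


class TestPolicy:
    def _agent(self):
        cfg = RLConfig(hidden_size=6, n_layers=1)
        return DRQNAgent(3, 2, cfg, seed=5)

    def test_greedy_when_eps_zero(self):
        agent = self._agent()
        s = np.zeros((9, 3))
        a0 = agent.select_action(s, eps=0.0)
        assert all(agent.select_action(s, eps=0.0) == a0 for _ in range(20))

    def test_uniform_when_eps_one(self):
        agent = self._agent()
        s = np.zeros((9, 3))
        counts = np.bincount([agent.select_action(s, eps=1.0)
                              for _ in range(10000)], minlength=2)
        # 3 sigma of Binomial(10^4, 1/2)
        assert abs(counts[0] - 5000) < 3 * np.sqrt(10000 * 0.25)

    def test_mixed_eps_frequency(self):
        # eps=0.5 over 2 actions: greedy arm frequency = 1 - eps/2 = 0.75
        agent = self._agent()
        s = np.zeros((9, 3))
        greedy = agent.select_action(s, eps=0.0)
        n = 10000
        hits = sum(agent.select_action(s, eps=0.5) == greedy
                   for _ in range(n))
        sd = np.sqrt(n * 0.75 * 0.25)
        assert abs(hits - 0.75 * n) < 3 * sd

    def test_epsilon_schedule_endpoints(self):
        cfg = RLConfig(eps_decay_steps=100)
        assert cfg.epsilon(0) == 1.0
        assert cfg.epsilon(100) == pytest.approx(0.05)
        assert cfg.epsilon(10**6) == pytest.approx(0.05)


class TestTargetSync:
    def test_hard_copy_and_freeze(self, rng):
        cfg = RLConfig(hidden_size=6, n_layers=1, target_sync=10,
                       batch_size=4, replay_capacity=50, eps_decay_steps=10)
        agent = DRQNAgent(3, 2, cfg, seed=0)
        s = rng.standard_normal((9, 3))
        for k in range(25):
            tr = Transition(rng.standard_normal((9, 3)),
                            int(rng.integers(2)), float(rng.normal()),
                            rng.standard_normal((9, 3)))
            agent.observe(tr)
            probe_q = agent.q.forward(s[None])[0]
            probe_t = agent.q_target.forward(s[None])[0]
            if agent.action_steps % 10 == 0:
                assert np.array_equal(probe_q, probe_t)
        # between syncs the target differs while q trains
        diffs = []
        for k in range(9):
            agent.observe(Transition(rng.standard_normal((9, 3)), 0, 0.0,
                                     rng.standard_normal((9, 3))))
            diffs.append(np.max(np.abs(agent.q.forward(s[None])
                                       - agent.q_target.forward(s[None]))))
        assert max(diffs) > 0


class TestReplay:
    def test_ring_buffer_evicts_oldest(self):
        mem = ReplayMemory(5)
        trs = [Transition(np.zeros((2, 1)), 0, float(i), np.zeros((2, 1)))
               for i in range(8)]
        for tr in trs:
            mem.push(tr)
        assert len(mem) == 5
        rewards = sorted(t.r for t in mem._buf)
        assert rewards == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_sample_without_replacement(self):
        mem = ReplayMemory(20)
        for i in range(20):
            mem.push(Transition(np.zeros((2, 1)), 0, float(i),
                                np.zeros((2, 1))))
        batch = mem.sample(10, np.random.default_rng(0))
        assert len({id(t) for t in batch}) == 10

    def test_non_finite_reward_rejected(self):
        with pytest.raises(ValueError):
            Transition(np.zeros((2, 1)), 0, np.nan, np.zeros((2, 1)))


class TestUpdate:
    def test_zero_td_batch_leaves_weights_nearly_fixed(self):
        # with zero TD error the gradient vanishes; Adam moves nothing
        cfg = RLConfig(hidden_size=6, n_layers=1, batch_size=4)
        agent = DRQNAgent(3, 2, cfg, seed=0)
        s = np.zeros((9, 3))
        qv = agent.q.forward(s[None])[0]
        # craft transitions whose target equals the current prediction
        batch = [Transition(s, a, float(qv[a]), s, terminal=True)
                 for a in (0, 1, 0, 1)]
        before = [p.copy() for p in agent.q.parameters()]
        agent.update_step(batch)
        after = agent.q.parameters()
        assert all(np.allclose(b, a_, atol=1e-12)
                   for b, a_ in zip(before, after))

    def test_single_transition_fixed_point(self):
        # a repeated terminal transition: Q(s,a) converges to r
        cfg = RLConfig(hidden_size=8, n_layers=1, batch_size=4, alpha=0.005)
        agent = DRQNAgent(3, 2, cfg, seed=0)
        s = np.ones((9, 3)) * 0.3
        tr = Transition(s, 1, 0.8, s, terminal=True)
        for k in range(3000):
            agent.update_step([tr] * 4)
            if abs(agent.q.forward(s[None])[0, 1] - 0.8) < 1e-3:
                break
        assert agent.q.forward(s[None])[0, 1] == pytest.approx(0.8, abs=1e-3)

    def test_loss_decreases_on_frozen_batch(self, rng):
        cfg = RLConfig(hidden_size=8, n_layers=1, batch_size=8)
        agent = DRQNAgent(3, 2, cfg, seed=0)
        batch = [Transition(rng.standard_normal((9, 3)), int(rng.integers(2)),
                            float(rng.normal()), rng.standard_normal((9, 3)),
                            terminal=True) for _ in range(8)]
        losses = [agent.update_step(batch) for _ in range(100)]
        assert losses[-1] < losses[0]
        # non-increasing within Adam noise: allow 5% transient bumps
        run_min = np.minimum.accumulate(losses)
        assert np.all(np.asarray(losses) <= run_min * 1.05 + 1e-9)


class TestDeterminism:
    def test_identical_seeds_identical_logs(self):
        from swimrl.envs import surrogate_env

        def run(seed):
            env = surrogate_env("p2p")
            cfg = RLConfig(hidden_size=6, n_layers=1, batch_size=8,
                           update_every=4, eps_decay_steps=200)
            agent = DRQNAgent(env.hist.row_dim, env.n_actions, cfg, seed=seed)
            log = agent.train(env, 8)
            return [(r.length, r.ret) for r in log]

        assert run(7) == run(7)
        assert run(7) != run(8)
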