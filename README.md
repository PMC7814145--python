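# swimrl

Fluid–structure interaction and reinforcement learning for self-propelled
undulatory swimmers, in two dimensions.

Fish adapt their gait to the flow around them: they chase prey, hold
station against a current (rheotaxis), and slalom between the vortices
behind a bluff body (the Kármán gait).  `swimrl` provides the two pieces
needed to study such behaviour numerically, and their coupling:

* a **D2Q9 multiple-relaxation-time lattice Boltzmann solver** with static
  nested grid refinement and a **feedback (penalty) immersed boundary**
  for moving, deforming bodies — validated on cylinder-wake and
  self-propelled-swimmer benchmarks; and
* a **deep recurrent Q-network (DRQN)** — stacked LSTM layers trained by
  one-step Q-learning with experience replay, a target network and an
  ε-greedy policy — that selects the swimmer's undulation parameters
  (period `T`, tail amplitude `θ_max`, wavelength `λ`) every half cycle.

The swimmer's midline deflects as `θ_l(s,t) = θ_max (s/L)² h(ζ)` with a
quintic waveform `h` per half cycle whose endpoint conditions make value,
slope and curvature continuous across gait changes, so the agent can retune
its stroke smoothly at every half period.  Translation and rotation of the
body are not prescribed: they follow `m r̈_c = F_fluid` and
`d(I_z ω)/dt = M_z` under an explicit weak coupling with the flow.

Three behavioural tasks are included (point-to-point prey capture in still
water, rheotaxis in a uniform current, station holding in the vortex street
of a D-shaped cylinder), each in two forms: a full CFD environment and a
closed-form kinematic surrogate with identical state/action/reward
interfaces for fast learning studies.

## Worked example

Drag and lift of a circular cylinder at Re = 100 (the classic wake
benchmark), with near-body spacing 0.01 D:

```sh
$ swimrl benchmark cylinder --re 100 --t-end 70
C_D=1.3504  dC_L=0.6821  St=0.1683
```

Mean drag coefficient 1.350 and peak-to-peak lift coefficient 0.682 sit
within the span of published values for this flow (C̄_D ≈ 1.35–1.45,
ΔC_L ≈ 0.58–0.70), and the vortices shed at St ≈ 0.17.  The command also
writes the C_D/C_L time series (CSV) and a final flow snapshot (VTK) under
`runs/cylinder/`.  The Kármán-street generator used by the learning task
is validated the same way: `swimrl benchmark dwake` reports St = 0.193 for
the D-shaped cylinder at Re_D = 300 (reference 0.1875).

Train a swimmer on the point-to-point surrogate task and evaluate it:

```sh
$ swimrl train p2p --seed 1 --episodes 500 --surrogate --hidden 24 --layers 1
trained 500 episodes; median length last 50: 19
$ swimrl evaluate runs/train/p2p_agent.h5 p2p --n-runs 20
success rate over 20 runs: 0.70
```

Early episodes last ~100 half-cycles (random wandering); after 500
episodes the median is 19 — the swimmer has learned to turn toward the
target and swim to it, reaching it in most greedy evaluation runs.  Exact
numbers vary a little with the seed; learning curves land in
`runs/train/p2p_learning.csv`.

The library surface mirrors the CLI: `swimrl.fsi` (solver, benchmarks),
`swimrl.body` (geometry/kinematics), `swimrl.drqn` (agent),
`swimrl.envs` (tasks), `swimrl.evaluate` (policy evaluation and gait
kinematics).  See `docs/methods.md` for the model details, parameter
defaults and limitations.

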