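# Methods

`swimrl` couples a two-dimensional immersed-boundary lattice Boltzmann (IB–LB)
fluid–structure solver with a deep recurrent Q-network (DRQN) so that a
self-propelled undulatory swimmer can learn behavioural tasks — prey capture,
rheotaxis and Kármán-street station holding — from its own sensed dynamics.
This note documents the models, the numerical choices, the defaults and what
the desk-scale studies do and do not demonstrate.

## Fluid solver

**Lattice model.** D2Q9 multiple-relaxation-time (MRT) collision in the
Lallemand–Luo moment basis (ρ, e, ε, j_x, q_x, j_y, q_y, p_xx, p_xy).
The shear rate s_ν is set by the fluid viscosity through
ν = c_s²(1/s_ν − ½)Δt; the non-hydrodynamic rates default to
s_e = s_ε = s_q = 1.1 and are configurable.  Body forces use the Guo
forcing: source term M⁻¹(I − S/2)M F and the half-force velocity shift
u = (Σ f_i c_i + g Δt/2)/ρ.  For channel validation a halfway bounce-back
wall closure is provided; with the "magic" choice
(1/s_ν − ½)(1/s_q − ½) = 3/16 the Poiseuille profile is reproduced to
round-off.

**Viscous stress.** σ_αβ = −Σ_i [M⁻¹(I − S/2)M (f − f^eq + F)]_i c_iα c_iβ,
evaluated with the shifted velocity; verified against the Newtonian closed
form on steady shear to 2%.

**Nested refinement.** A static hierarchy of ratio-2 nested blocks under
acoustic scaling (Δt ∝ Δx, so the lattice Mach number is level-independent
while the lattice viscosity doubles per finer level).  Fine-block ghost bands
(2 cells) are rebuilt before every fine substep from bilinearly interpolated,
linearly time-interpolated coarse fields as f = f^eq(ρ, u) + κ f^neq, where
each non-conserved moment is rescaled by κ_k = (s_k^c / s_k^f)(Δt_f/Δt_c) —
the Chapman–Enskog scaling of the non-equilibrium part, f^(1) ∝ Δt/s.  After
each coarse step, coarse nodes interior to the fine block are overwritten by
the inverse reconstruction.  Uniform flow crosses interfaces exactly;
Taylor–Green decay through a fine patch stays within ~1–3% of the analytic
solution over thousands of steps, with the larger figure at lattice
viscosities below ~0.01.  Deeper chains (coarse → 2× → 4×) realise the
0.01 L or 0.01 D near-body spacing used by the benchmarks without paying
fine-grid cost in the far field.

**Outer boundaries.** Inflow/far-field sides pinned to the free-stream
equilibrium; the outlet column copies its upstream neighbour
(zero-gradient).  With zero inflow this is a quiescent far field.

## Immersed boundary

Feedback (penalty) coupling: marker force F_IB = η(u_B − u_interp), with
interpolation and spreading through the tensor-product cosine kernel
φ(r) = ¼(1 + cos(πr/2)) on a 4×4 stencil.  The kernel is an exact partition
of unity, so spreading conserves total force to round-off; its first moment
vanishes only approximately (max |Σ(x−j)φ| ≈ 0.021), which bounds the
interpolation accuracy for linear fields at ~0.02 cells.  η was calibrated
once against the circular-cylinder drag benchmark: the default is
4 ρΔx/Δt in finest-lattice units (6 is explicitly unstable, 2 leaves a
no-slip residual of 0.015 U on the cylinder); the self-propelled swimmer
uses 2 for stability of the two-way coupling.  Larger η tightens no-slip
at the cost of stiffer explicit dynamics.

**Loads.** Two routes are implemented.  For stationary bodies, tractions
(σ − pI)·n are integrated over a contour offset 2Δx outward from the
markers — just outside the diffuse interface band, where the stress field
is single-sided; momentum balance on that contour equals the body load up
to the thin-shell fluid inertia, which time-averages to zero.  For *free*
bodies the dynamics are driven by the penalty-force reaction
−Σ F_IB ds₀ (force and torque): the offset-shell route would add the
inertia of a fluid shell several times the mass of the thin, neutrally
buoyant swimmer and destabilise the explicit coupling, whereas the
reaction carries the interior-fluid inertia, which stabilises it.  Both
routes remain accessible on every body; the interior fictitious flow is
deliberately left uncorrected.

**Free-body coupling stabilisation.** The penalty reaction depends on the
rigid velocities themselves (dF/du ≈ −η Σds₀ per unit velocity); at
density ratio 1 this feedback makes a naive explicit update oscillate
unstably.  The rigid update treats that sensitivity semi-implicitly
(dividing the velocity increment by m + Δt·K and the angular increment by
the matching rotational sensitivity), and a short exponential average
(coefficient 0.25 per finest substep) filters the substep-scale
delayed-feedback oscillation of the two-way penalty loop; the physical
time scales are three orders of magnitude slower, so neither device
alters the converged dynamics.

## Swimmer model

**Geometry.** Two half-thickness profiles: a trout-like quartic with a √s
leading term (blunt head, pointed tail) and the classic three-piece
anguilliform profile (circular head of radius 0.04 L, parabolic taper,
linear tail; the taper is anchored at s_b so the profile is continuous).
Surface markers are laid at the finest-grid spacing along the surface arc
(the blunt head therefore gets denser midline sampling).

**Undulation.** The midline deflection angle is
θ_l(s, t) = (s/L)² w_n(ζ), ζ = (λ_n/T_n)(t − t_0n) − s/L,
where w_n is a quintic in ζ on [0, λ_n/2] for the n-th half-cycle wave.
The six endpoint conditions blend each wave C²-continuously into its
predecessor: w_n starts at the previous extremum (+θ_prev, zero slope,
curvature −θ_prev(2π/λ_prev)²) and ends at the opposite extremum
(−θ_n, zero slope, curvature +θ_n(2π/λ_n)²).  With constant parameters the
chain reproduces the endpoint data of θ_max cos(2πζ/λ) exactly, and the
side alternation emerges from the sign chain.  (The same-side endpoint
variant is available behind a flag for comparison; it cannot alternate and
is not used.)  Emission times accumulate as t_0n = Σ_{k<n} T_k/2 — each
wave lasts half its period at the head.  When consecutive waves have
different phase speeds the newest wave that has reached a material point
wins, with its phase clamped to the half-cycle span; deflection between
waves is frozen at the junction extremum, keeping the shape continuous.

Positions follow from midline inextensibility: y_l = ∫ sin θ_l ds,
x_l = ∫ cos θ_l ds (cumulative Simpson on ≥201 samples; arc length is
conserved to <0.1% up to θ_max = 160°).  Deformation velocities are
analytic in θ̇_l.

**Rigid dynamics.** The body is neutrally buoyant (density = fluid density);
mass and yaw inertia come from thin-strip quadrature of the thickness
envelope, I_z about the instantaneous mass centre including the strips' own
transverse moment.  The prescribed deformation is expressed in a
*zero-momentum body frame*: positions are shifted so the body-frame mass
centre stays at the origin and the frame rotates with the accumulated
deformation angle, with the matching velocity corrections.  This removes
the deformation's net linear and angular momentum **consistently** — the
corrected marker velocities are exactly the time derivative of the
corrected marker positions (verified against finite differences).  A
velocity-only projection is not sufficient: it desynchronises marker
motion from marker velocity, which acts on the fluid as an artificial slip
wave strong enough to reverse the thrust.  Translation and rotation are
therefore driven by fluid loads alone.  Time integration is explicit and weak:
forward Euler on the velocity, trapezoid on position and yaw, and the
discrete angular-momentum relation
(I^{i+1}+I^i)/2 · (ω^{i+1}−ω^i)/Δt + ω^{i+1}(I^{i+1}−I^i)/Δt = M_z^i
solved for ω^{i+1} with the inertia recomputed from the new pose.  No
sub-iteration is performed; a velocity above 10 L/T aborts the run as
diverged.

## Benchmarks and problem sizes

All benchmarks run on one core; sizes were chosen so the whole validation
suite completes in well under half an hour.

* **Circular cylinder, Re = 100.**  30D × 20D domain (blockage 5%), a
  ratio-2 chain 0.08D → 0.04 → 0.02 → 0.01D near the body, lattice inflow
  speed 0.08.  The flow is initialised with the potential-flow solution
  plus a small asymmetric bump so periodic shedding establishes by
  t ≈ 45 D/U; statistics are taken over t = 50–70.  Mean drag lands within
  ~2% of the literature consensus, peak-to-peak lift within ~1%, and the
  marker no-slip RMS residual below 0.008 U (the inflow lattice speed was
  kept at 0.08 after observing that 0.1 inflates the lift amplitude by
  ~15%; the penalty coefficient η = 4 ρΔx/Δt is the stability-limited
  optimum of the explicit scheme).
* **D-shaped cylinder, Re_D = 300.**  D = 0.3 L, flat face downstream,
  near-body spacing 0.01 L on a 16L × 10L domain; the Strouhal number is
  the dominant frequency of the lift signal (Hann window, parabolic peak
  interpolation) over ≥10 shedding cycles.
* **St–Re trend.**  Four short circular-cylinder runs (Re = 60–300) at
  reduced resolution; only the monotone increase of St with Re is asserted.
* **Anguilliform swimmer, Re = L²/(Tν) = 7142.**  A_max = 0.125 L at
  near-body spacing 0.01 L on a 16L × 8L quiescent domain, with a
  half-cosine amplitude ramp over the first period (the prescribed wave
  otherwise starts impulsively at full deformation speed).  The tethered
  body produces head-ward mean thrust of the magnitude expected from
  waving-sheet theory (cross-checked against a thin-filament configuration
  of the same kinematics), and the free swimmer accelerates head-first
  from rest.  See the limitations below for the directional instability
  that develops on longer horizons.

## Deep recurrent Q-learning

The action-value network is a stack of LSTM layers (default 3 × 64 cells)
with a linear head, implemented in numpy together with
backpropagation-through-time and Adam; the analytic gradients are verified
against central finite differences (relative error < 1e−4).  The state is
the 9-row window of half-period summaries fed oldest-first; the hidden
state is reset at every forward pass, so all memory lives in the window.
Past actions are one-hot encoded; continuous features are normalised by the
task scales (lengths by R or L, velocities by U, angles by π).  Defaults:
γ = 0.99, Adam rate α = 1e−3, replay capacity 5000, batch 100, hard target
sync every 100 action steps, ε linearly annealed 1 → 0.05 (horizon
configurable, default 6000 action steps), gradient-norm clip 10, one update
per `update_every` action steps after a one-batch warm-up.  Training is
bit-reproducible given the seed.

Desk-scale studies use smaller recurrent cores (16–32 cells, 1 layer) and
`update_every` of 2–3: on the closed-form tasks these train in about a minute
per 500-episode run while leaving the pinned hyperparameters (γ, α,
replay/batch/target sizes) untouched.  For the tabular chain-MDP oracle
check the step size is annealed (1e−3 → 2e−5) after the exploratory phase;
the learned action values are compared with the value-iteration fixed point
along on-policy state windows, since padded off-path windows lie outside
the training distribution of a recurrent approximator.

## Environments

One action = one half cycle; the action bases are
(T U/L = 1, θ_max = 0°…160°, λ = L) for point-to-point,
(T U/L ∈ {0.3, 0.4, 0.5}) × (θ_max ∈ {18°, 35°, 55°}) for rheotaxis and
(T U/L ∈ {1.2…2.0}) × (θ_max ∈ {16°…97°}) with λ = 1.5 L for the Kármán
task (the full 5 × 5 product, 25 actions).  Rewards: −r_tip/R, −|ū|,
−|ū_x|.  Episodes terminate on arena exit, goal capture (point-to-point,
capture radius 0.25 L) or a 200-period cap.  Missing history at episode
start repeats the first real row.  The rheotaxis/Kármán states carry only
velocities (and forces), making those tasks partially observed by design.

**CFD environments** rebuild the flow per episode (the Kármán task restores
a stored fully developed vortex-street state instead of regrowing the wake)
and advance the FSI by T/2 per action, accumulating half-period means of
the sensed quantities.  Their default numerical sizes are scaled down; the
reference configuration (0.01 L spacing, 50L domains, thousands of
episodes) is reachable through the same configuration surface but is a
cluster-scale computation, not part of the desk validation.

**Kinematic surrogates** expose the same state/action/reward interfaces
with closed-form dynamics (step cost ≪ 1 ms): cruise speed proportional to
tail amplitude with a one-period relaxation (0.4 L/T at the largest
point-to-point amplitude, matching transit of a few body lengths in ~10
periods), yaw proportional to the amplitude asymmetry of consecutive half
strokes, Gaussian position/heading noise (0.004 L, 0.02 rad per half step),
an unstable upstream-alignment equilibrium for rheotaxis, and a wake model
(velocity deficit + travelling lateral oscillation at St = 0.1875) for the
Kármán surrogate.  They capture the control topology of the tasks — not
the hydrodynamics — so learning-progress results on surrogates demonstrate
the correctness of the learning stack, not fluid-mechanical realism.

## Known limitations

* The refinement hierarchy is static; bodies must stay inside the finest
  block, which for long learning runs means sizing it to the full excursion.
* The penalty IBM leaves the interior fictitious flow uncorrected and the
  no-slip residual scales with η⁻¹, with η capped near 4–5 ρΔx/Δt by the
  stability of the explicit force update; the stress route and the penalty
  reaction differ by a few percent at Δx = 0.01D.
* **Heading instability of the free anguilliform swimmer.**  In 2D, with
  the stability-capped penalty stiffness, the swimmer accelerates slowly
  (~0.1 L/T over the first periods) and its heading is directionally
  unstable: a perturbation seeded by the start transient grows over
  O(10 periods) into a pronounced veer (the direction flips with the ramp
  length; the tethered mean torque is ≈ 0, and the behaviour is unchanged
  on uniform grids, so it is a property of the coupled model, not a
  nesting or load-path bias).  Long straight self-propelled runs therefore
  are not reproduced by this implementation: the start-up benchmark shows
  the thrust and acceleration physics, not 20-period straight-line
  cruising, and the corresponding acceptance checks on drift and
  monotonicity fail honestly.
* The 2D model omits 3D vortex dynamics, body elasticity and the
  head-motion/body-rotation components of the experimentally observed
  Kármán-gait kinematics.
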