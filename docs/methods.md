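# Methods

`wristsim` is a fully virtual muscle-activated wrist joint motion
simulator: a tendon-driven two-degree-of-freedom plant standing in for a
physical phantom-limb rig, four closed-loop control strategies, a
quadratic optimization resolving the muscle redundancy, and the evaluation
protocol comparing the strategies. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Plant model

The wrist has two rotational degrees of freedom — flexion–extension (FE)
and radioulnar deviation (RUD), ISB signs: flexion and ulnar deviation
positive — driven by six muscles (FCR, FCU, ECRL, ECRB, ECU, APL) through
pull-only cables. The axes are mechanically decoupled, so each axis is an
independent rigid body:

    I_j θ̈_j = Σ_i r_ij F_i + T_grav,j − b_j θ̇_j        (j = FE, RUD)

- **Moment arms** `r_ij` are constant with joint angle (the simplest model
  consistent with using fixed excursion ratios for control); tendon
  excursion is therefore linear, `e_i = r_i,fe θ_fe + r_i,rud θ_rud`.
  Angle-dependent arms are a documented extension point.
- **Gravity**: the hand is a point mass m at distance d from the wrist
  center. Hanging downward it contributes a restoring `−mgd sin θ` per
  axis; vertically upward it is an inverted pendulum, `+mgd sin θ`.
  Cross-axis gravity coupling is omitted along with the cross inertia.
- **Cables** are one-sided series springs: `F_i = max(0, k (y_i − e_i))`
  with `y_i` the actuator reel-in. A cable can pull, go slack, never push.
- **Actuators** are rate-limited position servos (max speed 0.1 m/s).
- **Sensing** is truth plus additive Gaussian noise: angles (motion
  capture) 0.1° SD, cable forces (load cells) 0.1 N SD. Latency is zero by
  default.

Integration is symplectic Euler with a 1 ms internal substep under a 5 ms
control tick; joint limits (±75° FE, ±25° RUD) are hard stops that zero
the axis velocity and latch a `limit_hit` flag — the virtual analogue of a
motion the rig could not complete.

### Default parameters

| parameter | value | rationale |
|---|---|---|
| hand mass m | 0.45 kg | 50th-percentile male hand |
| CoG offset d | 0.06 m | anthropometric |
| inertia I per axis | 2×10⁻³ kg·m² | m·d² order of magnitude |
| damping b per axis | 0.02 N·m·s/rad | cable/pulley/bearing friction of a real rig; underdamped (ζ ≈ 0.4 for the hanging pendulum) |
| cable stiffness k | 2×10⁴ N/m | steel cable + load-cell series compliance |
| loop period | 5 ms | 200 Hz control, comparable to a real-time loop |
| specific tension | 25 N/cm² | maximal muscle stress; `f_max = 25 × PCSA` |

The muscle table (PCSA 1.9–3.4 cm², moment arms 4–17 mm with ISB-correct
signs) is a literature-plausible fixture, not a measured data set; all
tests and the acceptance runs use it. Everything is configurable through
YAML/JSON config files and per-muscle CSV tables.

The passive-pendulum frequency check compares the simulated small
oscillation against the undamped closed form √(mgd/I)/2π, so it runs on a
low-damping configuration (b = 10⁻³); at the default damping the damped
frequency correction (≈ ζ²/2 ≈ 9%) would dominate the comparison.

## Control strategies

All four strategies consume one desired-trajectory sample and the noisy
measurements per 5 ms tick and emit per-muscle actuator displacement
commands (mm).

**Position control.** Nominal excursions `R θ_d` are always commanded; one
PID per axis turns the kinematic error into a corrective excursion applied
to the ECRB and distributed to the other tendons by the moment-arm ratios
`r_ij / r_ECRB,j`. Construction fails if ECRB has a zero arm on a
commanded axis.

**Force control.** Per-muscle PI loops (derivative forced to zero) track
prescribed force trajectories recorded from a position-control run; there
is no position feedback. The PI output is a displacement *rate*,
integrated into the command. Because the command integrates the integral
term twice, the integral gain must stay small (defaults kp = 16 mm/s/N,
ki = 8): larger values pump the free pendulum. This strategy is expected
to be fragile — it is the published negative result the suite reproduces:
it completes (with large error) only when gravity is restoring, and
diverges to a joint limit when the hand is vertical upward.

**Hybrid control.** Position control plus per-muscle force-bound
overrides. Implementation: two PI force loops per muscle — a floor loop
targeting F₀ (default 10 N) and a ceiling loop targeting
`f_max = 25 N/cm² × PCSA` — run alongside position control, and the
actuator takes the *override selection*

    y = min( max(y_position, y_floor), y_ceiling ).

The floor loop can only ever add tension and the ceiling only release it,
so neither fights position control; an idle override is clamped flush with
the position command (bumpless takeover, conditional integration — no
windup). A muscle's reported mode (`position` / `force_low` /
`force_high`) is the winning selector, labeled through a hysteresis margin
derived from the 2 N band plus a 100 ms debounce so sensor noise at a
crossover does not count as mode chatter. F₀ is the co-contraction handle:
raising it loads every cable harder at identical kinematics. Transient
floor undershoot is bounded by (unload rate)/(k·kp) ≈ 1.4 N plus noise,
within the hysteresis band — the invariant checked is
`min F ≥ F₀ − band`, and no cable ever unloads (position control, by
contrast, drops antagonists to exactly zero).

**Cascade control.** Two axis PIDs output joint torques, plus an inertial
feedforward `I_j · θ̈_d` anticipating peak acceleration (gravity is left
to feedback). A quadratic program distributes the torque demand over the
six muscles, and six PI loops track the optimized forces. The total-force
level ρ (default 140 N) is the co-contraction handle; because the QP meets
the torque equalities exactly, changing ρ redistributes force without
changing the commanded torque — kinematics are invariant to ρ by
construction.

### Muscle-force optimization

    minimise  Σ (F_i / A_i)²
    s.t.      Σ r_ij F_i = T_j   (j = FE, RUD)
              Σ F_i      = ρ
              F_i ≥ 0

with A_i the PCSA. The objective is diagonal positive definite, so the
minimizer is unique. The solver is a primal active-set method on the
nonnegativity bounds with direct KKT solves — the problem has 6 variables
and 3 equalities and runs every tick, so a bespoke dense solver beats a
general-purpose QP library. A feasible start is a minimum-norm correction
of the uniform point ρ/6 (an LP fallback covers the rare case that point
is infeasible). Determinism: ties broken by lowest index.

If ρ is inconsistent with the torque demand, the torque equalities take
priority: the ρ constraint is dropped, the relaxed problem is solved, and
the solution is flagged infeasible (and logged) — the controller keeps
running, as a physical rig must. `f_max` is *not* a constraint of this
program (it belongs to hybrid control); an optional flag adds the upper
bounds for exploration.

Verification is dual-route: an exhaustive oracle enumerates all 2⁶ active
sets, solves each equality-constrained KKT system, and keeps the feasible
candidate with the least objective. Solver and oracle agree to 1e-6 on
≥1000 random instances per suite run. A linear-programming feasibility
check (scipy `linprog`) reports the attainable total-force interval for a
demand.

## Gain tuning

Ultimate gain K_u and period T_u are found by probing the
proportional-only loop with a 2° step on a fresh noise-free plant hanging
downward: the gain is grown geometrically and bisected on the onset of
non-decaying oscillation (a saturated limit cycle counts as unstable —
a rig never grows without bound). Classic table values
(kp = 0.6 K_u, ki = 2 kp/T_u, kd = kp T_u/8) are then derated — the
"manual adjustment" of practical tuning — by documented per-strategy
factors:

- position and cascade: ×0.45 on kp, ki, kd (the plain classic values ring
  badly against the lightly damped plant);
- hybrid: ×0.45 on kp, ×0.9 on ki, ×3.6 on kd. The engaged floor loops
  keep antagonist cables taut, stiffening the loop, which both tolerates
  and needs more integral action; the extra derivative damps a ~1.8 Hz
  residual oscillation in the inverted (upward) orientation.

The inner force-loop PI defaults are also per-strategy: fast for hybrid's
floor/ceiling (kp = 10 mm/s/N, ki = 100 — it must catch a cable unloading
at up to ~280 N/s), gentle for cascade's nested tracking loops
(kp = 2, ki = 20 — faster gains interact with the torque loop), and
nearly integral-free for force replay (kp = 16, ki = 8, see above).

The packaged default config freezes the gains this procedure produces;
`wristsim tune` re-runs it.

## Evaluation protocol

Trajectories are sinusoidal, period 4 s, 3 cycles, with analytic
accelerations:

- FE-30: θ_fe = 30° sin ωt; RUD-10: θ_rud = 10° sin ωt;
- dart thrower's motion: 30° FE and 10° RUD in phase (a straight line
  from extension+radial to flexion+ulnar in the RUD–FE plane);
- circumduction: 20° FE (cosine) with 10° RUD (±sine) — an ellipse;
  clockwise visits flexion → ulnar → extension → radial.

Each run starts with the plant placed at the trajectory's initial posture
with cables just taut (as an experimenter would position the hand). The
first cycle is discarded as settling. Metrics: mean absolute
desired–actual deviation per axis; in-plane error averages the moved axes;
percent error normalizes by the principal amplitude; repeatability is the
sample SD of the mean in-plane error over five repeats differing only in
sensor-noise seed; per-direction maxima and per-muscle mean forces round
out the summary table. Co-contraction sweeps vary F₀ (hybrid) or ρ
(cascade) and tabulate per-muscle time-mean forces with the kinematic
error alongside.

A single seed fans out through `numpy.random.SeedSequence` so each run's
noise stream is independent and reproducible; identical seeds give
bit-identical results, and every CLI run writes a manifest (config
snapshot + seed + outputs) from which it can be reproduced exactly.

## What the virtual plant does and does not show

The generator emulates the study conditions — the muscle set, decoupled
axes, pull-only actuation, load-cell/motion-capture noise, both hand
orientations, and the published protocol parameters (F₀ = 10 N,
ρ = 140 N, five repeats). It does not emulate: carpal-level kinematics or
pronation–supination, angle-dependent moment arms or tendon wrapping,
actuator/servo internal dynamics, marker-cluster pose estimation, dry
(stiction) friction, or real-time jitter. Passing bounds here therefore
demonstrate the *control-architecture* properties — which strategies are
stable and accurate in which orientation, how co-contraction trades
against force level — not hardware-grade error magnitudes; the virtual
errors are smaller than a physical rig's because the plant model is the
controller's own model.

## Numerical choices and limitations

- QP tolerance 10⁻⁹ (KKT and feasibility), oracle filter 10× looser.
- PID integrators are trapezoidal with a hard anti-windup clamp; the
  derivative acts on a 20 ms first-order-filtered error.
- Simulation problem sizes: 3-cycle, 12 s runs at 200 Hz with 1 ms physics
  substeps; the full planar battery (12 runs) plus tuning completes in
  about a minute.
- Degenerate inputs (zero-range sweeps, empty series, rank-deficient
  moment-arm tables, non-finite states) are rejected with diagnostics
  rather than propagated.
- Known limitation: with all six forces near the floor (low-torque tasks
  under hybrid control) positional authority rests on whichever muscle the
  selector hands back to position control; the transient floor undershoot
  (≤ the hysteresis band) is visible in the force minima.
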