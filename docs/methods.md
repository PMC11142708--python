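# Model and methods

## The physical model

A spherical cargo bead (radius `R = 280 nm`) is held by an optical trap
with per-axis stiffness `κ_t = (0.045, 0.045, 0.03) pN/nm` above a rigid
microtubule, modeled as a cylinder of outer radius 12.5 nm lying along x
on the coverslip plane `z = 0`.  A single motor is anchored at a point
`a` on the bead surface; its head `h` diffuses with constant `D_m` and is
connected to the anchor by an extension-only Hookean tether (stiffness
`κ_m = 0.32 pN/nm`, rest length `L_m` = the motor contour length
including the ~10 nm antibody linker).  The assay condition is the pair
(motor length, gap), where the gap is the mean distance between the bead
surface and the top of the microtubule; the trap center is placed to
realize it.  Units are nm, s, pN throughout; `kBT = 4.114 pN·nm`.

All three bodies evolve by overdamped Euler–Maruyama steps:

* cargo translation with Stokes drag `ξ_c = 6πηR`, forced by the trap,
  the tether reaction and thermal noise;
* cargo rotation with drag `8πηR³`; the rotation increment vector is
  applied to the anchor by Rodrigues' formula about the cargo center, so
  `|a − c| = R` is preserved to round-off;
* head motion with drag `kBT/D_m` under tether, weak-bond and thermal
  forces.

Hard constraints (cargo above the coverslip and outside the microtubule;
head outside the cargo and microtubule and above the coverslip) are
enforced by nearest-point projection after each step — the simplest
scheme consistent with "bodies cannot pass through each other", and one
that never moves a point farther than the attempted step.

The default fluid viscosity is `η = 1e-5 pN·s/nm²`.  This is the value
the fitted kinetic parameters pair with; it corresponds to a far more
viscous medium than water (the configuration accepts any positive value,
e.g. `1e-9` for aqueous buffer).  At this viscosity the trapped bead's
vertical relaxation time is `ξ_c/κ_t,z ≈ 1.8 s`, which has a direct
physical consequence discussed under *Limitations*.

## The kinetic state machine

The motor is coarse-grained to a single unit with one nucleotide flag
and one attachment flag, giving four states: ADP-bound searching, apo
searching, ADP-bound weakly attached, strongly attached (absorbing —
the simulated first-passage ends there).  Channels and rates:

| transition | rate | condition |
|---|---|---|
| ADP-search → apo-search | `k_offADP` | — |
| ADP-search → weak | `k_onMT` | head within `d_MT` of the MT surface |
| apo-search → ADP-search | `k_onADP` | — |
| apo-search → strong | `k_onMT` | head within `d_MT` |
| weak → strong | `k_offADP,Fast` | tubulin-stimulated release |
| weak → ADP-search | `k_offMT · exp(F_w/F_d)` | force-dependent slip |

`d_MT = 5 nm` (approximate size of the kinesin head; the fit is
insensitive to it) and `F_d = 4 pN`.  The weak bond is a spring of
stiffness `κ_w` between the head and its attachment point, the nearest
microtubule-surface point at the moment of weak binding.  The
diffusion-only variant keeps a single channel (search → strong at
`k_onMT` within reach) and zeroes all nucleotide bookkeeping.

Scheduling is Gillespie-style under a cap: each step draws exponential
waiting times for all open channels at the current (frozen) rates; if
the minimum is below `dt_max` that event fires, otherwise the system
advances `dt_max` and rates are re-evaluated at the new positions.  The
cap bounds the first-order error of freezing position-dependent rates;
`dt_max = 4 ms` is validated by a convergence test (means at 4/2/1 ms are
statistically indistinguishable).  Simultaneous minimal waits (a
probability-zero tie) break deterministically toward the lowest channel
index.  Attempts reaching the 100 s screen are censored and restarted
from a fresh initial configuration; reported binding times are measured
from the last restart, i.e. conditional on success within the screen,
matching how the assay reports times.

The initial configuration is the bead at the trap center, the anchor at
its bottom pole, and the head straight down at the tether's rest length
(clamped at the microtubule top), with the motor ADP-bound — the
configuration left behind by the fast trap reset.

## Design choices at genuinely open points

* **Trap force through the mobility.**  The trap enters the cargo update
  as a force, `κ_t ⊙ (x_trap − c) · dt/ξ_c`, because only that form is
  dimensionally consistent and reproduces Boltzmann statistics
  (`var = kBT/κ_t` per axis, verified by test).
* **Reaction force on the cargo.**  By default the cargo feels the
  negation of the Hookean tether force (Newton's third law); the
  same-sign convention is available as
  `PhysicalParams(third_law_cargo_force=False)`.
* **Weak-bond force while slack.**  The weak spring acts on the head
  whenever weakly bound, regardless of tether extension
  (`weak_force_taut_only=True` restricts it to the taut branch); a bond
  to the track has no reason to switch off when the tether goes slack.
* **Torque condition.**  The motor torque `(a−c) × F_cargo` acts on the
  cargo only while weakly bound by default (`torque_always=True`
  extends it to all states).
* **Wall corrections.**  Brenner's perpendicular-approach factors rescale
  the full isotropic translational and rotational drags; the
  parallel/perpendicular anisotropy is deliberately neglected.  Off by
  default.
* **Microtubule geometry.**  Standard outer radius 12.5 nm, resting on
  the coverslip; "distance" means bead surface to microtubule top.

## Numerical choices

* **Head-spring stability.**  The explicit head update is stable only
  for `(κ_m + κ_w)·D_m·dt < kBT`.  Inside the event loop the head
  update is automatically substepped when a parameter proposal violates
  this (common during global optimization, where `D_m` can be an order
  of magnitude above its fitted value), so every proposal is integrated
  stably.
* **Random numbers.**  The JIT-compiled event loop uses an inline
  xorshift128+ generator with polar-method normals (the variate budget,
  ~10 per 4 ms step, dominates simulator cost); distributional
  correctness is covered by KS tests.  Event and ensemble seeds derive
  from `numpy.random.SeedSequence`, and per-condition seeds are keyed by
  the condition itself, so results are independent of condition
  ordering.  Everything is reproducible from one integer seed.
* **Degenerate inputs.**  Coincident anchor and head are rejected; a
  zero rotation increment is the identity; projections handle the
  measure-zero "exactly on the axis" cases by a fixed upward convention.

## Inference

* **Point estimation.**  The loss is the squared distance between
  simulated and observed per-condition mean binding times (no
  distributional information).  For *fitting* the residuals are weighted
  by inverse squared reported SEMs: at desk-scale simulation budgets
  (S ≈ 15–25 events per condition per evaluation, against the reference
  S = 1000) the unweighted loss is dominated by the slowest, noisiest
  conditions and the sub-second plateau that identifies
  `k_offADP,Fast` disappears below the Monte-Carlo noise floor.  The
  optimizer is derivative-free and global over log-parameters:
  differential evolution followed by Nelder–Mead refinement within one
  evaluation budget, with common random numbers making the objective
  deterministic per seed.  During optimization, events are simulated as
  single attempts (restarts capped), averaging completed attempts only —
  an unbiased estimator of the conditional-on-success mean, with bounded
  cost for never-binding proposals; conditions whose running mean
  already far overshoots the data are scored early.
* **ABC-SMC.**  Lognormal priors per parameter, parameterized by their
  natural-scale mean and sd; all sampling and kernels live in log space,
  where the prior is Gaussian.  Generation 1 filters prior draws by the
  summed per-condition absolute relative error; later generations
  resample by weight, perturb with a diagonal Gaussian kernel (variance
  2× the weighted sample variance), and re-weight by
  `π(θ)/Σ_j w_j K(θ|θ_j)`.  The default threshold schedule is 1.8 down
  to 0.2 in steps of 0.2; the default fitting subset is three conditions
  (shortest motor at the smallest gap, mid motor at the middle gap,
  longest motor at the largest gap).  If a generation cannot fill its
  quota within a draw budget the run returns partially with a
  `stalled` flag — a prior–data conflict is reported, never looped.
* **Cross-validation.**  Leave-one-motor-length-out: fit on two lengths,
  simulate the held-out conditions at the fitted parameters, score by
  mean absolute percentage error (magnitudes, so over- and
  under-prediction cannot cancel).  Each model variant first gets a
  full-data fit whose estimate warm-starts the per-fold local
  refinements; both variants are treated identically.

## What the synthetic data does and does not emulate

`generate_dataset` reproduces the assay's design and reporting: 3 motor
lengths × 4 gaps, censored-at-100 s first-passage times, n = 100 events
per condition by default, summarized as mean ± SEM, with the ground
truth stored only in the metadata.  It does not emulate detector
physics: photodiode noise, the 15 nm/10 ms detection threshold (its
latency is fractions of a second and would not change the seconds-scale
conclusions), stage-displacement calibration error, or heterogeneity
between individual motors.  Passing recovery tests therefore show that
the inference machinery is sound *given the model*, not that the model
captures every feature of real traces.

## Problem sizes in the test suite

The test suite runs ensembles of 200 events per condition for pathway
and monotonicity checks, ABC with 50 particles, a 4-generation schedule
(1.8, 1.4, 1.0, 0.6) and S = 50 simulations per condition, and
cross-validation with ~110-evaluation full fits, 40-evaluation fold
refinements and S = 15–20 — sizes chosen so the full pipeline exercises
end to end on a single CPU in minutes while keeping every statistical
assertion at a pre-set size.

## Limitations

* With the fluctuation–dissipation-consistent trap update and the
  default viscosity, the trapped bead's vertical fluctuations are
  σ_z ≈ 11.7 nm with a ~1.8 s relaxation time.  The shortest motor at
  the largest gap then binds only through rare deep excursions: mean
  times reach tens of seconds, a substantial fraction of attempts censor
  at 100 s, and the fraction of time spent searching at that corner of
  the design approaches 95% — the search/chemistry decomposition spans
  roughly 10–95% across conditions rather than a narrower 20–80% band.
* The two-head mechanochemistry is coarse-grained away: one nucleotide
  flag, one attachment flag, no ATP binding or hydrolysis, no stepping
  after strong binding.
* Hydrodynamics is minimal: isotropic Stokes drags, optional scalar
  near-wall corrections, no translation–rotation coupling or lubrication.
* The tether is a simple one-way Hookean spring; wormlike-chain or
  crumpled-stalk models are out of scope.
* The priors pin `k_offMT` tightly (sd/mean = 0.1): with data generated
  at `k_offMT = 0.2 /s`, twice the prior mean, any posterior that
  respects the prior concentrates near 0.1, so recovery of this one
  parameter saturates at a ratio of ~0.5.
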