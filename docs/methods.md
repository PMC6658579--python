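# Methods

`fitloop` simulates a computational theory of how an organism can
estimate its own evolutionary fitness, benefit from the estimate, and
communicate it.  The theory is qualitative; this package supplies the
concrete functional forms, discretizations and statistical protocols
needed to turn it into running, testable code.  Every such concretization
is listed here, because none of them is forced: each is a design choice
of this package.

## The model

**World and fitness.**  The effective world `w` is split into the
organism's *form* `θ ∈ ℝ^d` (the part the organism itself can change;
`d = dim_form`, default 2) and an *environment* vector that follows a
mean-reverting (Ornstein–Uhlenbeck) walk with timescale `env_timescale`
and stationary sd `env_sd`.  Fitness is a scalar field over form space:

    f(θ) = Σ_j h_j · exp(−‖θ − c_j‖² / (2 w_j²)),

a sum of Gaussian bumps (heights `h_j > 0`, widths `w_j > 0`), optionally
multiplied by the positive gate `exp(env_gate · mean(env))`.  Per-bump
contributions are exposed as fitness components; the scalar pools them by
summation (the simplest monotone, non-negativity-preserving pooling —
the theory states only that components are transformed into the scalar).
Time is discretized with a fast step `dt` (default 0.01 time units); all
slow processes (environment, operator drift) have timescales ≫ `dt`.

**Estimator bank.**  A component estimator is the map
`x_i = φ(A u_i + b)` with `A ∈ ℝ^{n×m}`, bias `b`, and a strictly
increasing coordinatewise nonlinearity `φ`.  The default `φ` is
`softplus(z) + 0.2 z`: bijective on ℝ with slope in (0.2, 1.2), so the
square components are invertible on their range and stay well
conditioned.  Square matrices are drawn from a Gaussian ensemble and
resampled (then spectrally clipped) to respect a condition-number cap
(default 10⁴; fixtures use tighter caps).  A `blackbox` component kind
carries the same map but promises consumers forward evaluation only, so
the feedback loop is the only way to invert it — the honest test of the
inversion mechanism.  Parameters drift as an entrywise OU process around
their construction values (timescale `drift_timescale`, stationary sd
`drift_sd`), making the operator nonstationary but locally frozen.
Component outputs aggregate to the non-negative scalar estimate through
mean → weighted sum → softplus squash; this aggregation rule is a choice
the theory leaves open.

**Feedback inversion.**  The inversion circuit places the forward
operator `S` in the feedback path of a high-gain amplifier: at
equilibrium `q = g·B(p − S q)`, so the residual `p − S q` is forced to
`O(‖q‖/g)` and `q → S⁻¹p` as the gain grows, using only forward
evaluations.  For the linear scalar `S: q ↦ s q` the equilibrium is
exactly `q* = g p / (1 + g s)`, the closed form used throughout the
tests.

Two realizations:

* *fixed-point mode* iterates `q ← (1−η) q + η·g·B(p − S q)` to
  equilibrium within one time step.  The raw iteration contracts only
  when `η (1 + g‖S′‖) < 2`, which no fixed `η` satisfies across gains;
  the implementation therefore rescales the nominal damping by the
  estimated loop gain, `η_eff = min(η, 2η/(1+L))` with
  `L = g‖(B·S)′(0)‖` from a finite-difference linearization.  This
  leaves the equilibrium untouched and makes `damping` (default 0.5) a
  fraction of the stability limit.  A residual-growth safeguard halves
  the step a few times before declaring divergence, since a nonlinear
  `S` can be steeper away from the origin than at it.
* *dynamical mode* integrates
  `q ← q + relax_step·(−q + g·B(p − S q(t−delay)))` with an explicit
  transmission delay in the feedback path.  This mode is deliberately
  *not* stabilized: its purpose is to exhibit the instability of
  high-gain feedback under delay.  The default `relax_step = 0.002`
  keeps the canonical scalar cases inside the no-delay stability region
  `relax_step·(1+g s) < 2`.

**Preconditioner.**  Negative feedback through `S` alone (`B = I`) is
stable only when the linearization of `S` has spectrum in the right
half-plane.  That holds for scalar monotone maps but fails for generic
random matrices, at every step size — an instability of the circuit
itself, not of the discretization.  The default (`preconditioner="auto"`)
therefore uses `B = I` for scalar operators and the gradient-like
transpose preconditioner `B = J₀ᵀ/σ_max(J₀)²` (J₀ the finite-difference
linearization of `S` at 0) otherwise, which makes `g·B·S′` positive
semidefinite and hence stabilizable at any gain, and also covers
non-square operators (minimum-distance targets).  `B` is built from
forward evaluations only; no analytic inverse enters the loop.  The
analytic inverse of the structured family, `A⁻¹(φ⁻¹(p) − b)`, exists in
the package purely as a test oracle.

**Two-stage loop.**  One component instance alternates between stage 1
(forward, writing the `x` buffer) and stage 2 (in the feedback path,
writing the `û` buffer).  Buffer discipline is structural: each stage
can touch only its own buffer, and a diverged inversion leaves the `û`
buffer holding its previous value (sample-and-hold on failure).  Within
a cycle both stages see byte-identical parameters (asserted by a
parameter-snapshot hash); drift applies at cycle boundaries.  The option
`drift_within_cycle` instead drifts between the two stages, reproducing
the small error caused by the two roles not being evaluated at exactly
the same time; the per-cycle round-trip error is then judged through the
*stage-1* operator snapshot, which is where that nonstationarity error
lives.  The cycle period defaults to 0.1 time units (≈10 switches per
unit time — a parameter echoing cortical switching rates, not a claim);
duty 0.5.

**Internal dialogue.**  In the self-feeding mode the stage-2 output
becomes the next stage-1 input.  A structural fact discovered during
implementation and worth recording: the composed map
`û ← invert(apply(û))` has an *exact fixed point at the origin that does
not depend on the component parameters* (at the origin the forward image
equals the inversion target, so the finite-gain bias vanishes).  With a
stationary component the û sequence therefore contracts monotonically to
that fixed point at rate ≈ `g·s/(1+g·s)` per cycle; with a drifting
component the drift modulates the *trajectory*, not the asymptote.  The
drift-response property (change variance ∝ `drift_sd²`) is consequently
measured on the deviation from the seed-paired stationary baseline,
where the linear response is clean (measured log-log slope ≈ 1.0).

**Dialogue.**  The sender runs its two-stage loop, transmits `û`
through a channel (`u' = gain_loss·û + noise`), and the receiver applies
its own, similar estimator to reconstruct `x' ≈ x`.  Receiver similarity
is modelled by perturbing every parameter array with zero-mean noise of
relative RMS size `delta`.  The reply protocol: the listener uses the
received `u'` as its own next stage-1 input (the theory does not specify
the reply map; this is the simplest closure of the loop).  The
reconstruction error decomposes into finite-gain, channel and mismatch
contributions, each individually monotone; the ideal case (identical
agents, perfect channel, gain 10⁵) reconstructs to ~10⁻⁴.

**Variance-modulated drift.**  Per fast step the organism forms the
estimate `x = max(0, f + ε)`, `ε ~ N(0, estimate_noise_sd²)`, and takes
a random form step `θ ← θ + σ(x)·ξ` with isotropic standard-normal `ξ`:
direction fully random, only the magnitude controlled.  The modulation
is Hill-shaped by default,

    σ(x) = sigma_max / (1 + (x/x_half)^steepness),

strictly decreasing with σ(0) = sigma_max.  *Fitness-to-be* `f⁺` is the
trailing-window mean of `f` over the final 20% of the horizon.  Using
noisy truth rather than the full sense→estimator chain isolates the
mechanism: estimator quality becomes a single knob
(`estimate_noise_sd`), which is exactly the quantity the quality→f⁺
claim perturbs.  A full-chain mode exists for integration scenarios.

**Canonical drift experiment.**  Two bumps (heights 1.0 and 0.6, widths
1.0, centers (±2, ±2)), θ₀ ~ N(0, I), horizon 4000 steps, 20 paired
seeds.  The modulation parameters were fixed by a pilot design pass
(independent seeds, before freezing): with a too-shallow modulation
(x_half = 0.3, steepness = 2) the high-fitness trap is metastable —
walks find the peaks but escape, the median f⁺ is near zero and the
20-seed experiment has coin-flip power.  The frozen values
sigma_max = 0.25, x_half = 0.15, steepness = 4 give a stable trap
(median f⁺ ≈ 0.4 at zero estimate noise) and replication-stable
inference (contrast and trend p ≤ 10⁻³ across pilot replications).  The
control condition repeats each seed with a *constant* σ equal to the
modulated run's time-averaged σ, so mean step size is equalized and
only the x-dependence differs; inference is a one-sided paired
sign-flip permutation test (10⁴ flips).  The quality sweep runs
`estimate_noise_sd ∈ {0, 0.5, 1, 2, 4}` at 20 seeds per level and tests
the negative trend of f⁺ with Spearman's ρ against a permutation null
(2000 shuffles).

**Quality metrics.**  Estimation error = windowed time average of
`‖x − f‖`; inversion error = `‖x_i − X_i(û_i)‖`; each quality is the
reciprocal of its error with a documented floor of 10⁻¹² (reported
alongside).  Norms: absolute value / L2 by default, L1 offered.  The
expectation in the error definitions is realized as a finite-window time
average — the theory does not fix the ensemble.

## Reproducibility and problem sizes

One root seed; each module draws from an independent named stream
derived via SeedSequence spawn keys (`fitloop.rng.stream`), so any
sub-experiment can be reproduced in isolation.  All stochastic tests and
the acceptance script are seeded; traces are bit-reproducible given
(config, seed).

Simulation sizes used by the test suite and acceptance script (drift
horizon 4000 steps; 20 seeds per condition; 50 random components for the
oracle comparison; 10³ cycles for the loop-discipline check; delay grid
up to 400 steps) were chosen so the whole battery runs on a single CPU
in minutes while keeping Monte-Carlo error well below the asserted
margins.

## What the synthetic world does and does not show

The generator emulates: smooth multi-peak fitness over a low-dimensional
form space, slow operator and environment nonstationarity, additive
sensing and channel noise, and similar-but-not-identical communication
partners.  It does not emulate: high-dimensional or time-varying
dimensionality of the world, ecological interactions, reproduction or
selection between agents, learned estimators, or any neural
implementation detail.  Passing tests therefore show that the *mechanisms*
— high-gain inversion, switched dual use, channelled reconstruction,
variance-modulated drift — behave as the theory claims under clean,
controlled conditions; they do not show that real organisms implement
them.

## Known limitations

* The fixed-point mode's step normalization uses a linearization at the
  origin; operators far steeper away from the origin can still require
  the safeguard halvings, and pathological non-monotone operators are
  out of scope.
* The transpose preconditioner converges at a rate set by the squared
  condition number of the linearization (Landweber-like); very
  ill-conditioned components invert slowly.
* The internal dialogue's parameter-independent fixed point means
  long-run û carries no information about the drifting operator; only
  transients do.  This is a property of the composed map, not a bug.
* `f⁺` depends on the window convention; the trailing-20% default is
  reported with every trace.
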