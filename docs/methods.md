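# Methods

## Scope

`ionfit` estimates the parameters of Hodgkin–Huxley-type potassium current
formulations — the rapid (I_Kr), ultra-rapid (I_Kur) and slow (I_Ks) delayed
rectifiers of the Courtemanche et al. human atrial myocyte model — from
multi-sweep step voltage-clamp current recordings, and provides the
machinery to study the estimators themselves: exact trace simulation,
synthetic data with calibrated noise, four optimizers (trust-region-
reflective least squares, constriction particle swarm, their sequential
combination, and a per-iteration hybrid), and repeated-run experiment
designs with distributional summaries.

## Current formulations and the analytic simulator

Each current factors as `I = f(V, p) · Π_g x_g^e_g` where `f` collects the
conductance, driving force `V − E_K`, and any instantaneous
voltage-dependent factors, and each gate `x_g` obeys
`dx/dt = (x_∞(V) − x)/τ(V)`. Under a step protocol the voltage is piecewise
constant, so within each segment the gate relaxes exactly exponentially:
`x(t) = x_∞ + (x_0 − x_∞)·exp(−(t − t_0)/τ)`. The simulator initializes each
gate at its steady state for the holding voltage, propagates these exact
updates across segments, and evaluates the current on the 2 ms sampling
grid. No numerical ODE integration appears in the production path; a
stiff-solver integration at tight tolerance serves as the independent test
oracle (agreement ≤ 1e−8 pA/pF in the suite).

Conventions worth stating:

* Samples lie at `t = 0, 2, …, 820` ms inclusive — 411 per sweep, 5343 over
  the 13 sweeps of the standard protocol (20 ms at −80 mV, 400 ms at a step
  voltage −70 … +50 mV in 10 mV increments, 400 ms at −110 mV; 10.66 s in
  total).
* A sample on a segment boundary takes the *new* segment's voltage; gate
  values are continuous there either way.
* `E_K = −86.8 mV` (Nernst voltage for [K⁺]o = 5.4 mM, [K⁺]i = 139 mM at
  310 K), a fixed constant, never estimated.
* Removable singularities of the rate laws (`u/(1 − e^(−u/s))` at `u = 0`)
  are evaluated through `expm1` with an exact-zero guard returning the
  series limit `s`; this is accurate without a wide guard band. When the
  numerator and exponential voltage shifts of a rate differ (they are
  independent parameters, see below) the singularity is genuine; the
  simulator then reports the parameter vector as outside the model domain,
  and optimizers score such points with `+inf` (swarm) or a huge residual
  (trust region) rather than aborting.
* The fitting hot path runs in a compiled (numba) kernel; a plain-numpy
  reference implementation of the same arithmetic is kept and the two are
  cross-checked in the test suite. Both raise on invalid kinetics
  (`τ ≤ 0` or non-finite rates at any protocol voltage).

## Adjustable parameters

Every numeric constant of the current and gating equations is adjustable.
Additive parameters are voltage shifts (mV, varied by an absolute offset);
all others — conductances, rate scale factors, slope factors, dimensionless
denominator offsets — are multiplicative (varied by a factor). Three
conventions complete the enumeration:

* each rate function carries an explicit multiplicative scale, set to 1
  where the original formulation has none (the two I_Kur inactivation-gate
  rates);
* each current carries an overall conductance factor (for I_Kur, whose
  conductance is voltage-dependent, an extra unity scale — deliberately
  redundant with the two conductance terms, mirroring the practical
  non-identifiability of several I_Kur parameters);
* in activation rates of the form `A·u/(1 − e^(−u/s))` the voltage shift is
  one shared parameter, while in deactivation rates `A·u/(e^(u/s) − 1)` the
  numerator and exponential shifts are two independent parameters with
  equal base values.

This yields 12 parameters for I_Kr, 25 for I_Kur, and 10 for I_Ks. Gate
exponents (x_r¹, u_a³·u_i, x_s²), the I_Kur temperature factor K_Q10 = 3,
and the I_Ks time-constant factor ½ are fixed model constants. The I_Ks
steady state is the square root of a Boltzmann sigmoid, so the squared gate
has a first-power Boltzmann equilibrium.

A consequence of the independent deactivation-rate shifts deserves record:
in the wide I_Kr search space the exponential shift can saturate far below
its base value, making the deactivation rate effectively linear in voltage
over the protocol range. This creates a strong near-degenerate local
minimum of the clean-data objective around SSE ≈ 5×10⁻⁵ (pA/pF)² that
captures most random-start trust-region runs and, at desk-scale budgets,
the hybrid swarm as well. The global minimum (SSE = 0 at the generating
parameters) remains strict and is recovered when a particle reaches its
basin. See “Known limitations”.

## Search spaces and objective

Narrow bounds: additive `b ± 60`, multiplicative `0.1b … 10b`. Wide bounds:
`b ± 120` and `0.01b … 100b`. Bounds are sorted after scaling so they stay
ordered for negative bases; narrow boxes are nested in wide ones by
construction. The objective is the unweighted sum of squared errors between
simulated and observed current density over every sample of every sweep —
no phase exclusions, no per-sweep weights, no robust losses.

## Synthetic data and noise

Ground-truth traces are simulated at the published base parameters; the
estimators see only the trace (the generating vector travels in metadata
for scoring). Additive Gaussian white noise is calibrated as
`σ² = P_signal / 10^(SNR/10)` with `P_signal` the mean squared current
pooled over all samples and sweeps — one SNR figure per dataset, noise
i.i.d. across time and sweeps. The study grid uses one noisy copy each at
10, 20, 35 and 60 dB beside the clean trace. Noise generation is seeded and
bit-reproducible. For the clean I_Kr trace the noise energy at 10 dB
computes to ≈ 2.8×10¹ (pA/pF)², the floor that any fit against the noisy
input approaches. What the generator does *not* emulate: colored noise,
baseline drift, capacitive transients, leak currents, series-resistance
artifacts — so passing tests say nothing about robustness to structured
artifacts of real recordings.

## Optimizers

**Trust-region-reflective (TRR).** Bounded nonlinear least squares on the
residual vector, delegated to `scipy.optimize.least_squares(method="trf")`
behind a wrapper fixing the stopping semantics: step-norm tolerance
(`p_tol = 1e−11`), cost-change tolerance (`f_tol = 1e−11`, applied by the
backend relative to the current cost), iteration and function-evaluation
budgets (1e5 / 5e5), and an optional exact small iteration cap for hybrid
use. The backend counts at least one residual evaluation per iteration
(finite-difference Jacobian evaluations are not counted), so capping
evaluations at K guarantees at most K iterations; this mapping enforces
both `max_iter` and the cap, and is exercised on toy problems in the suite.
The gradient-norm criterion is disabled; the backend's status codes are
translated to exactly one of {pTol, fTol, maxIter, maxFunEval,
iteration_cap}, reporting pTol when both tolerances fire in one step.
Jacobians are forward finite differences with relative step 1e−8. Points
where the model is undefined are scored with a huge constant residual so
the trust region retreats instead of aborting.

**Particle swarm (PSO).** Clerc–Kennedy constriction form with
φ₁ = φ₂ = 2.05, χ = 2/(φ − 2 + √(φ² − 4φ)) ≈ 0.73, per-component uniform
draws, zero initial velocities, uniform random initial positions costed as
iteration 0, synchronous personal/global best updates at each iteration's
end. A component leaving the box re-enters at a uniform random point within
25% of the parameter range from the crossed boundary — the swarm's lasting
source of exploration. One master seed spawns an independent RNG stream per
particle, so evaluations could run in any order or in parallel without
changing the trajectory.

**Two-stage.** One full PSO run; the best M = 12 distinct personal bests
are refined independently by TRR to convergence and re-ranked.

**Hybrid.** In every swarm iteration each particle's velocity is updated,
the candidate position is boundary-enforced, refined by K capped TRR
iterations, and the velocity is redefined as the effective displacement
(new − old position) before the position update. After L iterations the
top-M personal bests are TRR-refined to convergence (the terminal stage;
on a converged swarm it changes the cost by well under 1%). With K = 0 the
hybrid is bit-identical to pure PSO at the same seed — the two share one
engine, which is also why the engine applies the effective-displacement
rule uniformly (for unrefined in-bounds candidates it coincides with the
plain velocity). Budget presets: low (K5, L250, N96), medium (K10, L500,
N192), high (K20, L1000, N384); `tiny`/`small` are reduced desk-scale
presets for quick studies, not part of the reference grid.

## Experiment designs

Plans run 25 repetitions by default, each with a seed derived from the
master seed (reproducible, below 2³¹). Summaries report order statistics
of final costs and termination-reason frequencies. The noise study reports,
per (SNR, algorithm) cell, both the optimized cost against the noisy input
and the squared error against the clean ground truth, next to the
noise-energy lower bound. Swarm-size sweeps double N per step and fit
log₁₀(median cost) against log₂(N) — the coordinate system such sweeps are
plotted in. Wall-clock times are recorded but never asserted.

The test suite runs reduced problem sizes chosen once: 2–5 random vectors
per current in unit-level oracle checks (20 per current in the acceptance
tier), 25 repetitions where the reference design is cheap (TRR, PSO), one
seed of the reference `medium` hybrid budget for the I_Kr recovery check
(seed count, not optimizer budget, is the scaled-down axis there — smaller
swarms are known to stall in the local minimum described above), and a
labeled desk preset for the I_Kur hybrid check, whose reference budget is
hours-scale. Test docstrings are explicit where a reduced size changes
what a passing test demonstrates.

## Known limitations

* The parameter enumeration (which constants are adjustable, and the
  tied/untied shift conventions) is the package's own documented rule; a
  different enumeration with the same counts would change the optimization
  landscape. Under this rule the wide-space I_Kr objective has the strong
  near-degenerate local minimum described above: desk-scale hybrid budgets
  frequently terminate there (SSE ≈ 5×10⁻⁵) rather than at the global
  minimum, and random-start TRR medians on clean data are correspondingly
  far below what a landscape without that minimum would produce.
* The cost-change tolerance is relative (backend semantics), so runs
  polish further at small costs than an absolute reading of the same
  tolerance would; termination-reason frequencies are sensitive to this.
* Measured-data support is limited to reading delimited trace exports;
  no preprocessing (leak subtraction, capacitance compensation) is
  provided.
* I_Ks is implemented and simulated like the others but the reference
  study grid exercises it only through unit-level checks; it has no
  synthetic benchmark of record here.
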