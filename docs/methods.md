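# Methods

## Model class

A community is a set of biomass densities `N` governed by

- producers: `dN_i/dt = N_i (r_i − s_i N_i) − Σ outgoing fluxes`
- consumers: `dN_j/dt = Σ ε F_in − Σ F_out − d_j N_j − s_j N_j²`

with `r` the intrinsic growth rate (per time), `d` the consumer death
rate (per time, entered positive), `s` intraspecific density dependence
(per density per time) and `ε ∈ (0, 1]` the conversion efficiency.  By
default producers are logistically self-limited and consumers take linear
(density-independent per-capita) mortality; this is the minimal closed
three-species chain that admits both stable points and limit cycles.  A
nonzero consumer `s` is supported and is occasionally needed: with purely
linear consumer mortality the community matrix acquires structural zeros
at equilibrium (the top consumer's per-capita growth vanishes), which
annihilates the density-mediated net-effects sensitivities on a chain.

Trophic links carry one of three functional responses for the
per-consumer consumption rate of resource `R` by consumer `C`:

- `linear` (type I): `a R`
- `holling2`: `a R / (1 + a h R)`
- `holling2_interference` (Beddington–DeAngelis): `a R / (1 + a h R + w C)`

Total flux is the per-consumer rate times `C`.

## Trophic interaction modifications

A TIM multiplies exactly one functional-response parameter of one link by
a term `f(c, K)` of the modifier density `K`:

| form | f(c, K) | character |
| --- | --- | --- |
| `exponential` | `exp(c K)` | unbounded, sign-symmetric, always positive |
| `linear_clipped` | `max(0, 1 + c K)` | linear, bounded below at 0 |
| `hyperbolic` | `1 + c K` if `c ≥ 0`, else `1/(1 + |c| K)` | saturating decay for negative effects |
| `sigmoid` | `1 + c K^s/(K^s + m^s)` | thresholded; midpoint `m > 0`, steepness `s > 0`, requires `c > −1` |

These four were chosen to span the unbounded, bounded-below, saturating
and thresholded response shapes used across the modelling literature;
`exponential` is the default because it is sign-symmetric, strictly
positive, and the identity at `c = 0`.  The hyperbolic form is made
piecewise in the sign of `c` so a single signed parameter covers
amplification and attenuation while remaining strictly positive for all
`K ≥ 0`.  Every form returns exactly 1.0 at `c = 0`, which makes the
null-TIM model bit-for-bit identical to the TIM-free model (an exact
invariant, tested as such).

Simultaneous TIMs on one link and parameter combine multiplicatively;
the combiner is a single replaceable function
(`combined_modification(..., combiner=...)`) because multiplicative
combination is a hypothesis, not a law.  When a TIM targets the handling
time the effective value is `h·f`; for interference, `w·f`.
Modification of modifications is out of scope.

TIMs are `dynamic` (modifier is a state variable; its feedback enters the
Jacobian) or `forced` (the modifier density is a fixed cue, matching
experiments that impose a modification without coupling the modifier to
the web).  A forced TIM at cue density `x` produces the same modification
term as a dynamic TIM whose modifier happens to sit at density `x`.

## Equilibria and matrices

`find_equilibrium` is Newton-type root finding (scipy `hybr`) with the
exact symbolic Jacobian supplied.  The interior root is the target:
iterates are taken in log-density space (`z = log N`), which keeps every
step strictly positive and avoids spurious clipped roots; a linear-space
clipped solve runs alongside to pick up boundary (extinction) roots, and
when neither start converges to a feasible root the flow itself is used —
a short integration (t = 50) from the start lands inside the Newton basin
of any attracting interior state.  Up to 20 seeded log-uniform random
restarts (densities 10^±2) repeat this recipe.  Results are ranked
converged > feasible > small residual; non-convergence is reported in the
result (`converged=False`), never raised.  One exception: a guess that is
already a root to tolerance (e.g. the origin) is returned as-is, so
extinction states remain reachable on purpose.

Defaults: residual tolerance 1e−10 (max-norm of the rates), feasibility
threshold 1e−8 on every density (separates interior points from the
extinction boundary), stability margin 1e−7 on eigenvalue real parts
(classifies the neutrally stable Lotka–Volterra centre as `marginal`
rather than forcing a decision).

The community matrix `A` (entry `(x, y) = ∂Ṅ_x/∂N_y`) is computed
symbolically (sympy, lambdified and cached per model) or by central
finite differences with step `h = ε_mach^{1/3} · max(|x|, 1)` per
coordinate — the standard optimal first-derivative scaling; numerical
differentiation is always cross-checked against the symbolic route in
tests because repeated differentiation propagates error.  States on the
zero-density clamp fall back to one-sided differences with a warning.
The net-effects matrix is `−A⁻¹`; a condition number above 1e12 raises a
singularity error rather than returning garbage.

## Metric conventions

- **Flux change** evaluates the target link's flux twice at the *same*
  densities: once as-is and once with the focal TIM's term forced to 1.
  Other TIMs on the link and the modifier's trophic role stay active, so
  the metric isolates one modification and composes under multiplicity.
  Orientation is unmodified/modified: a strengthening TIM (term > 1)
  gives a ratio < 1.
- **B_CR change** is the ratio of the resource's equilibrium density with
  the TIM to that with its strength zeroed.  Both solves use the same
  initial guess and restart policy and must converge to interior-feasible
  points, otherwise the metric fails loudly naming the failing side.  On
  the cue-forced Lotka–Volterra model this ratio has the closed form
  `exp(−c K)`, which the tests verify to 1e−6 across `c ∈ [−1, 1]`,
  `K ∈ {0.5, 1, 2}`.
- **Derivative metrics** (`∂A/∂K`, `∂(−A⁻¹)/∂K`) are direct partials: the
  modifier coordinate is perturbed with all other densities held fixed,
  with no re-equilibration.  Equilibrium-shift responses are deliberately
  captured elsewhere (the sweep).  The net-effects derivative uses
  `d(−A⁻¹)/dK = A⁻¹ (∂A/∂K) A⁻¹`.  This pair of metrics operationalises
  the direct-versus-density-mediated distinction: at `c = 0` the direct
  sensitivity is identically zero while the net sensitivity is generically
  nonzero whenever the modifier is trophically connected.
- **CV of modification** integrates the term along a trajectory window
  with the trapezoid rule (so the estimate converges with sampling
  density) and returns sd/mean.  The default window drops the first half
  of the span as transient — a convention, overridable per call.  A mean
  below 1e−12 raises (CV undefined).
- `compute_all_metrics` fills one report per context (`equilibrium`,
  `state`, `trajectory`); inapplicable fields are absent (`None`), and
  per-metric failures land in an error record instead of aborting the
  report.

## Dynamics

`simulate` wraps scipy's `solve_ivp` (LSODA default, rtol 1e−8 /
atol 1e−10) with densities clamped at zero; clip events are counted in
`solver_info`.  `classify_dynamics` integrates to `t_max = 1000`,
discards the first half, and inspects the late window: divergence above
1e8 density units; extinction below 1e−8; a relative peak-to-trough
amplitude under 1% per species indicates a fixed point, confirmed
against a converged stable equilibrium near the endpoint; sustained
oscillation around an unstable interior equilibrium is `cycling`, around
a marginal one (the neutral Lotka–Volterra centre) `marginal`.  The 1%
amplitude threshold is deliberately coarse — robust to solver ripple at
the default tolerances.

`static_replacement` removes a TIM and multiplies the affected parameter
by the term evaluated at a reference state (normally the interior
equilibrium).  The replaced model's vector field agrees with the
original's at that state exactly, so the equilibrium is preserved by
construction; the Jacobians differ because the modifier column's feedback
is gone.  This makes precise when a dynamic TIM is genuinely needed and
when a statically changed functional response suffices.

`stabilization_scan` sweeps a TIM strength across a grid on a cycling
system, classifying the dynamics and recording the leading eigenvalue of
the interior equilibrium at each point; the two detectors must agree on
where the cycle collapses.

## Demonstration systems

All demo parameters are package constants chosen (and re-verified by the
test suite) so that each system has a feasible, locally stable interior
equilibrium at `c = 0`.  They are illustrative communities, not fits to
data.

- `chain_linear`: plant–herbivore–predator, linear consumption.
  `r = 1`, plant `s = 0.05`, `a₁ = 0.5`, `a₂ = 0.4`, `ε = 0.5`,
  `d₁ = d₂ = 0.1`; exponential TIM of the predator on the
  plant–herbivore attack rate, default `c = −0.1` (predation risk
  suppressing herbivore foraging).  Interior equilibrium at `c = 0`:
  `(15, 0.5, 9.125)` (closed form, used as a solver oracle).
- `chain_nonlinear`: same topology with Holling II links.  `r = 1`,
  plant `s = 0.13`, `a₁ = 0.3`, `a₂ = 0.6`, `h₁ = h₂ = 0.2`, `ε = 0.5`,
  `d₁ = 0.25`, `d₂ = 0.13`, TIM as above.  These constants were selected
  so that, over the sweep grid `c ∈ [−1, 1]`, every point keeps a feasible
  equilibrium and the metric suite displays its characteristic divergence:
  the modification term responds monotonically to `c` while several
  metrics evaluated at the shifted equilibria do not.
- `aphid_parasitoid`: two hosts sharing one parasitoid, mass-action
  parasitism (`a₁ = 0.1`, `a₂ = 0.12`, `ε = 0.5`, `d = 0.1`), with an
  exponential TIM from host 1's density onto the parasitoid's attack on
  host 2 (`c = −0.2`).  The hosts are given logistic self-limitation
  (`r = 1`, `s = 0.1`): with purely exponential host growth a single
  parasitoid cannot generically regulate two hosts, so no robust interior
  equilibrium exists at `c = 0`.  Which functional-response parameter the
  TIM targets is exposed as configuration
  (`tims.T1.affected_parameter`), not asserted.
- Stabilisation demo: a Rosenzweig–MacArthur pair enriched past its Hopf
  point (`r = 1`, `s = 0.05` so carrying capacity 20, `a = 1`, `h = 0.5`,
  `ε = 0.5`, `d = 0.4`) with an exponential TIM in which the consumer's
  own density depresses its attack rate.  On the shipped grid
  `c ∈ [−0.8, 0]` the system cycles for `c ≳ −0.2` and collapses to a
  stable point for `c ≲ −0.3`, with the leading eigenvalue crossing zero
  in between — verified by the scan itself, not assumed.

## Synthetic data

`generate_random_chain` draws three-level chains with parameters uniform
on configurable ranges (growth 0.5–1.5, producer self-limitation
0.02–0.1, attack 0.2–0.8, efficiency 0.3–0.7, mortality 0.05–0.15, TIM
strength −0.5–0.5) and rejection-samples until the `c = 0` model has a
feasible stable interior equilibrium.  It emulates the *population-level*
setting the framework targets: deterministic ODE communities with known
structure.  It does not emulate observation error, demographic
stochasticity, or model misspecification, so passing property tests
demonstrate the mathematics of the framework, not its robustness to the
noise of real field data.

`generate_fr_experiment` simulates short-term functional-response
experiments over a prey-density × modifier-density design.  Observed
rates are the true surface times mean-one lognormal noise
(`σ² = ln(1 + CV²)`, location `−σ²/2`), so the expected observation
equals the truth and synthetic experiments are unbiased.  The default
study uses 5 prey levels × 5 modifier levels × 10 replicates (n = 250) at
CV = 5% — a level of replication a motivated lab study could reach.  The
surface is evaluated per consumer, so consumer-interference responses are
not part of the experiment generator.  `fit_tim_model` estimates
(attack rate, handling time, TIM strength) by multi-start trust-region
least squares with box bounds (`a > 0`, `h ≥ 0`, `c` unbounded except
`c > −1` for sigmoid); standard errors come from the Gauss–Newton
covariance at the optimum.  Noiseless data are recovered to ≲1e−6
relative; at the default noisy design the median relative error of the
strength estimate is ~1%.

## Sweeps

`sweep_tim_parameter` visits the strength grid from 0 outward in each
sign direction, starting every solve from the previous feasible
equilibrium (continuation maximises convergence); non-converged or
infeasible points are flagged and their metric fields left absent rather
than extrapolated.  The full metric report — including the B_CR change
against the re-solved `c = 0` model — is evaluated at each resultant
equilibrium.

## Known limitations

- Delayed TIMs, cue-state variables, stochastic dynamics and stage
  structure are out of scope; modifications are instantaneous functions
  of present densities.
- Derivative metrics linearise: they describe the system only near the
  evaluation state.
- `classify_dynamics` is a bounded-horizon heuristic; it does not detect
  chaos or compute Lyapunov/Floquet spectra, and very long transients can
  in principle be misread (the demo systems are verified against doubled
  integration spans).
- The sweep tracks one equilibrium branch by continuation; it does not
  switch branches or track folds beyond flagging lost feasibility.
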