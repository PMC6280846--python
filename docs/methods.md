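# Methods

## Model and assumptions

A host's immune status is a scalar antibody level y > 0.  Between exposures
it follows the waning flow π(t, y) = e^{−wt}·y (solution of dy/dt = −w·y);
exposures arrive as a homogeneous Poisson process with force of infection Λ
and instantly boost the level through f(y) = y(1 + σ₂/y)^σ₁.  The model
assumes: exposure rate independent of immune level and age; instantaneous
clearance (boost duration negligible on the waning time scale); no mortality
coupled to infection; all hosts share the same parameters.  The canonical
parameter family is the only one with first-class support: every
integrability and monotonicity property the solvers rely on is verified for
it by `check_conditions`, and the closed forms below are specific to it.

Derived constants: critical level y_c = (σ₁−1)σ₂ (minimizer of f), boost
floor f(y_c) (lower edge of the post-exposure support), asymptotic increment
δ = σ₁σ₂, and the waning-time parametrization T(y) = (1/w)·log(y_c/y) with
e^{−ΛT(y)} = (y/y_c)^{Λ/w}.

### Parameters

| name | meaning | units | canonical default |
|------|---------|-------|-------------------|
| Λ (`lam`) | force of infection | exposures / time | 1.5 |
| w | waning rate | 1 / time | 1.0 |
| σ₁ | boost shape (> 1) | — | 2.0 |
| σ₂ | boost scale | immune level | 1.0 |
| y_b | immune level at birth | immune level | 4.0 |

The canonical preset gives y_c = 1, f(y_c) = 4, f(f(y_c)) = 6.25, δ = 2 —
nice round landmarks that make hand verification easy and that satisfy all
sufficient conditions (in particular Λ > w(σ₁−1), the tail-integrability
margin).

## Sufficient conditions (`check_conditions`)

Advisory, never raising; each entry carries its numerical witnesses.

* `expected_jump_contraction` — f(π(ρ/Λ, y)) < y above a computed anchor
  level: boosting after a discounted mean exposure wait loses ground high
  up the axis (ρ defaults to 0.9; any ρ ∈ (0,1) works for g = −wy).
* `foi_exceeds_waning_gap` — Λ > w(σ₁−1), the sufficient condition for the
  post-jump tail to be integrable, and the package's summary
  `tail_integrability` flag.
* `postponed_jump_monotonicity` — f′(y)g(y)/g(f(y)) < 1 everywhere
  (postponing a jump lands higher).  For the canonical family the closed
  form f′(y)g(y) − g(f(y)) = wσ₁σ₂(1+σ₂/y)^{σ₁−1} > 0 settles it; both the
  grid ratio and the sign witness are reported.
* `alpha_delta_subcritical` — α(y)·δ < 1 near the top of the probe grid,
  the local characteristic-equation heuristic for tail decay.

Solvers that need a condition consult the report and refuse with the
condition's name; the conditions are sufficient, not necessary, so checking
is deliberately decoupled from solving.

## Simulator

Event-driven and exact: exponential(Λ) gaps, closed-form waning between
jumps, no time discretization.  Levels are stored at jumps only and
evaluated anywhere by the flow.  Ensemble routines exploit that, given k
exposures in [0, t], the exposure times are the order statistics of k
uniforms: hosts are grouped by Poisson-drawn count and pushed through the
jump chain vectorized, which makes 10⁵-host ensembles take well under a
second.  Per-trajectory substreams come from `SeedSequence(seed, spawn_key)`
so single trajectories are reproducible independently of ensemble order.
First-passage excursions are capped at 10³/Λ time units; the capped fraction
is reported and the estimate flagged above 10⁻³ (finiteness of the mean
passage time is not guaranteed a priori for all parameters).

## Generation-expansion kernels

* k = 0: atom at π(t,y), weight e^{−Λt} (exact).
* First-jump kernel: the post-boost level as a function of the jump time
  first decreases then increases, so the time set reaching any interval
  [a,b) is a union of at most two intervals with endpoints located exactly
  through the inverse branches of f and the transit time; the exponential
  density is then integrated by adaptive quadrature on each piece.
* k = 1: the jump-time → landing-level map s ↦ π(t−s, f(π(s,y))) is strictly
  increasing under `postponed_jump_monotonicity` (its derivative has the
  closed form g(η)·(f′(u)g(u)/g(f(u)) − 1), u = π(s,y)).  Its inverse S is
  found by Brent root finding (tolerance 10⁻¹⁴ in s) and the one-jump
  density is q¹ = dS/dη, evaluated analytically as 1/η′(S(η)).  Interval
  probabilities use S directly and are quadrature-free.  When the
  monotonicity condition fails the package refuses: a non-monotone landing
  map would need multi-branch inversion and no construction is provided.
* k ≥ 2: conditional Monte Carlo (uniform order statistics), histogrammed on
  a geometric grid, with the **exact** Poisson generation mass
  (Λt)^k e^{−Λt}/k! attached analytically.  Truncation level K_max is chosen
  from the exact Poisson tail, giving a certified error bound; tolerances
  unreachable with K_max ≤ 50 produce an explicit failure that reports the
  achievable bound.  The exact k-fold nested quadrature is retained only as
  a test oracle at k = 2.

`propagate_density` pushes a measure through Q_t: atoms are transported
exactly (weight factor e^{−Λt}), a density part is transported by the exact
change-of-variables formula with cell masses taken from the input
cumulative (mass-exact), the one-jump image of atoms uses q¹, and all
remaining jump parts use seeded Monte Carlo with samples clipped to the
output grid so the mass ledger stays exact.

## Measures

`DiscretizedMeasure` holds atoms plus a piecewise-linear density on a
(typically geometric) grid.  A measure may carry an explicit cumulative
array overriding trapezoid cell masses — used wherever closed-form or
root-finding-exact cumulatives are available (the one-jump kernel via S, the
next-generation image, MC histograms).  Distances between measures are
computed from per-cell mass differences on the union grid plus
location-matched atom differences; this converges to the L1/total-variation
distance as the grid refines and is robust to the singularity described
next.

## Stationary post-jump density φ

The fixed point of the next-generation operator K is constructed, not
iterated.  With a free constant c (the survival-weighted total
∫(η/y_c)^{−Λ/w} φ dη, set to 1 during construction and removed by the final
normalization — the result is exactly invariant to it):

* on the initial interval [f(y_c), f(f(y_c))] both φ and its cumulative are
  closed-form in the inverse branches of f;
* beyond it φ satisfies a linear delay integral equation whose memory term
  ∫_{f₊⁻¹(y)}^y φ only looks backward (f₊⁻¹(y) trails y by at least δ for
  the canonical family), so it is stepped forward by implicit trapezoid
  product integration.  When the memory window is shorter than one grid
  cell (large y on a geometric grid) the integral is formed inside the cell
  with φ interpolated implicitly — stepping it against an interpolated
  cumulative there would reference the unknown node and is unstable.

φ has an inverse-square-root singularity at f(y_c) (f′ vanishes at the
critical point).  The grid is therefore quadratically graded on the initial
interval (default: a quarter of the 4096 nodes) and geometric beyond; all
integrals over the singular region use the closed-form cumulative, never
pointwise values, so the singularity costs no accuracy.  The stored density
value at the left endpoint itself is cosmetic (copied from its neighbour).

The tail decays like a power law y^{−(1+Λ/(w(σ₁−1)))} — the driving term is
(f₋⁻¹(y)/y_c)^{Λ/w} with f₋⁻¹(y) ≍ y^{−1/(σ₁−1)} — so the tail mass beyond
y_max is estimated from the local log-log slope (an exponential-decay
estimate would be badly optimistic here).  y_max is chosen automatically so
the estimate is below 10⁻⁶ (y_max = 5000 for the canonical preset);
solutions with estimated tail above 10⁻³ are refused with advice to enlarge
y_max.  `apply_next_gen` implements K in the same cumulative form (exact
for atomic inputs, product-integrated for densities); its output is always
absolutely continuous, which also realizes the regularity bootstrap (one
application gives a density on the initial interval, two extend it past it,
and so on).

Diagnostics reported with every solve: ‖Kφ−φ‖₁, the K mass defect, and the
residual of the un-differentiated cumulative fixed-point identity at random
probe levels (≈ 4·10⁻⁶ relative at 4096 nodes, ≈ 2.5·10⁻⁷ at 16384; the
delay equation used for stepping is the derivative of that identity, and
the two are equivalent for integrable solutions).

## Time-stationary density ψ

At a random observation time the level is a post-jump draw η ~ φ waned for
an exponential(Λ) backward-recurrence time:

ψ(y) = (Λ/(wy))·(y/y_c)^{Λ/w}·∫_{max(y, f(y_c))}^∞ (η/y_c)^{−Λ/w} φ(η) dη.

Below f(y_c) the weight integral is the constant c and the cumulative is
closed-form (ψ ∝ y^{Λ/w−1} near 0, always integrable); above, the tail
integral is product-integrated on φ's grid.  ψ integrates to one by
construction up to the reported truncation, and two independent identities
are verified numerically: the pushforward of ψ through f recovers φ
(L1 ≈ 2.5·10⁻⁵ canonically), and the stationary forward equation
d/dy(gψ) + Λψ = Λφ·1{y ≥ f(y_c)} holds — analytically the residual vanishes
identically, and the reported sup-norm residual (≈ 3·10⁻⁵) is pure central-
difference error, evaluated away from small neighbourhoods of f(y_c)
(where φ is singular) and f(f(y_c)) (where φ′ jumps).

The general set-identity relating a stationary distribution to its
post-jump counterpart is only used in the unambiguous direction (pushforward
through f, enforced as a test); ψ is built independently via the
backward-recurrence representation.  The survival-weighted constant c and
the rate Λ are both surfaced in diagnostics without being equated: one is a
probability, the other a rate.

## Passage times

The expected time S(y) to wane from y > y_c down to y_c satisfies a renewal
equation; after integrating the elapsed-time terms in closed form it reads
S(y) = (1 − e^{−Λτ})/Λ + ∫₀^τ Λe^{−Λs} S(f(π(s,y))) ds with τ the
deterministic transit time.  Discretization: log-spaced grid on
(y_c, y_max = 300], 64-point Gauss–Legendre per node, log-linear
interpolation of S (linear extrapolation in log y above y_max, fraction
reported ≈ 3·10⁻⁵).  The discrete fixed-point map is affine with spectral
radius below one but approaching one as y_max grows (the contraction factor
at level y is 1 − e^{−Λτ(y)}), so plain iteration stalls on tall grids; the
default solver therefore solves the linear system directly and reports the
fixed-point sup-residual of the solution (≈ 10⁻¹⁴), with Picard iteration
retained as an option and verified equivalent.  Convergence failure is
reported rather than masked — a divergent iteration is evidence the mean
passage time may be infinite, which is not ruled out for all parameters.

## Demography and the force-of-infection balance

With a birth-level distribution, a survival function and an infectivity
ξ(y), the force of infection is self-consistent when the
population-averaged infectivity at a random stable-age observation equals
one.  The residual E[ξ(Y(A))] − 1 is estimated by seeded Monte Carlo
(ages from the normalized survival density, levels by exact simulation),
with a bracketing root finder over Λ using common random numbers as a
convenience wrapper.  Built-ins: exponential survival, point-mass birth
level, constant and step-below-critical infectivities.

## What the generator emulates, and what it does not

All test inputs are generated internally: ensembles of exact PDMP
trajectories from the canonical parameters are the package's synthetic
data.  They emulate the idealized model exactly — which is the point, since
the targets are analytic identities — but not features of real serological
data: assay noise and censoring at detection limits, host heterogeneity in
(w, σ₁, σ₂), age-dependent or seasonal Λ, and mortality.  Passing tests
certify the numerics and the internal consistency of the model, not its fit
to any dataset.

## Numerical defaults

| quantity | default | note |
|----------|---------|------|
| φ grid | 4096 nodes, ¼ graded on the initial interval | y_max auto (tail < 10⁻⁶) |
| f-inverse | closed form (σ₁ = 2), else bisection | 10⁻¹⁴ relative |
| one-jump inverse S | Brent, xtol 10⁻¹⁴ | requires monotonicity condition |
| kernel truncation | Poisson tail < tolerance, K_max ≤ 50 | certified bound returned |
| MC generation size | 2·10⁴ per generation | samples clipped into the grid |
| passage grid | 600 log-spaced nodes to y_max = 300 | 64-pt Gauss–Legendre |
| first-passage cap | 10³/Λ | flagged above 10⁻³ capped |

Problem sizes in the test suite (10⁵-host ensembles for distributional
checks, 10⁴ for convergence diagnostics, 2·10⁵ for the two-exposure
quadrature cross-check) were chosen so Monte-Carlo error sits comfortably
below the tolerances being verified while the whole suite runs in well
under a minute.

## Known limitations

* Only the canonical (g = −wy, power-law-boost) family is first-class; the
  architecture isolates the closed forms (`model`) so a user-supplied
  family would need its own T, inverse branches and α/β, falling back to
  root finding — contracts are documented but no alternative family ships.
* The one-jump density (and hence exact k = 1 kernels) requires the
  postponed-jump monotonicity condition; without it the package refuses.
* Stationary solutions are certified by residuals and cross-checks, not by
  re-proving uniqueness or asymptotic stability; convergence of the process
  law to ψ is demonstrated numerically (KS/L1 against simulated ensembles).
* The Kolmogorov forward/backward partial differential equations are not
  integrated as such; the stationary forward-equation residual check stands
  in for them.
* Age-dependent Λ, between-host transmission feedback and
  infection-coupled mortality are out of scope.
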