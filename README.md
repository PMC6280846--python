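# waneboost

**Waning and boosting of immune status: a piecewise-deterministic Markov
process (PDMP) toolkit for serological modelling.**

Serological surveys measure antibody titers, which rise abruptly when a host
is exposed to a pathogen and decay between exposures.  `waneboost` implements
the minimal within-host model behind such data: the immune status of a host
is a positive scalar *y* (an antibody titer) that

* **wanes** deterministically between exposures, dy/dt = g(y) with
  g(y) = −w·y (exponential decline at rate w), and
* is **boosted** instantaneously at exposures, which arrive as a Poisson
  process with force of infection Λ, through the map

  f(y) = y·(1 + σ₂/y)^σ₁,  σ₁ > 1, σ₂ > 0.

The boosting map decreases below and increases above the **critical level**
y_c = (σ₁−1)·σ₂, so a host with low immunity gets a large ("symptomatic")
boost while a well-protected host gets a small increment; for large *y* the
increment approaches δ = σ₁σ₂.  These ingredients define a PDMP for the
immune level Y(a) at age *a*, and the package answers the two natural
questions about it:

1. **What is the distribution of Y(a) given the birth level y_b?**
   The age-*t* transition kernel Q_t(y,·) is expanded by the number *k* of
   exposures: the k = 0 part is an atom with weight e^{−Λt}, the k = 1 part
   has an explicit density on [π(t,f(y)), f(π(t,y))], and each generation
   carries Poisson mass (Λt)^k e^{−Λt}/k!, so truncating the series leaves a
   certified tail bound (`waneboost.kernels`).  An exact event-driven
   simulator provides the stochastic counterpart (`waneboost.simulate`).
2. **What is the long-run (stationary) distribution of immune status?**
   The next-generation operator K maps the post-exposure level distribution
   to the distribution after the next exposure.  Its normalized fixed point
   φ — the stationary post-jump density on [f(y_c), ∞) — is constructed in
   closed form on [f(y_c), f(f(y_c))] and extended by a Volterra-type delay
   integral equation; the time-stationary density ψ follows as the
   exponential backward-recurrence mixture of φ (`waneboost.stationary`).
   Numerical convergence diagnostics, an expected-passage-time solver and a
   demographic consistency check for Λ round out the module.

## Worked example

```python
import waneboost as wb
from waneboost.stationary import stationary_process_density, solve_passage_time

model = wb.canonical_model()          # lam=1.5, w=1, sigma1=2, sigma2=1, y_b=4
print(model.y_c, model.f_yc)          # 1.0 4.0  (critical level, boost floor)

res = stationary_process_density(model, wb.solve_fixed_point(model))
print(round(res.phi_cumulative[-1] + res.tail_mass, 6))   # 1.0
print(round(res.c, 6))                                    # 0.073782
print(f"{res.residuals['fixed_point_l1']:.2e}")           # 1.17e-04

pt = solve_passage_time(model)
print(round(pt(2.0), 4))              # 5.6833
est = wb.estimate_first_passage(model, 2.0, 100_000, seed=41)
print(round(est.mean, 4))             # 5.6822

tp = wb.transition_probability(model, 2.0, 4.0, (1.0, 3.0), n_mc=50_000, seed=7)
print(round(tp["probability"], 4))    # 0.3208
```

Reading the numbers: the stationary post-jump density φ integrates to one;
`res.c` is the survival-weighted constant ∫(η/y_c)^{−Λ/w} φ(η)dη — the
stationary probability that a freshly boosted host wanes all the way to the
critical level before its next exposure (about 7.4% here).  The K-residual
‖Kφ−φ‖₁ ≈ 1.2·10⁻⁴ certifies the fixed point at the default grid.  The
expected time for a host at level 2 to wane down to y_c = 1 is ≈ 5.68 time
units by the renewal-equation solver, in agreement with direct Monte Carlo.
Finally, a host at level 4 has probability ≈ 0.32 of being found in [1, 3)
two time units later.

The same computations are available from a shell:

```sh
waneboost --preset canonical --out out stationary
waneboost --out out kernel --t 2 --y 4 --interval 0,inf
waneboost --out out --seed 7 simulate --n 1000 --age 2
```

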