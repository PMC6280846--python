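"""Generation expansion of the immune-status transition kernel.

The age-t transition kernel Q_t(y, .) decomposes by the number k of
exposures in [0, t]:

* k = 0: an atom at the waned level pi(t, y) with weight exp(-lam t);
* k = 1: an absolutely continuous part with explicit density q1 supported on
  [pi(t, f(y)), f(pi(t, y))], obtained by inverting the monotone map
  s -> pi(t - s, f(pi(s, y))) from jump time to landing level;
* k >= 2: estimated by conditional Monte Carlo — given exactly k exposures,
  the exposure times are the order statistics of k uniforms on [0, t] — with
  the exact Poisson generation mass (lam t)^k exp(-lam t) / k! attached
  analytically.

Truncating the expansion at K_max leaves a certified Poisson tail bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .measures import DiscretizedMeasure
from .model import (
    ConditionError,
    ModelIngredients,
    boost,
    boost_derivative,
    check_conditions,
    f_inverse,
    transit_time,
    wane,
)

__all__ = [
    "KernelEstimate",
    "q0_kernel",
    "first_jump_kernel",
    "one_jump_support",
    "one_jump_time_from_level",
    "one_jump_density",
    "one_jump_interval_prob",
    "generation_kernel_mc",
    "poisson_generation_mass",
    "transition_probability",
    "propagate_density",
]


def poisson_generation_mass(model: ModelIngredients, t: float, k) -> np.ndarray:
    """Exact mass of the k-exposure generation: (lam t)^k e^{-lam t} / k!."""
    return stats.poisson.pmf(k, model.lam * t)


# ---------------------------------------------------------------------------
# k = 0
# ---------------------------------------------------------------------------

def q0_kernel(model: ModelIngredients, t: float, y: float) -> tuple[float, float]:
    """The no-exposure part: an atom at pi(t, y) with weight e^{-lam t}."""
    if t < 0:
        raise ValueError("t must be >= 0")
    loc = float(wane(model, t, y))
    return loc, float(np.exp(-model.lam * t))


# ---------------------------------------------------------------------------
# First-jump (defective) kernel
# ---------------------------------------------------------------------------

def _first_jump_time_intervals(
    model: ModelIngredients, y: float, a: float, b: float
) -> list[tuple[float, float]]:
    """The set of jump times s for which the post-boost level f(pi(s, y))
    falls in [a, b): a union of at most two intervals, because the level map
    first decreases (while above the critical level) then increases."""
    fyc = model.f_yc

    def sublevel(v: float) -> tuple[float, float]:
        # {s : f(pi(s, y)) < v} = [tau(y, f_+^{-1}(v)), tau(y, f_-^{-1}(v)))
        if v <= fyc:
            return (0.0, 0.0)
        if np.isinf(v):
            return (0.0, np.inf)
        s_lo = float(transit_time(model, y, f_inverse(model, v, "plus")))
        s_hi = float(transit_time(model, y, f_inverse(model, v, "minus")))
        return (s_lo, max(s_hi, s_lo))

    lo_b, hi_b = sublevel(b)
    lo_a, hi_a = sublevel(a)
    # {V in [a,b)} = {V < b} minus {V < a}; the inner interval splits the outer
    pieces = [(lo_b, lo_a if hi_a > lo_a else hi_b), (hi_a, hi_b) if hi_a > lo_a else None]
    out = []
    for p in pieces:
        if p is None:
            continue
        s1, s2 = p
        if s2 > s1:
            out.append((s1, s2))
    return out


def first_jump_kernel(
    model: ModelIngredients,
    t: float,
    y: float,
    gamma: tuple[float, float],
    tail: float = 1e-10,
) -> float:
    """P(an exposure occurs in [0, t] and the level just after the first one
    lies in gamma = [a, b)), by adaptive quadrature of the exponential
    jump-time density over the (at most two) time intervals on which the
    post-boost level lies in gamma.

    ``t`` may be ``inf``; the quadrature is then truncated where the
    exponential tail drops below ``tail``.  For gamma = (0, inf) and t = inf
    the mass is 1: exposure is certain eventually.
    """
    a, b = gamma
    if not (0 <= a < b):
        raise ValueError(f"malformed interval {gamma}")
    if t < 0:
        raise ValueError("t must be >= 0 or inf")
    lam = model.lam
    t_cap = t if np.isfinite(t) else -np.log(tail) / lam
    total = 0.0
    for s1, s2 in _first_jump_time_intervals(model, y, a, b):
        s1, s2 = min(s1, t_cap), min(s2, t_cap)
        if s2 > s1:
            val, _ = integrate.quad(lambda s: lam * np.exp(-lam * s), s1, s2, limit=200)
            total += val
    return total


# ---------------------------------------------------------------------------
# k = 1: explicit one-jump density
# ---------------------------------------------------------------------------

def one_jump_support(model: ModelIngredients, t: float, y: float) -> tuple[float, float]:
    """Support [pi(t, f(y)), f(pi(t, y))] of the one-exposure landing level."""
    lo = float(wane(model, t, boost(model, y)))
    hi = float(boost(model, wane(model, t, y)))
    return lo, hi


def _require_monotone(model: ModelIngredients) -> None:
    rep = check_conditions(model)
    if not rep.holds("postponed_jump_monotonicity"):
        raise ConditionError(
            "postponed_jump_monotonicity fails: the jump-time -> landing-level "
            "map need not be invertible, so the one-jump density is not available"
        )


def _eta_of_s(model: ModelIngredients, t: float, y: float, s) -> np.ndarray:
    """Landing level at age t when the single exposure occurs at time s."""
    return wane(model, t - np.asarray(s), boost(model, wane(model, s, y)))


def _eta_prime(model: ModelIngredients, t: float, y: float, s) -> np.ndarray:
    """d eta / d s = g(eta) * (f'(u) g(u) / g(f(u)) - 1), u = pi(s, y);
    strictly positive when postponing a jump always lands higher."""
    u = wane(model, s, y)
    eta = _eta_of_s(model, t, y, s)
    ratio = boost_derivative(model, u) * model.g(u) / model.g(boost(model, u))
    return model.g(eta) * (ratio - 1.0)


def one_jump_time_from_level(model: ModelIngredients, t: float, y: float, eta: float) -> float:
    """Inverse S(eta) of the jump-time -> landing-level map, by bracketed
    root finding on [0, t].  Requires the monotonicity condition."""
    lo, hi = one_jump_support(model, t, y)
    if not (lo <= eta <= hi):
        raise ValueError(f"eta={eta} outside the one-jump support [{lo}, {hi}]")
    if eta <= lo:
        return 0.0
    if eta >= hi:
        return float(t)
    return float(
        optimize.brentq(lambda s: _eta_of_s(model, t, y, s) - eta, 0.0, t, xtol=1e-14, rtol=1e-15)
    )


def one_jump_density(model: ModelIngredients, t: float, y: float, eta) -> np.ndarray:
    """Density q1(t, y, eta) = dS/d eta on the one-jump support, zero outside.

    Integrates to t over the whole line, so the one-exposure part of the
    transition kernel is lam e^{-lam t} q1 d eta with mass lam t e^{-lam t}.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    _require_monotone(model)
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    lo, hi = one_jump_support(model, t, y)
    out = np.zeros_like(eta_arr)
    inside = (eta_arr >= lo) & (eta_arr <= hi)
    for i in np.flatnonzero(inside):
        s = one_jump_time_from_level(model, t, y, eta_arr[i])
        out[i] = 1.0 / float(_eta_prime(model, t, y, s))
    return out[0] if np.ndim(eta) == 0 else out


def one_jump_interval_prob(
    model: ModelIngredients, t: float, y: float, gamma: tuple[float, float]
) -> float:
    """Exact Q^1_t(y, [a, b)) = lam e^{-lam t} (S(b') - S(a')) with the
    interval clipped to the one-jump support."""
    _require_monotone(model)
    a, b = gamma
    lo, hi = one_jump_support(model, t, y)
    a, b = max(a, lo), min(b, hi)
    if b <= a:
        return 0.0
    s_a = one_jump_time_from_level(model, t, y, a)
    s_b = one_jump_time_from_level(model, t, y, b)
    return float(model.lam * np.exp(-model.lam * t) * (s_b - s_a))


def _one_jump_measure(
    model: ModelIngredients, t: float, y: float, grid: np.ndarray
) -> DiscretizedMeasure:
    """The Q^1 measure on a grid, with the exact cumulative lam e^{-lam t} S."""
    lo, hi = one_jump_support(model, t, y)
    scale = model.lam * np.exp(-model.lam * t)
    dens = scale * one_jump_density(model, t, y, grid)
    cum = np.empty_like(grid)
    for i, x in enumerate(grid):
        cum[i] = scale * one_jump_time_from_level(model, t, y, float(np.clip(x, lo, hi)))
    cum -= cum[0]
    return DiscretizedMeasure.from_density(grid, dens, cumulative=cum)


# ---------------------------------------------------------------------------
# k >= 2: conditional Monte Carlo
# ---------------------------------------------------------------------------

def _generation_samples(
    model: ModelIngredients, k: int, t: float, y: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Landing levels at age t given exactly k exposures: exposure times are
    order statistics of k uniforms on [0, t]."""
    times = np.sort(rng.uniform(0.0, t, size=(n, k)), axis=1)
    lvl = np.full(n, float(y))
    prev = np.zeros(n)
    for j in range(k):
        lvl = boost(model, wane(model, times[:, j] - prev, lvl))
        prev = times[:, j]
    return wane(model, t - prev, lvl)


def generation_kernel_mc(
    model: ModelIngredients,
    k: int,
    t: float,
    y: float,
    grid: np.ndarray | None = None,
    n: int = 20000,
    seed: int = 0,
) -> tuple[DiscretizedMeasure, float]:
    """Monte-Carlo density of the exactly-k-exposures part of Q_t(y, .)
    for k >= 2, scaled to the exact Poisson generation mass.

    Returns (measure, mass).  The measure is density-only on ``grid``
    (auto-built geometric grid when omitted).
    """
    if k < 2:
        raise ValueError("use q0_kernel / one_jump_density for k < 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
    pts = _generation_samples(model, k, t, y, n, rng)
    mass = float(poisson_generation_mass(model, t, k))
    if grid is None:
        grid = np.geomspace(pts.min() * 0.99, pts.max() * 1.01, 512)
    counts, _ = np.histogram(pts, bins=grid)
    cell_mass = counts / n * mass
    cum = np.concatenate([[0.0], np.cumsum(cell_mass)])
    widths = np.diff(grid)
    dens = np.zeros_like(grid)
    mid_dens = cell_mass / widths
    dens[1:-1] = 0.5 * (mid_dens[:-1] + mid_dens[1:])
    dens[0], dens[-1] = mid_dens[0], mid_dens[-1]
    return DiscretizedMeasure.from_density(grid, dens, cumulative=cum), mass


# ---------------------------------------------------------------------------
# Assembled transition kernel
# ---------------------------------------------------------------------------

@dataclass
class KernelEstimate:
    """Q_t(y, .) as a truncated generation series with a certified tail bound.

    ``generations[k]`` is the exactly-k-exposures sub-probability measure;
    the Poisson tail beyond ``k_max`` is ``truncation_bound``.
    """

    model: ModelIngredients
    y: float
    t: float
    generations: dict[int, DiscretizedMeasure]
    truncation_bound: float

    @property
    def k_max(self) -> int:
        return max(self.generations)

    @property
    def total_mass(self) -> float:
        return sum(m.total_mass for m in self.generations.values())

    def probability(self, gamma: tuple[float, float]) -> float:
        a, b = gamma
        total = 0.0
        for m in self.generations.values():
            total += float(m.cdf(b)[0] - m.cdf(a)[0]) if np.isfinite(b) else float(
                m.total_mass - m.cdf(a)[0]
            )
        return total


def _k_max_for(model: ModelIngredients, t: float, tolerance: float, cap: int = 50) -> int:
    mu = model.lam * t
    for k in range(cap + 1):
        if stats.poisson.sf(k, mu) < tolerance:
            return k
    achievable = float(stats.poisson.sf(cap, mu))
    raise ValueError(
        f"tolerance {tolerance} unreachable with K_max <= {cap}; "
        f"achievable truncation bound is {achievable}"
    )


def transition_probability(
    model: ModelIngredients,
    t: float,
    y: float,
    gamma: tuple[float, float],
    tolerance: float = 1e-8,
    n_mc: int = 20000,
    seed: int = 0,
) -> dict:
    """Q_t(y, gamma) by the truncated generation series.

    k = 0 and k = 1 are exact; k >= 2 use conditional Monte Carlo with the
    exact Poisson generation mass.  Returns a dict with the probability, the
    certified Poisson truncation bound, the per-generation contributions in
    gamma, and the Monte-Carlo standard error of the k >= 2 part.
    """
    a, b = gamma
    if not (0 <= a < b):
        raise ValueError(f"malformed interval {gamma}")
    if t == 0.0:
        loc = float(y)
        return {
            "probability": float(a <= loc < b),
            "truncation_bound": 0.0,
            "per_generation": {0: float(a <= loc < b)},
            "mc_se": 0.0,
            "k_max": 0,
        }
    k_max = _k_max_for(model, t, tolerance)
    per = {}
    loc, wgt = q0_kernel(model, t, y)
    per[0] = wgt * float(a <= loc < b)
    if k_max >= 1:
        per[1] = one_jump_interval_prob(model, t, y, gamma)
    mc_var = 0.0
    rng_seq = np.random.SeedSequence(seed)
    for k in range(2, k_max + 1):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        pts = _generation_samples(model, k, t, y, n_mc, rng)
        frac = float(np.mean((pts >= a) & (pts < b)))
        mass = float(poisson_generation_mass(model, t, k))
        per[k] = mass * frac
        mc_var += (mass**2) * frac * (1.0 - frac) / n_mc
    bound = float(stats.poisson.sf(k_max, model.lam * t))
    return {
        "probability": float(sum(per.values())),
        "truncation_bound": bound,
        "per_generation": per,
        "mc_se": float(np.sqrt(mc_var)),
        "k_max": k_max,
    }


def kernel_estimate(
    model: ModelIngredients,
    t: float,
    y: float,
    grid: np.ndarray | None = None,
    tolerance: float = 1e-8,
    n_mc: int = 20000,
    seed: int = 0,
) -> KernelEstimate:
    """Assemble Q_t(y, .) as per-generation DiscretizedMeasures."""
    k_max = _k_max_for(model, t, tolerance)
    gens: dict[int, DiscretizedMeasure] = {}
    loc, wgt = q0_kernel(model, t, y)
    gens[0] = DiscretizedMeasure.from_atom(loc, wgt)
    if grid is None:
        lo, _ = one_jump_support(model, t, y)
        grid = np.geomspace(min(loc, lo) * 0.5, boost(model, y) * np.exp(0.5 * model.lam * t) * 4, 1024)
    if k_max >= 1:
        gens[1] = _one_jump_measure(model, t, y, grid)
    for k in range(2, k_max + 1):
        gens[k], _ = generation_kernel_mc(model, k, t, y, grid=grid, n=n_mc, seed=seed)
    return KernelEstimate(
        model=model,
        y=y,
        t=t,
        generations=gens,
        truncation_bound=float(stats.poisson.sf(k_max, model.lam * t)),
    )


# ---------------------------------------------------------------------------
# Density propagation
# ---------------------------------------------------------------------------

def propagate_density(
    model: ModelIngredients,
    m: DiscretizedMeasure,
    t: float,
    grid: np.ndarray | None = None,
    tolerance: float = 1e-8,
    n_mc: int = 50000,
    seed: int = 0,
) -> DiscretizedMeasure:
    """Push a measure through the age-t transition kernel.

    The no-exposure part is exact: atoms are transported along the flow with
    weight factor e^{-lam t}, and a density part is transported by the exact
    change-of-variables formula
    (T0(t) phi)(x) = e^{-lam t} (g(pi(-t, x)) / g(x)) phi(pi(-t, x)).
    Exposure parts: atoms use the explicit one-jump density plus conditional
    Monte Carlo for k >= 2; the density part uses Monte Carlo conditioned on
    at least one exposure, carrying the exact mass (1 - e^{-lam t}).
    Total mass is preserved up to Monte-Carlo binning of out-of-grid mass.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return m
    lam = model.lam
    no_jump = float(np.exp(-lam * t))

    out_atoms_loc, out_atoms_w = [], []
    for loc, wgt in zip(m.atom_locations, m.atom_weights):
        out_atoms_loc.append(float(wane(model, t, loc)))
        out_atoms_w.append(wgt * no_jump)

    if grid is None:
        grid = _default_output_grid(model, m, t)
    cell_mass = np.zeros(len(grid) - 1)
    node_dens = np.zeros(len(grid))

    # jump parts of atoms: k = 1 explicit, k >= 2 conditional MC
    k_max = _k_max_for(model, t, tolerance)
    for ai, (loc, wgt) in enumerate(zip(m.atom_locations, m.atom_weights)):
        q1 = _one_jump_measure(model, t, loc, grid)
        node_dens += wgt * q1.density
        cell_mass += wgt * q1.density_cell_masses()
        for k in range(2, k_max + 1):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1000 + ai, k)))
            pts = _generation_samples(model, k, t, loc, n_mc, rng)
            pts = np.clip(pts, grid[0], grid[-1])  # keep the mass ledger exact
            mass_k = wgt * float(poisson_generation_mass(model, t, k))
            counts, _ = np.histogram(pts, bins=grid)
            cm = counts / n_mc * mass_k
            cell_mass += cm
            node_dens += _cells_to_nodes(grid, cm)

    # density part
    if m.grid.size >= 2 and m.density_mass > 0:
        # exact no-jump transport: node densities by change of variables and
        # cell masses from the input cumulative (mass-exact up to truncation)
        src = wane(model, -t, grid)
        inside = (src >= m.grid[0]) & (src <= m.grid[-1])
        phi_src = np.where(inside, np.interp(src, m.grid, m.density), 0.0)
        trans = no_jump * (model.g(src) / model.g(grid)) * phi_src
        node_dens += trans
        in_cum = np.concatenate([[0.0], np.cumsum(m.density_cell_masses())])
        src_cdf = np.interp(src, m.grid, in_cum, left=0.0, right=in_cum[-1])
        cell_mass += no_jump * np.diff(src_cdf)
        # jump part by MC conditioned on >= 1 exposure
        from .simulate import _ensemble_levels  # local import to avoid cycle

        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
        starts = _sample_from_density(m, n_mc, rng)
        levels, counts_k = _ensemble_levels(model, starts, t, rng)
        jumped = np.clip(levels[counts_k >= 1], grid[0], grid[-1])
        if jumped.size:
            mass_jump = m.density_mass * (1.0 - no_jump)
            counts, _ = np.histogram(jumped, bins=grid)
            cm = counts / jumped.size * mass_jump
            cell_mass += cm
            node_dens += _cells_to_nodes(grid, cm)

    cum = np.concatenate([[0.0], np.cumsum(cell_mass)])
    return DiscretizedMeasure(
        atom_locations=np.asarray(out_atoms_loc),
        atom_weights=np.asarray(out_atoms_w),
        grid=grid,
        density=node_dens,
        cumulative=cum,
    )


def _default_output_grid(model: ModelIngredients, m: DiscretizedMeasure, t: float) -> np.ndarray:
    support = []
    if m.atom_locations.size:
        support += [m.atom_locations.min(), m.atom_locations.max()]
    if m.grid.size:
        support += [m.grid[0], m.grid[-1]]
    lo, hi = min(support), max(support)
    lo_out = float(wane(model, t, lo)) * 0.5
    hi_out = float(boost(model, boost(model, hi)) + model.delta * (model.lam * t + 4 * np.sqrt(model.lam * t)))
    return np.geomspace(lo_out, hi_out, 1024)


def _cells_to_nodes(grid: np.ndarray, cell_mass: np.ndarray) -> np.ndarray:
    mid = cell_mass / np.diff(grid)
    dens = np.zeros_like(grid)
    dens[1:-1] = 0.5 * (mid[:-1] + mid[1:])
    dens[0], dens[-1] = mid[0], mid[-1]
    return dens


def _sample_from_density(m: DiscretizedMeasure, n: int, rng: np.random.Generator) -> np.ndarray:
    cm = m.density_cell_masses()
    cum = np.concatenate([[0.0], np.cumsum(cm)])
    cum /= cum[-1]
    u = rng.uniform(size=n)
    return np.interp(u, cum, m.grid)
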