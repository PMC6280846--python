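"""Exact stochastic simulation of the waning/boosting PDMP.

All randomness is in the Poisson exposure times: between jumps the immune
level wanes along the closed-form flow, at a jump it is boosted through f.
The simulator is therefore exact — no time discretization anywhere.  Ensemble
routines use vectorized sampling grouped by jump count (given the count k on
[0, t], the jump times are distributed as the order statistics of k uniform
draws), which keeps 1e5-trajectory ensembles fast.

Per-trajectory RNG substreams are derived from (seed, index) via
``numpy.random.SeedSequence`` spawn keys so single-trajectory output is
independent of ensemble ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelIngredients, boost, transit_time, wane

__all__ = [
    "Trajectory",
    "AgeMarginalSample",
    "FirstPassageEstimate",
    "simulate_trajectory",
    "sample_age_marginal",
    "estimate_first_passage",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class Trajectory:
    """One PDMP realization, stored at jumps only.

    ``levels_pre[i]`` is the level just before jump ``i`` (after waning since
    the previous jump) and ``levels_post[i] = f(levels_pre[i])``.
    """

    model: ModelIngredients
    y_b: float
    horizon: float
    seed: int
    jump_ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    levels_pre: np.ndarray = field(default_factory=lambda: np.empty(0))
    levels_post: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_jumps(self) -> int:
        return len(self.jump_ages)

    def level(self, age):
        """Immune level at any age in [0, horizon], via the closed-form flow."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0) or np.any(age > self.horizon * (1 + 1e-12)):
            raise ValueError("age must lie in [0, horizon]")
        if self.n_jumps == 0:
            return wane(self.model, age, self.y_b)
        idx = np.searchsorted(self.jump_ages, age, side="right")
        base_age = np.where(idx > 0, self.jump_ages[np.maximum(idx - 1, 0)], 0.0)
        base_lvl = np.where(idx > 0, self.levels_post[np.maximum(idx - 1, 0)], self.y_b)
        return wane(self.model, age - base_age, base_lvl)


@dataclass
class AgeMarginalSample:
    """Levels Y(a) and exposure counts k for n independent hosts at one age."""

    model: ModelIngredients
    y_b: float
    age: float
    levels: np.ndarray
    counts: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.levels)

    def stratum(self, k: int) -> np.ndarray:
        """Levels of hosts that experienced exactly k exposures."""
        return self.levels[self.counts == k]


@dataclass
class FirstPassageEstimate:
    """Monte-Carlo estimate of the mean time to wane down to the critical level."""

    mean: float
    se: float
    n: int
    capped_fraction: float
    cap: float
    flagged: bool
    times: np.ndarray | None = None


def simulate_trajectory(
    model: ModelIngredients, y_b: float, horizon: float, seed: int, index: int = 0
) -> Trajectory:
    """Simulate one trajectory on [0, horizon] with i.i.d. exponential gaps."""
    if y_b <= 0:
        raise ValueError("y_b must be positive")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    rng = _rng(seed, index)
    ages, pre, post = [], [], []
    t, level = 0.0, y_b
    while True:
        gap = rng.exponential(1.0 / model.lam)
        if t + gap > horizon:
            break
        t += gap
        lvl_pre = float(wane(model, gap, level))
        level = float(boost(model, lvl_pre))
        ages.append(t)
        pre.append(lvl_pre)
        post.append(level)
    return Trajectory(
        model=model,
        y_b=y_b,
        horizon=horizon,
        seed=seed,
        jump_ages=np.asarray(ages),
        levels_pre=np.asarray(pre),
        levels_post=np.asarray(post),
    )


def _ensemble_levels(
    model: ModelIngredients,
    start_levels: np.ndarray,
    age: float,
    rng: np.random.Generator,
    record_ages: np.ndarray | None = None,
):
    """Levels at ``age`` (and optionally at intermediate record ages) for an
    ensemble started at ``start_levels``, grouped by jump count.

    Returns (levels_at_age, counts) or (levels_matrix, counts) where
    ``levels_matrix`` has one column per record age.
    """
    n = len(start_levels)
    counts = rng.poisson(model.lam * age, size=n)
    if record_ages is None:
        record_ages = np.asarray([age])
        squeeze = True
    else:
        record_ages = np.asarray(record_ages, dtype=float)
        squeeze = False
    out = np.empty((n, len(record_ages)))

    for k in np.unique(counts):
        sel = np.flatnonzero(counts == k)
        y0 = start_levels[sel]
        if k == 0:
            levels_path = np.broadcast_to(y0[:, None], (len(sel), 1))
            times = np.zeros((len(sel), 1))
            post = y0[:, None]
        else:
            times = np.sort(rng.uniform(0.0, age, size=(len(sel), k)), axis=1)
            post = np.empty((len(sel), k))
            lvl = y0
            prev = np.zeros(len(sel))
            for j in range(k):
                lvl = boost(model, wane(model, times[:, j] - prev, lvl))
                post[:, j] = lvl
                prev = times[:, j]
        # evaluate at each record age: level at last jump <= a, waned forward
        jt = times if k else np.zeros((len(sel), 0))
        for ci, a in enumerate(record_ages):
            if k == 0:
                out[sel, ci] = wane(model, a, y0)
            else:
                idx = np.sum(jt <= a, axis=1)  # jumps before a
                base_age = np.where(idx > 0, jt[np.arange(len(sel)), np.maximum(idx - 1, 0)], 0.0)
                base_lvl = np.where(idx > 0, post[np.arange(len(sel)), np.maximum(idx - 1, 0)], y0)
                out[sel, ci] = wane(model, a - base_age, base_lvl)
    if squeeze:
        return out[:, 0], counts
    return out, counts


def _levels_at_ages(
    model: ModelIngredients,
    start_levels: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Level of host i at its own age ``ages[i]``, starting from
    ``start_levels[i]`` (vectorized, grouped by jump count)."""
    n = len(start_levels)
    ages = np.asarray(ages, dtype=float)
    counts = rng.poisson(model.lam * ages)
    out = np.empty(n)
    for k in np.unique(counts):
        sel = np.flatnonzero(counts == k)
        y0 = start_levels[sel]
        a = ages[sel]
        if k == 0:
            out[sel] = wane(model, a, y0)
            continue
        times = np.sort(rng.uniform(0.0, 1.0, size=(len(sel), k)), axis=1) * a[:, None]
        lvl = y0
        prev = np.zeros(len(sel))
        for j in range(k):
            lvl = boost(model, wane(model, times[:, j] - prev, lvl))
            prev = times[:, j]
        out[sel] = wane(model, a - prev, lvl)
    return out


def sample_age_marginal(
    model: ModelIngredients, y_b: float, age: float, n: int, seed: int
) -> AgeMarginalSample:
    """n independent hosts born at level y_b, observed at the given age."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if y_b <= 0:
        raise ValueError("y_b must be positive")
    if age < 0:
        raise ValueError("age must be >= 0")
    rng = _rng(seed)
    if age == 0.0:
        return AgeMarginalSample(model, y_b, age, np.full(n, float(y_b)), np.zeros(n, dtype=int), seed)
    levels, counts = _ensemble_levels(model, np.full(n, float(y_b)), age, rng)
    # note: counts here is the number of exposures in [0, age]
    return AgeMarginalSample(model, y_b, age, levels, counts, seed)


def estimate_first_passage(
    model: ModelIngredients,
    y: float,
    n: int,
    seed: int,
    cap: float | None = None,
    keep_times: bool = False,
) -> FirstPassageEstimate:
    """Monte-Carlo mean of the first time the level wanes down to y_c from y > y_c.

    Waning-only passage would take the deterministic transit time; any jump
    before that resets the excursion upward.  Excursions are capped at
    ``cap`` (default 1e3 / lam) time units; the capped fraction is reported
    and the estimate flagged when it exceeds 1e-3.
    """
    yc = model.y_c
    if y <= yc:
        raise ValueError(f"start level must exceed the critical level {yc}")
    if cap is None:
        cap = 1e3 / model.lam
    rng = _rng(seed)
    level = np.full(n, float(y))
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    while np.any(active):
        idx = np.flatnonzero(active)
        tau = transit_time(model, level[idx], yc)
        gap = rng.exponential(1.0 / model.lam, size=len(idx))
        done = gap >= tau
        di = idx[done]
        t[di] += tau[done]
        active[di] = False
        ji = idx[~done]
        t[ji] += gap[~done]
        level[ji] = boost(model, wane(model, gap[~done], level[ji]))
        over = ji[t[ji] >= cap]
        t[over] = cap
        active[over] = False
    capped = float(np.mean(t >= cap))
    mean = float(np.mean(t))
    se = float(np.std(t, ddof=1) / np.sqrt(n))
    return FirstPassageEstimate(
        mean=mean,
        se=se,
        n=n,
        capped_fraction=capped,
        cap=cap,
        flagged=capped > 1e-3,
        times=t if keep_times else None,
    )
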