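"""Stationary immune-status distributions via the next-generation operator.

The next-generation operator K maps the distribution of immune status just
after one exposure to the distribution just after the next.  Its normalized
fixed point phi — the stationary *post-jump* density, supported on
[f(y_c), inf) — is constructed explicitly: on the initial interval
[f(y_c), f(f(y_c))] it is given in closed form (up to a free constant c),
and beyond it satisfies a linear delay integral equation

    phi(y) = alpha(y) * int_{f_+^{-1}(y)}^{y} phi  +  (alpha(y) + beta(y)) *
             (f_-^{-1}(y)/y_c)^(lam/w) * c,

which is Volterra-like in y (the delayed argument f_+^{-1}(y) lies behind y)
and is stepped forward by implicit trapezoid product integration.  The
time-stationary density psi of the process itself is the backward-recurrence
mixture of phi: the level observed at a random time is the post-jump level
eta ~ phi waned for an exponential(lam) duration,

    psi(y) = (lam / (w y)) (y/y_c)^(lam/w)
             * int_{max(y, f(y_c))}^{inf} (eta/y_c)^(-lam/w) phi(eta) d eta.

phi has an inverse-square-root singularity at f(y_c) (the boosting map has a
critical point there); the grid is quadratically graded on the initial
interval and all integrals there use exact closed-form cumulatives, so the
singularity never degrades the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .measures import DiscretizedMeasure
from .model import (
    ConditionError,
    ConditionReport,
    ModelIngredients,
    alpha,
    beta,
    boost,
    boost_derivative,
    check_conditions,
    f_inverse,
    survival_to_critical,
    transit_time,
    wane,
)

__all__ = [
    "StationaryResult",
    "PassageTimeResult",
    "apply_next_gen",
    "solve_fixed_point",
    "power_iteration",
    "stationary_process_density",
    "pushforward_through_boost",
    "forward_equation_residual",
    "convergence_diagnostic",
    "solve_passage_time",
    "lambda_consistency_residual",
    "solve_lambda",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ep(model: ModelIngredients, y):
    """exp(-lam T(f_+^{-1}(y))) = (f_+^{-1}(y)/y_c)^(lam/w)."""
    return (f_inverse(model, y, "plus") / model.y_c) ** (model.lam / model.w)


def _em(model: ModelIngredients, y):
    """exp(-lam T(f_-^{-1}(y))) = (f_-^{-1}(y)/y_c)^(lam/w)."""
    return (f_inverse(model, y, "minus") / model.y_c) ** (model.lam / model.w)


def _exp_lam_T(model: ModelIngredients, y):
    """exp(lam T(y)) = (y/y_c)^(-lam/w): survival of waning from y to y_c."""
    return survival_to_critical(model, y)


def build_grid(model: ModelIngredients, y_max: float, n: int = 4096, frac_initial: float = 0.25) -> np.ndarray:
    """Solver grid on [f(y_c), y_max]: quadratically graded on the initial
    interval [f(y_c), f(f(y_c))] (to contain the inverse-sqrt singularity at
    the left endpoint), geometric beyond."""
    fyc, f2 = model.f_yc, model.f2_yc
    m = max(64, int(n * frac_initial))
    u = np.linspace(0.0, 1.0, m + 1)
    seg_a = fyc + (f2 - fyc) * u**2
    seg_b = np.geomspace(f2, y_max, n - m)
    return np.unique(np.concatenate([seg_a, seg_b]))


@dataclass
class StationaryResult:
    """Post-jump density phi, time-stationary density psi, and diagnostics."""

    model: ModelIngredients
    grid: np.ndarray
    phi: np.ndarray
    phi_cumulative: np.ndarray
    c: float  # the survival-weighted constant evaluated at the normalized phi
    tail_mass: float
    psi_grid: np.ndarray | None = None
    psi: np.ndarray | None = None
    psi_cumulative: np.ndarray | None = None
    residuals: dict = field(default_factory=dict)
    conditions: ConditionReport | None = None

    def phi_measure(self) -> DiscretizedMeasure:
        return DiscretizedMeasure.from_density(self.grid, self.phi, cumulative=self.phi_cumulative)

    def psi_measure(self) -> DiscretizedMeasure:
        if self.psi is None:
            raise ValueError("psi not computed; call stationary_process_density first")
        return DiscretizedMeasure.from_density(self.psi_grid, self.psi, cumulative=self.psi_cumulative)

    def psi_cdf(self, points) -> np.ndarray:
        if self.psi is None:
            raise ValueError("psi not computed")
        return np.interp(points, self.psi_grid, self.psi_cumulative, left=0.0,
                         right=self.psi_cumulative[-1])


# ---------------------------------------------------------------------------
# The next-generation operator
# ---------------------------------------------------------------------------

def _tail_survival_integrals(b: DiscretizedMeasure, model: ModelIngredients):
    """Per-node tail integrals R(x) = int_{[x, inf)} (eta/y_c)^(-lam/w) b(d eta)
    for x on b's grid (density part only), by product integration with b's
    cell masses; returns (grid, R_nodes)."""
    if b.grid.size < 2:
        return np.empty(0), np.empty(0)
    w_vals = _exp_lam_T(model, b.grid)
    cell = 0.5 * (w_vals[1:] + w_vals[:-1]) * b.density_cell_masses()
    R = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
    return b.grid, R


def _atom_tail(b: DiscretizedMeasure, model: ModelIngredients, x) -> np.ndarray:
    """Atom contribution to the survival-weighted tail integral over [x, inf)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for loc, wgt in zip(b.atom_locations, b.atom_weights):
        out += wgt * float(_exp_lam_T(model, loc)) * (loc >= x)
    return out


def _strict_cdf(b: DiscretizedMeasure, x) -> np.ndarray:
    """b((0, x)) with atoms at x excluded (half-open set convention)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for loc, wgt in zip(b.atom_locations, b.atom_weights):
        out += wgt * (x > loc)
    if b.grid.size >= 2:
        cum = np.concatenate([[0.0], np.cumsum(b.density_cell_masses())])
        out += np.interp(x, b.grid, cum, left=0.0, right=cum[-1])
    return out


def apply_next_gen(
    model: ModelIngredients,
    b: DiscretizedMeasure,
    grid: np.ndarray | None = None,
) -> DiscretizedMeasure:
    """One application of the next-generation operator K.

    The input must be supported on [f(y_c), inf).  The output is always
    absolutely continuous (the exposure time is continuous), with density

        (Kb)'(y) = alpha(y) (f_+^{-1}(y)/y_c)^(lam/w) * C_+(y)
                 + beta(y) (f_-^{-1}(y)/y_c)^(lam/w) * c,

    where C_+(y) integrates the survival weight (eta/y_c)^(-lam/w) over b on
    [f_+^{-1}(y), inf) and c = C_+(f(y_c)) is the survival-weighted total.
    The cumulative over the sets [f(y_c), y) is evaluated in closed form from
    the same ingredients, so cell masses are quadrature-exact given b.
    """
    fyc = model.f_yc
    support_lo = np.inf
    if b.atom_locations.size:
        support_lo = min(support_lo, float(b.atom_locations.min()))
    if b.grid.size:
        first = b.grid[np.argmax(b.density > 0)] if np.any(b.density > 0) else b.grid[0]
        support_lo = min(support_lo, float(first))
    if support_lo < fyc * (1.0 - 1e-9):
        raise ValueError(
            f"input support must lie in [f(y_c), inf) = [{fyc}, inf); found mass at {support_lo}"
        )
    if grid is None:
        grid = b.grid if b.grid.size >= 2 else build_grid(model, max(100.0 * model.f2_yc, 100.0))

    tgrid, R = _tail_survival_integrals(b, model)

    def c_plus(x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = _atom_tail(b, model, x)
        if tgrid.size:
            out += np.interp(x, tgrid, R, left=R[0] if R.size else 0.0, right=0.0)
        return out

    c = float(c_plus(fyc)[0])
    x_plus = f_inverse(model, grid, "plus")
    ep = (x_plus / model.y_c) ** (model.lam / model.w)
    em = _em(model, grid)
    cp = c_plus(x_plus)
    with np.errstate(divide="ignore", over="ignore"):
        dens = np.where(
            grid > fyc,
            _safe_alpha(model, grid) * ep * cp + _safe_beta(model, grid) * em * c,
            0.0,
        )
    if len(dens) > 1 and not np.isfinite(dens[0]):
        dens[0] = dens[1]
    dens = np.nan_to_num(dens, posinf=0.0)
    if len(dens) > 1:
        dens[0] = dens[1]
    cum = _strict_cdf(b, x_plus) + ep * cp - em * c
    cum = cum - cum[0]
    cum = np.maximum.accumulate(np.maximum(cum, 0.0))
    return DiscretizedMeasure.from_density(grid, dens, cumulative=cum)


def _safe_alpha(model: ModelIngredients, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    ok = y > model.f_yc * (1.0 + 1e-13)
    if np.any(ok):
        out[ok] = alpha(model, y[ok])
    return out


def _safe_beta(model: ModelIngredients, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    ok = y > model.f_yc * (1.0 + 1e-13)
    if np.any(ok):
        out[ok] = beta(model, y[ok])
    return out


def power_iteration(
    model: ModelIngredients,
    grid: np.ndarray,
    start: DiscretizedMeasure | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[DiscretizedMeasure, int]:
    """Iterate K from an atom at f(y_c) (default) until L1-Cauchy; the limit
    is the fixed point, independently of the starting measure."""
    b = start if start is not None else DiscretizedMeasure.from_atom(model.f_yc, 1.0)
    prev = None
    for it in range(1, max_iter + 1):
        b = apply_next_gen(model, b, grid=grid).normalized()
        if prev is not None and prev.l1_distance(b) < tol:
            return b, it
        prev = b
    return b, max_iter


# ---------------------------------------------------------------------------
# Constructive fixed point
# ---------------------------------------------------------------------------

def solve_fixed_point(
    model: ModelIngredients,
    n_grid: int = 4096,
    y_max: float | None = None,
    c: float = 1.0,
    tail_target: float = 1e-6,
    compute_residuals: bool = True,
) -> StationaryResult:
    """Construct the normalized fixed point phi of the next-generation operator.

    With the free constant ``c``, phi is closed-form on the initial interval
    [f(y_c), f(f(y_c))]; beyond it the delay equation is stepped by implicit
    trapezoid product integration (the delayed lower limit f_+^{-1}(y) always
    lies at least the asymptotic jump size behind y, so only already-computed
    values are needed).  The result is renormalized to unit mass, which makes
    it independent of ``c``.  The tail beyond y_max is estimated from the
    local power-law decay of phi and reported.
    """
    rep = check_conditions(model)
    for key in ("tail_integrability", "expected_jump_contraction"):
        if not rep.holds(key):
            raise ConditionError(
                f"cannot certify an integrable fixed point: condition '{key}' fails "
                f"(witnesses: {rep.witnesses(key)})"
            )
    if y_max is None:
        y_max = _auto_y_max(model, c, tail_target)
    grid = build_grid(model, y_max, n_grid)
    phi, cum = _construct_phi(model, grid, c)

    tail = _tail_estimate(model, grid, phi)
    mass = cum[-1] + tail
    if tail > 1e-3 * mass:
        raise RuntimeError(
            f"tail mass estimate {tail / mass:.2e} beyond y_max={y_max} exceeds 1e-3 "
            "of the total; increase y_max"
        )
    phi_n = phi / mass
    cum_n = cum / mass
    c_norm = _survival_weighted_total(model, grid, cum_n)

    result = StationaryResult(
        model=model,
        grid=grid,
        phi=phi_n,
        phi_cumulative=cum_n,
        c=c_norm,
        tail_mass=tail / mass,
        conditions=rep,
    )
    if compute_residuals:
        meas = result.phi_measure()
        k_meas = apply_next_gen(model, meas, grid=grid)
        result.residuals["fixed_point_l1"] = meas.l1_distance(k_meas)
        result.residuals["k_mass_defect"] = abs(k_meas.total_mass - meas.total_mass)
        result.residuals["cumulative_eq"] = _cumulative_equation_residual(model, result)
    return result


def _construct_phi(model: ModelIngredients, grid: np.ndarray, c: float):
    fyc, f2 = model.f_yc, model.f2_yc
    lam_w = model.lam / model.w
    n = len(grid)
    phi = np.zeros(n)
    cum = np.zeros(n)

    in_a = grid <= f2 * (1.0 + 1e-12)
    ia = np.flatnonzero(in_a)
    ga = grid[ia]
    ep_a = _ep(model, ga)
    em_a = _em(model, ga)
    phi[ia] = c * (_safe_alpha(model, ga) * ep_a + _safe_beta(model, ga) * em_a)
    phi[ia[0]] = phi[ia[1]] if len(ia) > 1 else 0.0  # endpoint is singular; cosmetic value
    cum[ia] = c * (ep_a - em_a)

    # closed-form cumulative on the initial interval, for interpolating the
    # delayed memory integral (linear interpolation would smear the sqrt shape)
    def cum_initial(x):
        return c * (_ep(model, x) - _em(model, x))

    start = ia[-1] + 1
    a_all = _safe_alpha(model, grid)
    b_all = _safe_beta(model, grid)
    em_all = np.empty(n)
    em_all[ia] = em_a
    if start < n:
        em_all[start:] = _em(model, grid[start:])
    x_delay = f_inverse(model, grid, "plus")

    for i in range(start, n):
        h = grid[i] - grid[i - 1]
        x = x_delay[i]
        rhs = (a_all[i] + b_all[i]) * em_all[i] * c
        if x > grid[i - 1]:
            # memory window shorter than one cell: integrate within the cell
            # with phi interpolated linearly between the endpoints (implicit)
            th = (x - grid[i - 1]) / h
            d = grid[i] - x
            coef_prev = 0.5 * d * (1.0 - th)
            coef_cur = 0.5 * d * (1.0 + th)
            phi[i] = (a_all[i] * coef_prev * phi[i - 1] + rhs) / (1.0 - a_all[i] * coef_cur)
        else:
            if x <= f2:
                cum_x = float(cum_initial(x))
            else:
                j = np.searchsorted(grid, x) - 1
                th = (x - grid[j]) / (grid[j + 1] - grid[j])
                cum_x = cum[j] * (1 - th) + cum[j + 1] * th
            partial = cum[i - 1] + 0.5 * h * phi[i - 1] - cum_x
            phi[i] = (a_all[i] * partial + rhs) / (1.0 - 0.5 * a_all[i] * h)
        cum[i] = cum[i - 1] + 0.5 * h * (phi[i - 1] + phi[i])
    return phi, cum


def _tail_estimate(model: ModelIngredients, grid: np.ndarray, phi: np.ndarray) -> float:
    """Tail mass beyond grid[-1] from the local log-log slope of phi."""
    sel = grid >= grid[-1] * 0.7
    x, v = grid[sel], phi[sel]
    pos = v > 0
    if pos.sum() < 4:
        return 0.0
    p = np.polyfit(np.log(x[pos]), np.log(v[pos]), 1)[0]
    if p >= -1.0:
        raise RuntimeError(
            f"phi does not decay integrably near y_max (log-log slope {p:.3f} >= -1); "
            "increase y_max or check the integrability conditions"
        )
    return float(phi[-1] * grid[-1] / (-p - 1.0))


def _auto_y_max(model: ModelIngredients, c: float, tail_target: float) -> float:
    y_max = max(50.0 * model.f2_yc, 50.0)
    for _ in range(8):
        grid = build_grid(model, y_max, 1024)
        phi, cum = _construct_phi(model, grid, c)
        try:
            tail = _tail_estimate(model, grid, phi)
        except RuntimeError:
            y_max *= 4.0
            continue
        if tail <= tail_target * (cum[-1] + tail):
            return y_max
        y_max *= 4.0
    return y_max


def _survival_weighted_total(model: ModelIngredients, grid: np.ndarray, cum: np.ndarray) -> float:
    """c = int (eta/y_c)^(-lam/w) phi(eta) d eta by product integration."""
    w_vals = _exp_lam_T(model, grid)
    return float(np.sum(0.5 * (w_vals[1:] + w_vals[:-1]) * np.diff(cum)))


def _cumulative_equation_residual(
    model: ModelIngredients, res: StationaryResult, n_probe: int = 20, seed: int = 0
) -> float:
    """Max relative residual of the cumulative fixed-point identity
    Phi(y) = Phi(f_+^{-1}(y)) + (f_+^{-1}(y)/y_c)^(lam/w) C_+(y) - (f_-^{-1}(y)/y_c)^(lam/w) c
    at random probe levels above f(f(y_c))."""
    rng = np.random.default_rng(seed)
    grid, cum = res.grid, res.phi_cumulative
    probes = np.exp(rng.uniform(np.log(model.f2_yc * 1.05), np.log(grid[-1] * 0.5), n_probe))
    w_vals = _exp_lam_T(model, grid)
    cell = 0.5 * (w_vals[1:] + w_vals[:-1]) * np.diff(cum)
    R = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
    c = float(R[0])
    worst = 0.0
    for y in probes:
        x = float(f_inverse(model, y, "plus"))
        lhs = np.interp(y, grid, cum)
        rhs = (
            np.interp(x, grid, cum)
            + float(_ep(model, y)) * np.interp(x, grid, R)
            - float(_em(model, y)) * c
        )
        worst = max(worst, abs(lhs - rhs) / max(lhs, 1e-12))
    return worst


# ---------------------------------------------------------------------------
# Time-stationary density of the process
# ---------------------------------------------------------------------------

def stationary_process_density(
    model: ModelIngredients, res: StationaryResult, mass_tol: float = 1e-8
) -> StationaryResult:
    """Fill in the time-stationary density psi from the normalized phi.

    psi is the backward-recurrence mixture: the level at a random observation
    time is a post-jump draw eta ~ phi waned for an exponential(lam) time,
    giving the closed form in the module docstring.  Below f(y_c) the weight
    integral is the constant c and the cumulative is closed-form; above it the
    tail integral is product-integrated on phi's grid.  psi integrates to one
    by construction, up to the reported truncation.
    """
    if abs(res.phi_cumulative[-1] + res.tail_mass - 1.0) > 1e-3:
        raise ValueError("phi must be normalized before building psi")
    grid, cum = res.grid, res.phi_cumulative
    lam, w, yc, fyc = model.lam, model.w, model.y_c, model.f_yc
    lam_w = lam / w

    w_vals = _exp_lam_T(model, grid)
    cell = 0.5 * (w_vals[1:] + w_vals[:-1]) * np.diff(cum)
    R = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
    c = float(R[0])

    # grid below f(y_c): geometric down to where the closed-form mass is tiny
    y_lo = yc * (mass_tol / max(c, 1e-300)) ** (1.0 / lam_w)
    low = np.geomspace(y_lo, fyc, 512)
    psi_grid = np.unique(np.concatenate([low, grid]))
    G = np.where(
        psi_grid <= fyc,
        c,
        np.interp(psi_grid, grid, R, right=0.0),
    )
    psi = (lam / (w * psi_grid)) * (psi_grid / yc) ** lam_w * G

    # cumulative: closed form below f(y_c), trapezoid above
    psi_cum = np.empty_like(psi_grid)
    below = psi_grid <= fyc
    psi_cum[below] = c * (psi_grid[below] / yc) ** lam_w
    ia = np.flatnonzero(~below)
    run = c * (fyc / yc) ** lam_w
    prev_y, prev_v = fyc, (lam / (w * fyc)) * (fyc / yc) ** lam_w * c
    for i in ia:
        run += 0.5 * (psi[i] + prev_v) * (psi_grid[i] - prev_y)
        psi_cum[i] = run
        prev_y, prev_v = psi_grid[i], psi[i]

    res.psi_grid = psi_grid
    res.psi = psi
    res.psi_cumulative = psi_cum
    res.residuals["psi_mass_defect"] = abs(psi_cum[-1] + res.tail_mass - 1.0)
    res.residuals["pushforward_l1"] = pushforward_through_boost(model, res)
    res.residuals["forward_equation_sup"] = forward_equation_residual(model, res)
    return res


def pushforward_through_boost(model: ModelIngredients, res: StationaryResult) -> float:
    """L1 distance between the density of f(Y), Y ~ psi, and phi.

    Stationarity means the level just after a jump from a stationary draw is
    again a post-jump draw: f_* psi = phi.  Computed by change of variables
    through both monotone branches of f."""
    grid = res.grid
    interior = grid[(grid > model.f_yc * 1.0005) & (grid < grid[-1] * 0.999)]
    u = f_inverse(model, interior, "plus")
    v = f_inverse(model, interior, "minus")
    psi_u = np.interp(u, res.psi_grid, res.psi)
    psi_v = np.interp(v, res.psi_grid, res.psi, left=0.0)
    push = psi_u / np.abs(boost_derivative(model, u)) + psi_v / np.abs(
        boost_derivative(model, v)
    )
    phi_i = np.interp(interior, grid, res.phi)
    return float(np.trapezoid(np.abs(push - phi_i), interior))


def forward_equation_residual(
    model: ModelIngredients, res: StationaryResult, exclusion: float = 0.05
) -> float:
    """Sup-norm residual of the stationary forward (master) equation

        d/dy (g psi) + lam psi - lam phi 1{y >= f(y_c)} = 0

    by central differences on the psi grid.  Relative neighbourhoods of
    f(y_c) and f(f(y_c)) are excluded: phi has an inverse-sqrt singularity at
    the former and a derivative jump at the latter, so finite differences of
    g*psi are inaccurate there although the identity holds pointwise.
    """
    y = res.psi_grid
    gpsi = model.g(y) * res.psi
    d = np.gradient(gpsi, y)
    phi_at = np.where(y >= model.f_yc, np.interp(y, res.grid, res.phi, left=0.0), 0.0)
    resid = d + model.lam * res.psi - model.lam * phi_at
    keep = (
        (np.abs(y - model.f_yc) > exclusion * model.f_yc)
        & (np.abs(y - model.f2_yc) > 0.02 * model.f2_yc)
        & (y < y[-1] * 0.99)
        & (y > y[0] * 1.01)
    )
    return float(np.max(np.abs(resid[keep])))


# ---------------------------------------------------------------------------
# Convergence diagnostics (numerical asymptotic stability)
# ---------------------------------------------------------------------------

def convergence_diagnostic(
    model: ModelIngredients,
    initial_levels,
    time_points,
    n: int,
    seed: int,
    res: StationaryResult,
) -> list[dict]:
    """Distance of the simulated age-marginal distribution to psi over time.

    ``initial_levels`` may be a scalar (all hosts start there) or an array of
    length n.  Returns one record per time point with the KS distance to the
    psi CDF, a binned L1 distance, and the Monte-Carlo scale 1/sqrt(n).
    """
    from .simulate import _ensemble_levels, _rng

    time_points = np.sort(np.asarray(time_points, dtype=float))
    rng = _rng(seed)
    starts = np.full(n, float(initial_levels)) if np.ndim(initial_levels) == 0 else np.asarray(
        initial_levels, dtype=float
    )
    levels, _ = _ensemble_levels(model, starts, float(time_points[-1]), rng, record_ages=time_points)
    out = []
    edges = np.geomspace(res.psi_grid[0], res.psi_grid[-1], 64)
    psi_cell = np.diff(res.psi_cdf(edges))
    for ci, t in enumerate(time_points):
        x = np.sort(levels[:, ci])
        emp = np.arange(1, n + 1) / n
        ks = float(np.max(np.abs(emp - res.psi_cdf(x))))
        hist, _ = np.histogram(x, bins=edges)
        l1 = float(np.sum(np.abs(hist / n - psi_cell)))
        out.append({"t": float(t), "ks": ks, "l1": l1, "mc_se": 1.0 / np.sqrt(n)})
    return out


# ---------------------------------------------------------------------------
# Expected passage time to the critical level
# ---------------------------------------------------------------------------

@dataclass
class PassageTimeResult:
    """Expected first-passage time S(y) to the critical level on a grid."""

    model: ModelIngredients
    grid: np.ndarray
    S: np.ndarray
    iterations: int
    sup_update: float
    extrapolated_fraction: float

    def __call__(self, y):
        return np.interp(np.log(np.asarray(y, dtype=float)), np.log(self.grid), self.S)


def solve_passage_time(
    model: ModelIngredients,
    y_max: float = 300.0,
    n_grid: int = 600,
    tolerance: float = 1e-10,
    max_iter: int = 200000,
    method: str = "direct",
    n_quad: int = 64,
) -> PassageTimeResult:
    """Solve the renewal equation for the expected time S(y) to reach y_c.

        S(y) = (1 - e^{-lam tau}) / lam
               + int_0^tau lam e^{-lam s} S(f(pi(s, y))) ds,   tau = tau(y, y_c),

    discretized on a log-spaced grid over (y_c, y_max] with Gauss-Legendre
    quadrature of the jump integral and log-linear interpolation of S (linear
    extrapolation in log y above y_max, fraction reported).  The discretized
    fixed point is solved directly (``method='direct'``) or by Picard
    iteration (``method='picard'``); the sup-norm fixed-point update at the
    returned solution is reported either way.
    """
    yc, lam = model.y_c, model.lam
    grid = np.geomspace(yc * (1.0 + 1e-8), y_max, n_grid)
    tau = transit_time(model, grid, yc)
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    # map to (0, tau_i)
    s = 0.5 * tau[:, None] * (nodes[None, :] + 1.0)
    wq = 0.5 * tau[:, None] * wts[None, :] * lam * np.exp(-lam * s)
    eta = boost(model, wane(model, s, grid[:, None]))
    loggrid = np.log(grid)
    pos = np.clip(np.searchsorted(loggrid, np.log(eta)) - 1, 0, n_grid - 2)
    th = (np.log(eta) - loggrid[pos]) / (loggrid[pos + 1] - loggrid[pos])
    extrapolated = float(np.mean(eta > grid[-1]))

    A = np.zeros((n_grid, n_grid))
    rows = np.repeat(np.arange(n_grid), n_quad)
    np.add.at(A, (rows, pos.ravel()), (wq * (1.0 - th)).ravel())
    np.add.at(A, (rows, (pos + 1).ravel()), (wq * th).ravel())
    rhs = (1.0 - np.exp(-lam * tau)) / lam

    if method == "direct":
        S = np.linalg.solve(np.eye(n_grid) - A, rhs)
        iters = 1
    elif method == "picard":
        S = rhs.copy()
        iters = max_iter
        for it in range(1, max_iter + 1):
            S_new = A @ S + rhs
            upd = float(np.max(np.abs(S_new - S)))
            S = S_new
            if upd < tolerance:
                iters = it
                break
        else:
            raise RuntimeError(
                f"passage-time iteration did not converge in {max_iter} sweeps "
                f"(last update {upd:.2e}); the mean passage time may be infinite "
                "for these parameters"
            )
    else:
        raise ValueError("method must be 'direct' or 'picard'")
    sup_update = float(np.max(np.abs(A @ S + rhs - S)))
    if np.any(S < tau - 1e-9):
        raise RuntimeError("solution violates the lower bound S >= transit time")
    return PassageTimeResult(
        model=model,
        grid=grid,
        S=S,
        iterations=iters,
        sup_update=sup_update,
        extrapolated_fraction=extrapolated,
    )


# ---------------------------------------------------------------------------
# Force-of-infection consistency
# ---------------------------------------------------------------------------

def lambda_consistency_residual(
    model: ModelIngredients,
    xi: Callable[[np.ndarray], np.ndarray],
    survival_sampler: Callable[[np.random.Generator, int], np.ndarray],
    birth_sampler: Callable[[np.random.Generator, int], np.ndarray],
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo residual of the demographic force-of-infection balance.

    The force of infection is consistent when the population-averaged
    infectivity equals one:  1 = E[ xi(Y(A)) ] with A drawn from the stable
    age density (survival function normalized) and Y(A) the immune level of a
    host of age A born at a level drawn from the birth distribution.  Returns
    (mean xi - 1, standard error).
    """
    from .simulate import _levels_at_ages, _rng

    rng = _rng(seed)
    ages = np.asarray(survival_sampler(rng, n), dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages sampled from the survival distribution must be >= 0")
    births = np.asarray(birth_sampler(rng, n), dtype=float)
    levels = _levels_at_ages(model, births, ages, rng)
    vals = np.asarray(xi(levels), dtype=float)
    return float(np.mean(vals) - 1.0), float(np.std(vals, ddof=1) / np.sqrt(n))


def solve_lambda(
    base: ModelIngredients,
    xi,
    survival_sampler,
    birth_sampler,
    bracket: tuple[float, float],
    n: int = 20000,
    seed: int = 0,
) -> float:
    """Bracketing root finder for the force of infection that balances the
    consistency condition, using common random numbers across evaluations."""

    def resid(lam: float) -> float:
        m = ModelIngredients(lam=lam, w=base.w, sigma1=base.sigma1, sigma2=base.sigma2, y_b=base.y_b)
        return lambda_consistency_residual(m, xi, survival_sampler, birth_sampler, n, seed)[0]

    return float(optimize.brentq(resid, *bracket, xtol=1e-3))
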