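"""Closed-form algebra of the waning-and-boosting model ingredients.

The immune status of a host is a positive scalar ``y`` (an antibody titer).
Between exposures it wanes deterministically, ``dy/dt = g(y)`` with
``g(y) = -w*y`` (exponential decline at rate ``w``).  Exposures arrive as a
Poisson process with constant force of infection ``lam``; an exposure at
level ``y`` boosts the host instantaneously to ``f(y)``, with the canonical
within-host boosting map

    f(y) = y * (1 + sigma2 / y) ** sigma1,   sigma1 > 1, sigma2 > 0.

``f`` decreases on ``(0, y_c)`` and increases on ``(y_c, inf)`` where
``y_c = (sigma1 - 1) * sigma2`` is the *critical level* separating large
("symptomatic") boosts from small ("asymptomatic") increments; for large
``y`` the boost tends to the constant increment ``delta = sigma1 * sigma2``.

This module provides the flow ``wane``, its time parametrization
``waning_time`` (the signed time needed to wane from the critical level),
the boosting map and its two inverse branches, the coefficient functions
``alpha``/``beta`` that drive the stationary post-jump density, and the
advisory condition checks that the downstream solvers rely on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ModelIngredients",
    "ConditionReport",
    "InvalidModelError",
    "ConditionError",
    "PRESETS",
    "canonical_model",
    "model_from_dict",
    "wane",
    "waning_time",
    "waning_time_inverse",
    "transit_time",
    "boost",
    "boost_derivative",
    "critical_level",
    "f_inverse",
    "alpha",
    "beta",
    "survival_to_critical",
    "check_conditions",
    "probe_grid",
]


class InvalidModelError(ValueError):
    """Raised when parameters violate the model hypotheses."""


class ConditionError(RuntimeError):
    """Raised by solvers when a required sufficient condition fails."""


@dataclass(frozen=True)
class ModelIngredients:
    """The parameter set (lam, w, sigma1, sigma2, y_b) plus derived constants.

    Attributes
    ----------
    lam : float
        Force of infection (exposures per unit time), > 0.
    w : float
        Waning rate (per unit time), > 0.
    sigma1 : float
        Boost shape (dimensionless), > 1.
    sigma2 : float
        Boost scale (immune-level units), > 0.
    y_b : float
        Immune level at birth.
    """

    lam: float
    w: float
    sigma1: float
    sigma2: float
    y_b: float = 1.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise InvalidModelError(f"force of infection must be > 0, got {self.lam}")
        if not self.w > 0:
            raise InvalidModelError(f"waning rate must be > 0, got {self.w}")
        if not self.sigma1 > 1:
            raise InvalidModelError(
                f"boost shape sigma1 must be > 1 (otherwise f is monotone), got {self.sigma1}"
            )
        if not self.sigma2 > 0:
            raise InvalidModelError(f"boost scale sigma2 must be > 0, got {self.sigma2}")
        if not self.y_b > 0:
            raise InvalidModelError(f"birth immune level must be > 0, got {self.y_b}")

    # -- derived constants -------------------------------------------------
    @property
    def y_c(self) -> float:
        """Critical level: the unique minimizer of the boosting map."""
        return (self.sigma1 - 1.0) * self.sigma2

    @property
    def f_yc(self) -> float:
        """Boosted critical level f(y_c), the lower edge of the post-jump support."""
        return boost(self, self.y_c)

    @property
    def f2_yc(self) -> float:
        """Twice-boosted critical level f(f(y_c))."""
        return boost(self, self.f_yc)

    @property
    def delta(self) -> float:
        """Asymptotic jump size: f(y) - y -> sigma1 * sigma2 as y -> inf."""
        return self.sigma1 * self.sigma2

    def g(self, y):
        """Waning speed g(y) = -w*y (negative)."""
        return -self.w * np.asarray(y, dtype=float)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "w": self.w,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "y_b": self.y_b,
        }


PRESETS: dict[str, dict] = {
    "canonical": {"lambda": 1.5, "w": 1.0, "sigma1": 2.0, "sigma2": 1.0, "y_b": 4.0},
}


def canonical_model() -> ModelIngredients:
    return model_from_dict(PRESETS["canonical"])


def model_from_dict(d: dict) -> ModelIngredients:
    """Build a model from a config mapping with keys lambda/w/sigma1/sigma2/y_b."""
    lam = d.get("lambda", d.get("lam"))
    if lam is None:
        raise InvalidModelError("config must provide 'lambda'")
    return ModelIngredients(
        lam=float(lam),
        w=float(d["w"]),
        sigma1=float(d["sigma1"]),
        sigma2=float(d["sigma2"]),
        y_b=float(d.get("y_b", 1.0)),
    )


def _require_positive(y, what: str = "immune level"):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(~np.isfinite(y)):
        raise ValueError(f"{what} must be positive and finite, got {y}")
    return y


# ---------------------------------------------------------------------------
# Flow and time parametrization
# ---------------------------------------------------------------------------

def wane(model: ModelIngredients, t, y):
    """Deterministic waning flow pi(t, y) = exp(-w t) * y.

    ``t`` may be negative (backward flow).  Satisfies the semigroup property
    pi(s, pi(t, y)) = pi(s + t, y).
    """
    y = _require_positive(y)
    return np.exp(-model.w * np.asarray(t, dtype=float)) * y


def waning_time(model: ModelIngredients, y):
    """Signed time T(y) = (1/w) log(y_c / y) to wane from the critical level to y.

    T is strictly decreasing with T(y_c) = 0; positive below y_c, negative
    above.  Inverse: :func:`waning_time_inverse`.
    """
    y = _require_positive(y)
    return np.log(model.y_c / y) / model.w


def waning_time_inverse(model: ModelIngredients, a):
    """Inverse of the time parametrization: T^{-1}(a) = exp(-w a) * y_c."""
    return np.exp(-model.w * np.asarray(a, dtype=float)) * model.y_c


def transit_time(model: ModelIngredients, y1, y2):
    """Waning time from level y1 down to y2; zero when y2 >= y1.

    tau(y1, y2) = T(y2) - T(y1) when y2 <= y1, extended by zero otherwise,
    so that pi(tau(y1, y2), y1) = y2 whenever y2 <= y1.
    """
    y1 = _require_positive(y1)
    y2 = _require_positive(y2)
    return np.maximum(0.0, np.log(np.asarray(y1) / np.asarray(y2)) / model.w)


# ---------------------------------------------------------------------------
# Boosting map and its inverse branches
# ---------------------------------------------------------------------------

def boost(model: ModelIngredients, y):
    """Boosting map f(y) = y (1 + sigma2/y)^sigma1; always f(y) > y >= ... >= f(y_c)."""
    y = _require_positive(y)
    return y * (1.0 + model.sigma2 / y) ** model.sigma1


def boost_derivative(model: ModelIngredients, y):
    """f'(y) = (1 + sigma2/y)^(sigma1-1) * (y + (1 - sigma1) sigma2) / y.

    Negative below y_c, zero at y_c, positive above.
    """
    y = _require_positive(y)
    s1, s2 = model.sigma1, model.sigma2
    return (1.0 + s2 / y) ** (s1 - 1.0) * (y + (1.0 - s1) * s2) / y


def critical_level(model: ModelIngredients) -> float:
    """The unique root y_c = (sigma1 - 1) sigma2 of f'."""
    return model.y_c


def f_inverse(model: ModelIngredients, x, branch: str):
    """Inverse of the boosting map on one monotone branch.

    Parameters
    ----------
    x : array-like
        Levels in the range of f, i.e. >= f(y_c).
    branch : {"minus", "plus"}
        "minus" returns the preimage below y_c, "plus" the one above.
        Both branches return y_c at x = f(y_c).
    """
    if branch not in ("minus", "plus"):
        raise ValueError(f"branch must be 'minus' or 'plus', got {branch!r}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    fyc = model.f_yc
    if np.any(x < fyc * (1.0 - 1e-12)):
        raise ValueError(f"no preimage: x < f(y_c) = {fyc}")
    x = np.maximum(x, fyc)
    if model.sigma1 == 2.0:
        # (y + sigma2)^2 / y = x  is a quadratic in y with roots
        # ((x - 2 s2) -+ sqrt((x - 2 s2)^2 - 4 s2^2)) / 2
        s2 = model.sigma2
        b = x - 2.0 * s2
        disc = np.sqrt(np.maximum(b * b - 4.0 * s2 * s2, 0.0))
        out = (b - disc) / 2.0 if branch == "minus" else (b + disc) / 2.0
        out = np.clip(out, None, model.y_c) if branch == "minus" else np.maximum(out, model.y_c)
    else:
        out = _f_inverse_bisect(model, x, branch)
    return float(out[0]) if scalar else out


def _f_inverse_bisect(model: ModelIngredients, x: np.ndarray, branch: str) -> np.ndarray:
    """Vectorized bisection on one strictly monotone branch of f."""
    yc = model.y_c
    if branch == "plus":
        lo = np.full_like(x, yc)
        hi = np.maximum(x, yc * (1.0 + 1e-9))  # f(x) > x so the root is below x
        increasing = True
    else:
        hi = np.full_like(x, yc)
        lo = np.full_like(x, yc)
        # shrink geometrically until f(lo) >= x (f -> inf as y -> 0)
        need = boost(model, lo) < x
        while np.any(need):
            lo[need] *= 0.5
            need = boost(model, lo) < x
        increasing = False
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = boost(model, mid)
        go_right = (fm < x) if increasing else (fm > x)
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
        if np.max(hi - lo) <= 1e-14 * np.max(hi):
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Coefficient functions for the stationary post-jump density
# ---------------------------------------------------------------------------

def alpha(model: ModelIngredients, y):
    """alpha(y) = -lam / (g(u) f'(u)) with u = f_+^{-1}(y); positive.

    Equals -lam * d/dy T(f_+^{-1}(y)).  Diverges as y -> f(y_c)+ because
    f'(y_c) = 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= model.f_yc):
        raise ValueError("alpha requires y > f(y_c)")
    u = f_inverse(model, y, "plus")
    return -model.lam / (model.g(u) * boost_derivative(model, u))


def beta(model: ModelIngredients, y):
    """beta(y) = lam / (g(v) f'(v)) with v = f_-^{-1}(y); positive."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= model.f_yc):
        raise ValueError("beta requires y > f(y_c)")
    v = f_inverse(model, y, "minus")
    return model.lam / (model.g(v) * boost_derivative(model, v))


def survival_to_critical(model: ModelIngredients, eta):
    """exp(lam * T(eta)) = (y_c/eta)^(lam/w) for eta >= y_c.

    The probability of waning from eta all the way to the critical level
    without being hit by an exposure.
    """
    eta = _require_positive(eta)
    return (model.y_c / np.asarray(eta)) ** (model.lam / model.w)


# ---------------------------------------------------------------------------
# Condition checks
# ---------------------------------------------------------------------------

def probe_grid(model: ModelIngredients, n: int = 512, span: float = 1e3) -> np.ndarray:
    """Geometric probe grid spanning [y_c/span, y_c*span].

    Geometric spacing is uniform in the waning-time coordinate, so it
    equidistributes flow time across the grid.
    """
    yc = model.y_c
    return np.geomspace(yc / span, yc * span, n)


@dataclass
class ConditionReport:
    """Advisory report on the sufficient conditions for the stationary theory.

    Maps a condition identifier to ``(holds, witnesses)`` where the witnesses
    are the numerical evaluations used to decide it.  Checking never raises;
    solvers that require a condition consult the report and refuse with an
    explanatory error when it fails.

    Identifiers
    -----------
    expected_jump_contraction
        f(pi(rho/lam, y)) < y for all probed y >= f_+^{-1}(z): jumping after
        a (rho-discounted) mean exposure interval loses immunity high up.
    foi_exceeds_waning_gap
        lam > w (sigma1 - 1): sufficient for integrability of the post-jump
        density tail for the canonical family.
    waning_speed_margin
        For g = -w y the waning speed is unbounded below, so the contraction
        headroom v rho/lam + delta < 0 is attainable for any rho in (0, 1).
    tail_integrability
        Summary flag: holds when foi_exceeds_waning_gap holds (sufficient
        condition for the canonical family).
    postponed_jump_monotonicity
        f'(y) g(y) / g(f(y)) < 1 everywhere: postponing a jump lands the host
        higher.  For the canonical family this always holds; the closed-form
        witness is f'(y) g(y) - g(f(y)) = w sigma1 sigma2 (1+sigma2/y)^(sigma1-1) > 0.
    alpha_delta_subcritical
        alpha(y) * delta < 1 at the top of the probe grid: the local
        characteristic-equation heuristic for tail decay.
    """

    entries: dict[str, tuple[bool, dict]] = field(default_factory=dict)

    def holds(self, key: str) -> bool:
        return self.entries[key][0]

    def witnesses(self, key: str) -> dict:
        return self.entries[key][1]

    def all_hold(self, *keys: str) -> bool:
        return all(self.holds(k) for k in keys)

    def to_json(self) -> str:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        payload = {
            k: {"holds": bool(h), "witnesses": {n: _clean(v) for n, v in w.items()}}
            for k, (h, w) in self.entries.items()
        }
        return json.dumps(payload, indent=2)


def check_conditions(
    model: ModelIngredients,
    rho: float = 0.9,
    grid: np.ndarray | None = None,
) -> ConditionReport:
    """Evaluate the sufficient conditions for existence/stability of the
    stationary immune-status distribution.  Advisory: never raises."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    if grid is None:
        grid = probe_grid(model)
    rep = ConditionReport()

    # contraction of the boost-after-mean-wait map high up the axis
    z = _default_contraction_anchor(model, rho, grid)
    lo = f_inverse(model, z, "plus")
    ys = grid[grid >= lo]
    if ys.size == 0:
        ys = np.array([lo * 1.01, lo * 10.0])
    mapped = boost(model, wane(model, rho / model.lam, ys))
    holds_325 = bool(np.all(mapped < ys))
    rep.entries["expected_jump_contraction"] = (
        holds_325,
        {"rho": rho, "z": z, "y": ys, "f_pi_y": mapped, "max_ratio": float(np.max(mapped / ys))},
    )

    # lam > w (sigma1 - 1)
    gap = model.lam - model.w * (model.sigma1 - 1.0)
    rep.entries["foi_exceeds_waning_gap"] = (
        bool(gap > 0),
        {"lam": model.lam, "w_times_sigma1_minus_1": model.w * (model.sigma1 - 1.0), "margin": gap},
    )

    # g = -w y is unbounded below: any rho in (0,1) gives v rho/lam + delta < 0
    # by taking z large enough (v = -w z).
    z_need = model.delta * model.lam / (model.w * rho)
    v = -model.w * 2.0 * z_need
    rep.entries["waning_speed_margin"] = (
        True,
        {"rho": rho, "z": 2.0 * z_need, "v": v, "v_rho_over_lam_plus_delta": v * rho / model.lam + model.delta},
    )

    rep.entries["tail_integrability"] = (
        rep.holds("foi_exceeds_waning_gap"),
        {"via": "foi_exceeds_waning_gap", "margin": gap},
    )

    # f'(y) g(y) / g(f(y)) < 1 on the probe grid + canonical closed-form sign
    ratio = boost_derivative(model, grid) * model.g(grid) / model.g(boost(model, grid))
    sign_wit = model.w * model.sigma1 * model.sigma2 * (1.0 + model.sigma2 / grid) ** (model.sigma1 - 1.0)
    rep.entries["postponed_jump_monotonicity"] = (
        bool(np.all(ratio < 1.0)) and bool(np.all(sign_wit > 0.0)),
        {"max_ratio": float(np.max(ratio)), "min_sign_witness": float(np.min(sign_wit))},
    )

    # alpha * delta < 1 near the top of the probe grid (tail heuristic)
    ytop = grid[grid > model.f_yc * 1.05][-8:]
    if ytop.size:
        ad = alpha(model, ytop) * model.delta
        rep.entries["alpha_delta_subcritical"] = (
            bool(np.all(ad < 1.0)),
            {"y": ytop, "alpha_delta": ad},
        )
    else:
        rep.entries["alpha_delta_subcritical"] = (False, {"y": ytop, "alpha_delta": np.array([])})
    return rep


def _default_contraction_anchor(model: ModelIngredients, rho: float, grid: np.ndarray) -> float:
    """Anchor level z >= f(f(y_c)) above which the contraction check applies:
    the larger of f(f(y_c)) and the first grid level where the boost-after-wait
    map is below the identity."""
    mapped = boost(model, wane(model, rho / model.lam, grid))
    below = grid[mapped < grid]
    cand = below[0] if below.size else grid[-1]
    # z lives in the image of f: the probed region starts at f_+^{-1}(z) = cand
    return float(max(model.f2_yc, boost(model, cand)))
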