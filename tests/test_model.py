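"""Closed-form algebra of the model ingredients: flow, time parametrization,
boosting map, inverse branches, coefficient functions, condition checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

import waneboost as wb
from waneboost.model import InvalidModelError


# ---------------------------------------------------------------------------
# waning flow and time parametrization
# ---------------------------------------------------------------------------

class TestFlow:
    def test_identity_at_zero(self, canonical):
        assert wb.wane(canonical, 0.0, 3.7) == 3.7

    def test_halving_time_matches_ode_integration(self, canonical):
        # independent oracle: integrate dy/dt = -w y numerically
        sol = solve_ivp(lambda t, y: -canonical.w * y, (0, np.log(2)), [4.0], rtol=1e-12, atol=1e-14)
        assert wb.wane(canonical, np.log(2), 4.0) == pytest.approx(2.0, abs=1e-12)
        assert sol.y[0, -1] == pytest.approx(2.0, abs=1e-9)

    def test_backward_flow(self, canonical):
        assert wb.wane(canonical, -np.log(2), 2.0) == pytest.approx(4.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        s=st.floats(-3, 3), t=st.floats(-3, 3),
        y=st.floats(0.01, 100.0),
    )
    def test_semigroup_property(self, s, t, y):
        m = wb.canonical_model()
        lhs = wb.wane(m, s, wb.wane(m, t, y))
        rhs = wb.wane(m, s + t, y)
        assert abs(lhs - rhs) < 1e-12 * max(1.0, rhs)

    def test_flow_y_derivative_identity(self, canonical, rng):
        # d pi/d y (t, y) = g(pi(t,y)) / g(y), checked by central differences
        for _ in range(20):
            t = rng.uniform(0, 3)
            y = rng.uniform(0.1, 50)
            h = 1e-6 * y
            fd = (wb.wane(canonical, t, y + h) - wb.wane(canonical, t, y - h)) / (2 * h)
            exact = canonical.g(wb.wane(canonical, t, y)) / canonical.g(y)
            assert fd == pytest.approx(float(exact), rel=1e-6)

    def test_flow_through_time_parametrization(self, canonical, rng):
        # pi(t - t0, y0) = T^{-1}(t - t0 + T(y0))
        for _ in range(20):
            dt = rng.uniform(-2, 2)
            y0 = rng.uniform(0.1, 30)
            lhs = wb.wane(canonical, dt, y0)
            rhs = wb.waning_time_inverse(canonical, dt + wb.waning_time(canonical, y0))
            assert abs(lhs - rhs) < 1e-10 * max(1.0, lhs)

    def test_domain_errors(self, canonical):
        with pytest.raises(ValueError):
            wb.wane(canonical, 1.0, -2.0)
        with pytest.raises(ValueError):
            wb.waning_time(canonical, 0.0)


class TestWaningTime:
    def test_zero_at_critical_level(self, canonical):
        assert wb.waning_time(canonical, canonical.y_c) == 0.0

    def test_closed_form(self, canonical):
        assert wb.waning_time(canonical, 4.0) == pytest.approx(-np.log(4))

    def test_inverse_round_trip(self, canonical):
        assert wb.waning_time_inverse(canonical, wb.waning_time(canonical, 0.3)) == pytest.approx(
            0.3, rel=1e-12
        )

    def test_strictly_decreasing(self, canonical):
        ys = np.geomspace(0.01, 100, 64)
        assert np.all(np.diff(wb.waning_time(canonical, ys)) < 0)


class TestTransitTime:
    def test_zero_when_target_above(self, canonical):
        assert wb.transit_time(canonical, 2.0, 5.0) == 0.0

    def test_equal_levels(self, canonical):
        assert wb.transit_time(canonical, 0.7, 0.7) == 0.0

    def test_closed_form_and_flow_consistency(self, canonical):
        tau = wb.transit_time(canonical, 4.0, 1.0)
        assert tau == pytest.approx(np.log(4))
        assert wb.wane(canonical, tau, 4.0) == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# boosting map
# ---------------------------------------------------------------------------

class TestBoost:
    @pytest.mark.parametrize("y,expected", [(1.0, 4.0), (0.5, 4.5)])
    def test_values(self, canonical, y, expected):
        assert wb.boost(canonical, y) == pytest.approx(expected)

    def test_always_above_identity_and_floor(self, canonical):
        ys = np.geomspace(1e-3, 1e3, 256)
        fy = wb.boost(canonical, ys)
        assert np.all(fy > ys)
        assert np.all(fy >= canonical.f_yc - 1e-12)

    def test_asymptotic_increment(self, canonical):
        # f(y) - y -> sigma1 sigma2 for large y
        assert wb.boost(canonical, 1e6) - 1e6 == pytest.approx(canonical.delta, abs=1e-4)

    def test_shape_around_critical_level(self, canonical):
        ys = np.geomspace(1e-2, 1e2, 512)
        fy = wb.boost(canonical, ys)
        yc = canonical.y_c
        below, above = ys < yc, ys > yc
        assert np.all(np.diff(fy[below]) < 0)
        assert np.all(np.diff(fy[above]) > 0)


class TestCriticalLevel:
    @pytest.mark.parametrize(
        "s1,s2,expected", [(2.0, 1.0, 1.0), (3.0, 0.5, 1.0), (1.5, 2.0, 1.0)]
    )
    def test_formula_matches_minimizer(self, s1, s2, expected):
        m = wb.ModelIngredients(lam=1.0, w=1.0, sigma1=s1, sigma2=s2)
        assert wb.critical_level(m) == pytest.approx(expected)
        opt = minimize_scalar(lambda y: wb.boost(m, y), bounds=(1e-3, 50), method="bounded")
        assert opt.x == pytest.approx(expected, rel=1e-5)

    def test_derivative_vanishes(self, canonical):
        yc = canonical.y_c
        h = 1e-5
        fd = (wb.boost(canonical, yc + h) - wb.boost(canonical, yc - h)) / (2 * h)
        assert abs(fd) < 1e-9
        assert abs(wb.boost_derivative(canonical, yc)) < 1e-14

    def test_monotone_map_rejected(self):
        with pytest.raises(InvalidModelError):
            wb.ModelIngredients(lam=1.0, w=1.0, sigma1=1.0, sigma2=1.0)


class TestFInverse:
    def test_quadratic_closed_form(self, canonical):
        assert wb.f_inverse(canonical, 4.5, "plus") == pytest.approx(2.0, rel=1e-12)
        assert wb.f_inverse(canonical, 4.5, "minus") == pytest.approx(0.5, rel=1e-12)

    def test_branches_meet_at_minimum(self, canonical):
        for branch in ("plus", "minus"):
            assert wb.f_inverse(canonical, canonical.f_yc, branch) == pytest.approx(1.0, rel=1e-9)

    def test_round_trip(self, canonical):
        for branch in ("plus", "minus"):
            y = wb.f_inverse(canonical, 7.3, branch)
            assert wb.boost(canonical, y) == pytest.approx(7.3, rel=1e-10)

    def test_branches_bracket_critical_level(self, canonical):
        xs = np.geomspace(canonical.f_yc * 1.001, 1e3, 64)
        assert np.all(wb.f_inverse(canonical, xs, "minus") <= canonical.y_c)
        assert np.all(wb.f_inverse(canonical, xs, "plus") >= canonical.y_c)

    def test_bisection_branch_general_shape(self):
        m = wb.ModelIngredients(lam=1.0, w=1.0, sigma1=2.7, sigma2=0.8)
        xs = np.geomspace(m.f_yc * 1.0001, 500, 40)
        for branch in ("plus", "minus"):
            roots = wb.f_inverse(m, xs, branch)
            assert np.allclose(wb.boost(m, roots), xs, rtol=1e-10)

    def test_below_range_rejected(self, canonical):
        with pytest.raises(ValueError):
            wb.f_inverse(canonical, canonical.f_yc - 0.1, "plus")


# ---------------------------------------------------------------------------
# coefficient functions
# ---------------------------------------------------------------------------

class TestAlphaBeta:
    def test_closed_values(self, canonical):
        # at y = 4.5: f_+^{-1} = 2 (g = -2, f' = 0.75), f_-^{-1} = 0.5 (g = -0.5, f' = -3)
        assert wb.alpha(canonical, 4.5) == pytest.approx(1.0, rel=1e-10)
        assert wb.beta(canonical, 4.5) == pytest.approx(1.0, rel=1e-10)

    def test_match_numerical_derivative_of_waning_times(self, canonical):
        lam = canonical.lam
        for y in [4.3, 5.0, 6.25, 9.0, 40.0]:
            h = 1e-6 * y
            tp = lambda x: wb.waning_time(canonical, wb.f_inverse(canonical, x, "plus"))
            tm = lambda x: wb.waning_time(canonical, wb.f_inverse(canonical, x, "minus"))
            a_fd = -lam * (tp(y + h) - tp(y - h)) / (2 * h)
            b_fd = lam * (tm(y + h) - tm(y - h)) / (2 * h)
            assert wb.alpha(canonical, y) == pytest.approx(a_fd, rel=1e-6)
            assert wb.beta(canonical, y) == pytest.approx(b_fd, rel=1e-6)

    def test_positive_on_log_grid(self, canonical):
        ys = np.geomspace(canonical.f_yc * 1.001, 1e3, 128)
        assert np.all(wb.alpha(canonical, ys) > 0)
        assert np.all(wb.beta(canonical, ys) > 0)

    def test_domain_error_at_or_below_floor(self, canonical):
        with pytest.raises(ValueError):
            wb.alpha(canonical, canonical.f_yc)


# ---------------------------------------------------------------------------
# condition checks
# ---------------------------------------------------------------------------

class TestConditions:
    def test_foi_gap_holds_iff_lam_exceeds(self):
        good = wb.ModelIngredients(lam=1.5, w=1.0, sigma1=2.0, sigma2=1.0)
        bad = wb.ModelIngredients(lam=0.5, w=1.0, sigma1=2.0, sigma2=1.0)
        assert wb.check_conditions(good).holds("foi_exceeds_waning_gap")
        assert not wb.check_conditions(bad).holds("foi_exceeds_waning_gap")

    @pytest.mark.parametrize("w,s1,s2", [(1.0, 2.0, 1.0), (0.3, 4.0, 0.2), (2.5, 1.2, 3.0)])
    def test_postponed_jump_monotonicity_holds_for_family(self, w, s1, s2):
        m = wb.ModelIngredients(lam=1.0, w=w, sigma1=s1, sigma2=s2)
        rep = wb.check_conditions(m)
        assert rep.holds("postponed_jump_monotonicity")

    def test_contraction_holds_for_canonical(self, canonical):
        rep = wb.check_conditions(canonical)
        assert rep.holds("expected_jump_contraction")
        assert rep.witnesses("expected_jump_contraction")["max_ratio"] < 1.0

    def test_advisory_never_raises_and_serializes(self):
        bad = wb.ModelIngredients(lam=0.1, w=2.0, sigma1=3.0, sigma2=1.0)
        rep = wb.check_conditions(bad)  # several conditions fail; no exception
        payload = rep.to_json()
        assert '"holds"' in payload and '"witnesses"' in payload


class TestConfig:
    def test_preset_round_trip(self, canonical):
        m = wb.model_from_dict(canonical.to_dict())
        assert m == canonical

    def test_invalid_parameters_rejected(self):
        for kw in [dict(lam=-1), dict(w=0), dict(sigma1=0.5), dict(sigma2=-2)]:
            params = dict(lam=1.5, w=1.0, sigma1=2.0, sigma2=1.0)
            params.update(kw)
            with pytest.raises(InvalidModelError):
                wb.ModelIngredients(**params)
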