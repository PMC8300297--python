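"""Production-economics calculus: marginal products, isoquants, RTS,
isoclines, unconstrained and budget-constrained optima."""

import numpy as np
import pytest

from feedopt import (
    PriceSet,
    ReducedQuadratic,
    constrained_optimum,
    isoquant_x1,
    isoquant_x2,
    least_cost_isocline_x2,
    marginal_products,
    optimal_inputs,
    profit,
    reduce_to_quadratic,
    rts,
)


from _helpers import random_problem


def spring_q(scenarios, coeffs):
    return reduce_to_quadratic(coeffs, scenarios["spring"].state)


class TestMarginalProducts:
    def test_spring_at_current_intakes(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        mp1, mp2 = marginal_products(q, 2.0, 10.6)
        # direct substitution: 0.107 - 2*0.005*2 - 0.002*10.6 etc.
        assert mp1 == pytest.approx(0.0658, abs=1e-12)
        assert mp2 == pytest.approx(0.0536, abs=1e-12)

    def test_at_origin_equal_linear_terms(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        assert marginal_products(q, 0.0, 0.0) == (q.a1, q.a2)

    def test_first_order_condition_at_optimum(self, scenarios, coeffs):
        for name, cfg in scenarios.items():
            q = reduce_to_quadratic(coeffs, cfg.state)
            plan = optimal_inputs(q, cfg.prices)
            mp1, mp2 = marginal_products(q, plan.conc_dmi, plan.pf_dmi)
            assert mp1 == pytest.approx(cfg.prices.p1 / cfg.prices.py, abs=1e-9)
            assert mp2 == pytest.approx(cfg.prices.p2 / cfg.prices.py, abs=1e-9)


class TestIsoquant:
    def test_round_trip(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        target = float(q(3.0, 14.0))
        assert isoquant_x2(q, 3.0, target) == pytest.approx(14.0, abs=1e-9)
        assert isoquant_x1(q, 14.0, target) == pytest.approx(3.0, abs=1e-9)

    def test_sweep_reproduces_target(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        target = optimal_inputs(q, scenarios["spring"].prices).yield_kg
        for c in np.arange(0.0, 8.0, 0.25):
            p = isoquant_x2(q, float(c), target)
            assert float(q(c, p)) == pytest.approx(target, abs=1e-9)
            # rising branch: marginal product of the solved input >= 0
            assert marginal_products(q, float(c), p)[1] >= -1e-12

    def test_origin_level_returns_zero(self, scenarios, coeffs):
        q0 = spring_q(scenarios, coeffs)
        assert isoquant_x2(q0, 0.0, float(q0(0.0, 0.0))) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_unattainable_yield_raises(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        with pytest.raises(ValueError, match="unattainable"):
            isoquant_x2(q, 2.0, 10.0)


class TestRts:
    def test_matches_marginal_product_ratio(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        rng = np.random.default_rng(2)
        for c, p in rng.uniform([0, 0], [10, 20], size=(50, 2)):
            mp1, mp2 = marginal_products(q, c, p)
            assert rts(q, c, p) == pytest.approx(-mp2 / mp1, rel=1e-12)
            assert rts(q, c, p, "x2_for_x1") == pytest.approx(
                -mp1 / mp2, rel=1e-12
            )

    def test_isocline_tangency(self, scenarios, coeffs):
        """Along the least-cost isocline, -RTS equals the input price
        ratio p2/p1."""
        cfg = scenarios["spring"]
        q = spring_q(scenarios, coeffs)
        for c in np.arange(0.5, 8.0, 0.5):
            p = least_cost_isocline_x2(q, cfg.prices, float(c))
            assert -rts(q, float(c), p) == pytest.approx(
                cfg.prices.p2 / cfg.prices.p1, abs=1e-9
            )

    def test_finite_difference_along_isoquant(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        c0, p0 = 3.0, 14.0
        target = float(q(c0, p0))
        h = 1e-4
        c1 = isoquant_x1(q, p0 - h, target)
        assert (c1 - c0) / (-h) == pytest.approx(rts(q, c0, p0), abs=1e-3)

    def test_ridge_line_error(self):
        q = ReducedQuadratic(a0=1, a1=0.1, a2=0.1, a11=-0.005,
                             a22=-0.005, a12=-0.001)
        # MP1 = 0 at X1 = a1 / (2*0.005) with X2 = 0
        with pytest.raises(ZeroDivisionError, match="ridge"):
            rts(q, 10.0, 0.0)


class TestIsocline:
    def test_spring_line(self, scenarios, coeffs):
        """Algebraic solve of the tangency condition for the spring prices
        gives intercept ~5.184, slope ~2.629."""
        cfg = scenarios["spring"]
        q = spring_q(scenarios, coeffs)
        i0 = least_cost_isocline_x2(q, cfg.prices, 0.0)
        i1 = least_cost_isocline_x2(q, cfg.prices, 1.0)
        assert i0 == pytest.approx(5.184, abs=1e-3)
        assert i1 - i0 == pytest.approx(2.629, abs=1e-3)

    def test_passes_through_unconstrained_optimum(self, scenarios, coeffs):
        for name, cfg in scenarios.items():
            q = reduce_to_quadratic(coeffs, cfg.state)
            plan = optimal_inputs(q, cfg.prices)
            on_line = least_cost_isocline_x2(q, cfg.prices, plan.conc_dmi)
            assert on_line == pytest.approx(plan.pf_dmi, abs=1e-9)

    def test_symmetry_with_equal_prices(self):
        q = ReducedQuadratic(a0=1, a1=0.1, a2=0.1, a11=-0.004,
                             a22=-0.004, a12=-0.002)
        prices = PriceSet(
            conc_price_ton=270, forage_price_ton=270,
            conc_dm_frac=0.9, forage_dm_frac=0.9,
            protein_price=8, fat_price=5,
        )
        for c in (0.0, 2.0, 7.0):
            assert least_cost_isocline_x2(q, prices, c) == pytest.approx(
                c, abs=1e-12
            )


class TestOptimalInputs:
    def test_autumn_concentrate(self, scenarios, coeffs):
        cfg = scenarios["autumn"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = optimal_inputs(q, cfg.prices)
        assert plan.conc_dmi == pytest.approx(6.2, rel=0.02)

    def test_spring_profit(self, scenarios, coeffs):
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = optimal_inputs(q, cfg.prices)
        assert plan.profit == pytest.approx(8.93, rel=0.005)

    def test_beats_grid_search(self, scenarios, coeffs):
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = optimal_inputs(q, cfg.prices)
        c = np.arange(0, 12.001, 0.01)
        p = np.arange(0, 25.001, 0.01)
        cc, pp = np.meshgrid(c, p, indexing="ij")
        pr = q(cc, pp) * cfg.prices.py - cfg.prices.p1 * cc - cfg.prices.p2 * pp
        assert plan.profit >= pr.max() - 1e-12

    def test_currency_conservation(self, scenarios, coeffs):
        for name, cfg in scenarios.items():
            q = reduce_to_quadratic(coeffs, cfg.state)
            plan = optimal_inputs(q, cfg.prices)
            assert plan.milk_income - plan.feed_cost - plan.profit == 0.0
            assert plan.feed_cost == pytest.approx(
                cfg.prices.p1 * plan.conc_dmi + cfg.prices.p2 * plan.pf_dmi,
                abs=1e-12,
            )

    def test_boundary_clamp_expensive_concentrate(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        prices = PriceSet(
            conc_price_ton=5000, forage_price_ton=251,
            protein_price=7.99, fat_price=4.65,
        )
        plan = optimal_inputs(q, prices)
        assert plan.conc_dmi == 0.0
        assert plan.pf_dmi > 0.0
        # re-optimised on the boundary: FOC in the remaining input
        _, mp2 = marginal_products(q, 0.0, plan.pf_dmi)
        assert mp2 == pytest.approx(prices.p2 / prices.py, abs=1e-9)

    def test_monotonic_in_prices(self, scenarios, coeffs):
        """Raising the output price weakly raises both intakes; raising
        the concentrate price weakly lowers concentrate intake."""
        q = spring_q(scenarios, coeffs)
        base = dict(forage_price_ton=251, protein_price=7.99, fat_price=4.65)
        conc_prev, pf_prev = -1.0, -1.0
        for fat in (3.0, 4.0, 5.0, 6.0):
            plan = optimal_inputs(
                q, PriceSet(conc_price_ton=324, forage_price_ton=251,
                            protein_price=7.99, fat_price=fat)
            )
            assert plan.conc_dmi >= conc_prev and plan.pf_dmi >= pf_prev
            conc_prev, pf_prev = plan.conc_dmi, plan.pf_dmi
        conc_prev = np.inf
        for ct in (250, 324, 420, 600):
            plan = optimal_inputs(q, PriceSet(conc_price_ton=ct, **base))
            assert plan.conc_dmi <= conc_prev
            conc_prev = plan.conc_dmi

    def test_random_problems_satisfy_foc_and_dominate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q, prices = random_problem(rng)
            plan = optimal_inputs(q, prices)
            mp1, mp2 = marginal_products(q, plan.conc_dmi, plan.pf_dmi)
            assert prices.py * mp1 - prices.p1 == pytest.approx(0, abs=1e-9)
            assert prices.py * mp2 - prices.p2 == pytest.approx(0, abs=1e-9)
            pts = rng.uniform([0, 0], [12, 25], size=(1000, 2))
            profits = [profit(q, prices, c, p) for c, p in pts]
            assert plan.profit >= max(profits)


class TestConstrainedOptimum:
    def test_spring_three_dollar_budget(self, scenarios, coeffs):
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = constrained_optimum(q, cfg.prices, 3.0)
        assert plan.constrained
        assert plan.conc_dmi == pytest.approx(1.3, abs=0.1)
        assert plan.pf_dmi == pytest.approx(8.6, abs=0.1)
        assert plan.feed_cost == pytest.approx(3.0, abs=1e-9)

    def test_slack_budget_returns_unconstrained(self, scenarios, coeffs):
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        unc = optimal_inputs(q, cfg.prices)
        plan = constrained_optimum(q, cfg.prices, unc.feed_cost)
        assert plan.conc_dmi == pytest.approx(unc.conc_dmi, abs=1e-12)
        assert not plan.constrained

    def test_budget_point_beats_grid(self, scenarios, coeffs):
        """No grid point satisfying the budget out-produces the returned
        point (one grid step of slack)."""
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = constrained_optimum(q, cfg.prices, 3.0)
        step = 0.01
        c = np.arange(0, 12.001, step)
        p = np.arange(0, 25.001, step)
        cc, pp = np.meshgrid(c, p, indexing="ij")
        cost = cfg.prices.p1 * cc + cfg.prices.p2 * pp
        y = np.where(cost <= 3.0, q(cc, pp), -np.inf)
        i, j = np.unravel_index(np.argmax(y), y.shape)
        best = y[i, j]
        # slack: the continuous point can beat the grid by at most the
        # yield change over one grid step
        assert plan.yield_kg >= best - 0.2 * step

    def test_infeasible_budget(self, scenarios, coeffs):
        q = spring_q(scenarios, coeffs)
        with pytest.raises(ValueError, match="budget"):
            constrained_optimum(q, scenarios["spring"].prices, -1.0)


class TestProfit:
    def test_spring_optimum_value(self, scenarios, coeffs):
        cfg = scenarios["spring"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = optimal_inputs(q, cfg.prices)
        assert profit(q, cfg.prices, plan.conc_dmi, plan.pf_dmi) == \
            pytest.approx(8.93, rel=0.005)

    def test_autumn_optimum_value(self, scenarios, coeffs):
        cfg = scenarios["autumn"]
        q = reduce_to_quadratic(coeffs, cfg.state)
        plan = optimal_inputs(q, cfg.prices)
        assert plan.profit == pytest.approx(7.37, rel=0.01)

    def test_zero_intakes_zero_anchor(self, scenarios):
        q = ReducedQuadratic(a0=0.0, a1=0.1, a2=0.1, a11=-0.005,
                             a22=-0.002, a12=-0.002)
        assert profit(q, scenarios["spring"].prices, 0.0, 0.0) == 0.0


class TestPriceSet:
    def test_derived_unit_prices(self, scenarios):
        prices = scenarios["spring"].prices
        assert prices.p1 == pytest.approx(0.36, abs=1e-12)
        assert prices.p2 == pytest.approx(251 / 850, abs=1e-12)
        assert prices.py == pytest.approx(
            (3.3 * 7.99 + 4.0 * 4.65) / 7.3, abs=1e-12
        )

    @pytest.mark.parametrize(
        "kw",
        [
            dict(conc_price_ton=-10),
            dict(conc_dm_frac=0.0),
            dict(forage_dm_frac=1.5),
            dict(protein_price=-1),
        ],
    )
    def test_validation(self, kw):
        base = dict(conc_price_ton=324, forage_price_ton=251,
                    protein_price=7.99, fat_price=4.65)
        base.update(kw)
        with pytest.raises(ValueError):
            PriceSet(**base)
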