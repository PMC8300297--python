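"""Production-economics calculus on the two-input quadratic.

Given the reduced quadratic  Y = a0 + a1·X1 + a2·X2 + a11·X1² + a22·X2² +
a12·X1·X2  (X1 concentrate DMI, X2 pasture + forage DMI, kg DM/cow·day),
and per-kg-DM input prices p1, p2 with an output price py per kg milk
protein plus fat, this module provides the classical closed forms:

* marginal products            MP1 = a1 + 2a11·X1 + a12·X2 (and MP2)
* isoquants                    input combinations with equal output
* rate of technical substitution (RTS), the isoquant slope
* least-cost isocline          the expansion path where −RTS = price ratio
* unconstrained optimum        py·MP_i = p_i for both inputs
* budget-constrained optimum   isocline ∩ isocost line

Pasture and forage are pooled into one input priced at the forage price
per kg DM — they are treated as substitutes following a common response
trajectory.  Grazed pasture on a real farm is usually cheaper than
conserved forage, so a farm that grows most of its own pasture should read
the pooled input price as the *marginal* cost of extra pasture + forage,
which these scenarios take to be purchased forage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .model import ReducedQuadratic

__all__ = [
    "PriceSet",
    "OptimalPlan",
    "marginal_products",
    "isoquant_x1",
    "isoquant_x2",
    "rts",
    "least_cost_isocline_x2",
    "optimal_inputs",
    "constrained_optimum",
    "profit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriceSet:
    """Feed and milk-component prices for one scenario.

    Feed prices are quoted as delivered ($/tonne fresh weight) with a dry
    matter fraction; per-kg-DM prices are derived.  The output price per kg
    of milk protein plus fat is the component-price average weighted by an
    assumed energy-corrected milk composition (default 3.3% protein,
    4.0% fat), the fixed ratio in which predicted solids are split.
    """

    conc_price_ton: float
    forage_price_ton: float
    conc_dm_frac: float = 0.90
    forage_dm_frac: float = 0.85
    protein_price: float = 0.0
    fat_price: float = 0.0
    assumed_protein_pct: float = 3.3
    assumed_fat_pct: float = 4.0

    def __post_init__(self) -> None:
        if self.conc_price_ton <= 0 or self.forage_price_ton <= 0:
            raise ValueError("feed prices must be positive")
        for name in ("conc_dm_frac", "forage_dm_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.protein_price < 0 or self.fat_price < 0:
            raise ValueError("milk component prices must be non-negative")

    @property
    def p1(self) -> float:
        """Concentrate price, $/kg DM."""
        return self.conc_price_ton / 1000.0 / self.conc_dm_frac

    @property
    def p2(self) -> float:
        """Pooled pasture + forage price, $/kg DM (forage price basis)."""
        return self.forage_price_ton / 1000.0 / self.forage_dm_frac

    @property
    def py(self) -> float:
        """Output price, $/kg milk protein plus fat."""
        w_p, w_f = self.assumed_protein_pct, self.assumed_fat_pct
        return (w_p * self.protein_price + w_f * self.fat_price) / (w_p + w_f)


@dataclass(frozen=True)
class OptimalPlan:
    """A solved feeding plan: intakes, yield and the money columns."""

    conc_dmi: float
    pf_dmi: float
    yield_kg: float
    feed_cost: float
    milk_income: float
    profit: float
    constrained: bool = False
    budget: float | None = None


def _plan(
    q: ReducedQuadratic,
    prices: PriceSet,
    x1: float,
    x2: float,
    constrained: bool = False,
    budget: float | None = None,
) -> OptimalPlan:
    y = float(q(x1, x2))
    cost = prices.p1 * x1 + prices.p2 * x2
    income = y * prices.py
    return OptimalPlan(
        conc_dmi=x1,
        pf_dmi=x2,
        yield_kg=y,
        feed_cost=cost,
        milk_income=income,
        profit=income - cost,
        constrained=constrained,
        budget=budget,
    )


def marginal_products(
    q: ReducedQuadratic, conc: float, pf: float
) -> tuple[float, float]:
    """Marginal products (kg output per kg DM) of each input.

    MP1 = ∂Y/∂X1 = a1 + 2a11·X1 + a12·X2; MP2 symmetric.
    """
    mp1 = q.a1 + 2.0 * q.a11 * conc + q.a12 * pf
    mp2 = q.a2 + 2.0 * q.a22 * pf + q.a12 * conc
    return mp1, mp2


def _isoquant_root(a_lin, a_quad, a_cross, other_lin, other_quad,
                   other_value, a0, target):
    # Solve a_quad·x² + (a_lin + a_cross·other)·x + (rest − target) = 0 for
    # the rising-branch root (the one with non-negative marginal product).
    b = a_lin + a_cross * other_value
    const = (
        other_lin * other_value + other_quad * other_value**2 + a0 - target
    )
    disc = b * b - 4.0 * a_quad * const
    if disc < 0:
        raise ValueError(
            f"target yield {target} unattainable at the given input level "
            f"{other_value} (negative discriminant)"
        )
    # a_quad < 0: the '+' root is the smaller one, on the rising branch.
    x = (-b + math.sqrt(disc)) / (2.0 * a_quad)
    if x < 0:
        logger.warning(
            "isoquant root %.4f is negative: target infeasible with "
            "non-negative intakes at this input level", x,
        )
    return x


def isoquant_x2(q: ReducedQuadratic, conc: float, target_yield: float) -> float:
    """Pasture + forage intake producing ``target_yield`` at the given conc.

    Returns the rising-branch root (marginal product of X2 ≥ 0) of the
    quadratic in X2.  Raises if the target is unattainable at this
    concentrate level; a negative root is returned but logged as
    infeasible.
    """
    return _isoquant_root(
        q.a2, q.a22, q.a12, q.a1, q.a11, conc, q.a0, target_yield
    )


def isoquant_x1(q: ReducedQuadratic, pf: float, target_yield: float) -> float:
    """Concentrate intake producing ``target_yield`` at the given pasture
    + forage level (rising-branch root)."""
    return _isoquant_root(
        q.a1, q.a11, q.a12, q.a2, q.a22, pf, q.a0, target_yield
    )


def rts(
    q: ReducedQuadratic,
    conc: float,
    pf: float,
    substituting: str = "x1_for_x2",
) -> float:
    """Rate of technical substitution at an input point.

    ``x1_for_x2``: extra concentrate needed per unit of pasture + forage
    given up at constant output, −MP2/MP1.  ``x2_for_x1`` is the
    reciprocal direction, −MP1/MP2.
    """
    mp1, mp2 = marginal_products(q, conc, pf)
    if substituting == "x1_for_x2":
        num, den = mp2, mp1
    elif substituting == "x2_for_x1":
        num, den = mp1, mp2
    else:
        raise ValueError("substituting must be 'x1_for_x2' or 'x2_for_x1'")
    if den == 0:
        raise ZeroDivisionError(
            "marginal product of the substituting input is zero: the point "
            "is on the ridge line"
        )
    return -num / den


def least_cost_isocline_x2(
    q: ReducedQuadratic, prices: PriceSet, conc: float
) -> float:
    """Pasture + forage intake on the least-cost isocline at a given conc.

    The isocline is the locus where −RTS equals the input price ratio
    k = p1/p2 — the expansion path of cost-minimising input mixes:

        X2 = [k·a2 − a1 + (k·a12 − 2a11)·X1] / (a12 − 2k·a22)

    It passes through the unconstrained profit-maximising point.
    """
    k = prices.p1 / prices.p2
    den = q.a12 - 2.0 * k * q.a22
    if abs(den) < 1e-15:
        raise ValueError(
            "degenerate isocline: a12 - 2*k*a22 is zero at this price ratio"
        )
    return (k * q.a2 - q.a1 + (k * q.a12 - 2.0 * q.a11) * conc) / den


def optimal_inputs(q: ReducedQuadratic, prices: PriceSet) -> OptimalPlan:
    """Unconstrained profit-maximising input combination.

    Solves the first-order conditions py·MP_i = p_i as the linear system

        2a11·X1 + a12·X2 = p1/py − a1
        a12·X1 + 2a22·X2 = p2/py − a2

    Requires a negative-definite Hessian (interior maximum).  A negative
    solution component is clamped to zero and the remaining input
    re-optimised on that boundary.
    """
    if not q.is_concave():
        raise ValueError("Hessian not negative definite: no interior maximum")
    if prices.py <= 0:
        logger.info("non-positive output price: optimal plan is zero feeding")
        return _plan(q, prices, 0.0, 0.0)
    r1 = prices.p1 / prices.py - q.a1
    r2 = prices.p2 / prices.py - q.a2
    det = 4.0 * q.a11 * q.a22 - q.a12 * q.a12
    x1 = (2.0 * q.a22 * r1 - q.a12 * r2) / det
    x2 = (2.0 * q.a11 * r2 - q.a12 * r1) / det
    if x1 < 0 or x2 < 0:
        # Boundary: drop the negative input, re-optimise the other alone.
        cand = []
        x2_only = (prices.p2 / prices.py - q.a2) / (2.0 * q.a22)
        cand.append((0.0, max(x2_only, 0.0)))
        x1_only = (prices.p1 / prices.py - q.a1) / (2.0 * q.a11)
        cand.append((max(x1_only, 0.0), 0.0))
        plans = [_plan(q, prices, c, p) for c, p in cand]
        best = max(plans, key=lambda pl: pl.profit)
        logger.info(
            "interior optimum (%.3f, %.3f) infeasible; clamped to boundary "
            "(%.3f, %.3f)", x1, x2, best.conc_dmi, best.pf_dmi,
        )
        return best
    return _plan(q, prices, x1, x2)


def constrained_optimum(
    q: ReducedQuadratic, prices: PriceSet, budget: float
) -> OptimalPlan:
    """Best feeding plan under a daily feed-spend ceiling.

    When the unconstrained optimum already costs no more than the budget
    the constraint is slack and that optimum is returned.  Otherwise the
    plan is the intersection of the isocost line p1·X1 + p2·X2 = budget
    with the least-cost isocline — the output-maximising (hence
    profit-maximising) point on the budget line.  If the intersection
    leaves an input negative, the whole budget is spent on the other
    input.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    unconstrained = optimal_inputs(q, prices)
    if unconstrained.feed_cost <= budget + 1e-12:
        return unconstrained
    k = prices.p1 / prices.p2
    den = q.a12 - 2.0 * k * q.a22
    if abs(den) < 1e-15:
        raise ValueError("degenerate isocline at this price ratio")
    # X2 = alpha + beta * X1 on the isocline; substitute into the isocost.
    alpha = (k * q.a2 - q.a1) / den
    beta = (k * q.a12 - 2.0 * q.a11) / den
    denom = prices.p1 + prices.p2 * beta
    if abs(denom) < 1e-15:
        raise ValueError("isocline parallel to the isocost line")
    x1 = (budget - prices.p2 * alpha) / denom
    x2 = alpha + beta * x1
    if x1 < 0 or x2 < 0:
        cand = [
            (0.0, budget / prices.p2),
            (budget / prices.p1, 0.0),
        ]
        plans = [
            _plan(q, prices, c, p, constrained=True, budget=budget)
            for c, p in cand
        ]
        best = max(plans, key=lambda pl: pl.yield_kg)
        logger.info(
            "isocline/isocost intersection (%.3f, %.3f) infeasible; "
            "spending the budget on one input (%.3f, %.3f)",
            x1, x2, best.conc_dmi, best.pf_dmi,
        )
        return best
    return _plan(q, prices, x1, x2, constrained=True, budget=budget)


def profit(
    q: ReducedQuadratic, prices: PriceSet, conc: float, pf: float
) -> float:
    """Daily profit at given intakes: milk income minus feed cost.

    profit = Y(conc, pf)·py − p1·conc − p2·pf, $/cow·day.
    """
    if conc < 0 or pf < 0:
        raise ValueError("intakes must be non-negative")
    return (
        float(q(conc, pf)) * prices.py
        - prices.p1 * conc
        - prices.p2 * pf
    )
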