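"""Seasonal scenario engine: end-to-end runs, surfaces and curve sets.

A scenario couples one herd state with one set of feed and milk prices,
optionally a daily feed budget, and a grid over the two intake axes.
``run_scenario`` produces the season's profit-maximising plan (and the
budget-constrained plan when a budget is given); ``surfaces`` evaluates
the yield or profit surface over the grid; ``curves`` samples the
isoquant / isocline / isocost polylines that picture the optimisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import economics
from .model import CowState, ModelCoefficients, reduce_to_quadratic

__all__ = [
    "GridSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "SurfaceGrid",
    "CurveSet",
    "run_scenario",
    "surfaces",
    "curves",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid over the intake plane (kg DM/cow·day).

    Defaults cover concentrate 0-12 and pasture + forage 0-25 at a 0.1-kg
    step — the envelope of the underlying experimental intakes and of the
    published surface plots.
    """

    conc_min: float = 0.0
    conc_max: float = 12.0
    pf_min: float = 0.0
    pf_max: float = 25.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.conc_max <= self.conc_min or self.pf_max <= self.pf_min:
            raise ValueError("grid ranges must be non-empty")

    def conc_axis(self) -> np.ndarray:
        n = int(round((self.conc_max - self.conc_min) / self.step)) + 1
        return self.conc_min + self.step * np.arange(n)

    def pf_axis(self) -> np.ndarray:
        n = int(round((self.pf_max - self.pf_min) / self.step)) + 1
        return self.pf_min + self.step * np.arange(n)


@dataclass(frozen=True)
class ScenarioConfig:
    """One herd state + one price set (+ optional budget and grid)."""

    state: CowState
    prices: economics.PriceSet
    budget: float | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    coefficients: ModelCoefficients | None = None

    def resolve_coefficients(self) -> ModelCoefficients:
        return (
            self.coefficients
            if self.coefficients is not None
            else ModelCoefficients.default()
        )


@dataclass(frozen=True)
class ScenarioResult:
    """A season's answer: current position, optimal and constrained plans."""

    season: str
    current: economics.OptimalPlan
    optimal: economics.OptimalPlan
    constrained: economics.OptimalPlan | None = None


@dataclass(frozen=True)
class SurfaceGrid:
    """Yield or profit evaluated over the intake grid.

    ``values[i, j]`` corresponds to ``conc_axis[i]``, ``pf_axis[j]``.
    """

    conc_axis: np.ndarray
    pf_axis: np.ndarray
    values: np.ndarray
    season: str
    mode: str  # "yield" | "profit"

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.conc_axis[i]), float(self.pf_axis[j])


@dataclass(frozen=True)
class CurveSet:
    """Sampled polylines: isoquants, least-cost isocline, isocost line.

    Each polyline is an (n, 2) array of (conc, pasture+forage) points.
    """

    isoquant_current: np.ndarray
    isoquant_optimal: np.ndarray
    isocline: np.ndarray
    isocost: np.ndarray | None
    season: str


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Solve one seasonal scenario end to end.

    Reduces the fitted model to the season's quadratic (anchored at the
    current yield), solves the unconstrained optimum, and — when a budget
    is configured — the budget-constrained optimum.  Runs are pure:
    identical configs give identical results.
    """
    coeffs = cfg.resolve_coefficients()
    if cfg.state.season == "Winter":
        logger.info(
            "winter scenario uses the pooled winter/spring season effect "
            "and the defaulted winter x concentrate interaction %.3f",
            coeffs.season_conc_interaction["Winter"],
        )
    q = reduce_to_quadratic(coeffs, cfg.state)
    current = economics._plan(
        q, cfg.prices, cfg.state.current_conc_dmi, cfg.state.current_pf_dmi
    )
    optimal = economics.optimal_inputs(q, cfg.prices)
    constrained = None
    if cfg.budget is not None:
        constrained = economics.constrained_optimum(q, cfg.prices, cfg.budget)
    return ScenarioResult(
        season=cfg.state.season,
        current=current,
        optimal=optimal,
        constrained=constrained,
    )


def surfaces(cfg: ScenarioConfig, mode: str = "yield") -> SurfaceGrid:
    """Evaluate the yield or profit surface over the configured grid.

    Yield is the baseline-anchored prediction (the reduced quadratic), so
    the surface passes through the current yield at the current intakes;
    profit is income minus feed cost at every node.
    """
    if mode not in ("yield", "profit"):
        raise ValueError("mode must be 'yield' or 'profit'")
    coeffs = cfg.resolve_coefficients()
    q = reduce_to_quadratic(coeffs, cfg.state)
    conc = cfg.grid.conc_axis()
    pf = cfg.grid.pf_axis()
    c_grid, p_grid = np.meshgrid(conc, pf, indexing="ij")
    y = q(c_grid, p_grid)
    if mode == "profit":
        values = y * cfg.prices.py - cfg.prices.p1 * c_grid - cfg.prices.p2 * p_grid
    else:
        values = y
    return SurfaceGrid(
        conc_axis=conc, pf_axis=pf, values=values,
        season=cfg.state.season, mode=mode,
    )


def curves(cfg: ScenarioConfig) -> CurveSet:
    """Sample the isoquant / isocline / isocost picture for a scenario.

    Isoquants are sampled at the current-yield and optimal-yield levels
    over the concentrate axis; infeasible samples (unattainable target or
    negative intake) are omitted with a log notice.  The isocost line is
    included when the config carries a budget.
    """
    coeffs = cfg.resolve_coefficients()
    q = reduce_to_quadratic(coeffs, cfg.state)
    optimal = economics.optimal_inputs(q, cfg.prices)
    conc = cfg.grid.conc_axis()

    def _isoquant(level: float) -> np.ndarray:
        pts = []
        dropped = 0
        for c in conc:
            try:
                p = economics.isoquant_x2(q, float(c), level)
            except ValueError:
                dropped += 1
                continue
            if p < 0:
                dropped += 1
                continue
            pts.append((float(c), p))
        if dropped:
            logger.info(
                "isoquant at level %.3f: %d infeasible samples omitted",
                level, dropped,
            )
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    iso_cur = _isoquant(float(q(cfg.state.current_conc_dmi,
                                cfg.state.current_pf_dmi)))
    iso_opt = _isoquant(optimal.yield_kg)

    cline = []
    for c in conc:
        p = economics.least_cost_isocline_x2(q, cfg.prices, float(c))
        if p >= 0:
            cline.append((float(c), p))
    isocline = np.asarray(cline, dtype=float).reshape(-1, 2)

    isocost = None
    if cfg.budget is not None:
        pts = []
        for c in conc:
            p = (cfg.budget - cfg.prices.p1 * c) / cfg.prices.p2
            if p >= 0:
                pts.append((float(c), p))
        isocost = np.asarray(pts, dtype=float).reshape(-1, 2)

    return CurveSet(
        isoquant_current=iso_cur,
        isoquant_optimal=iso_opt,
        isocline=isocline,
        isocost=isocost,
        season=cfg.state.season,
    )
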