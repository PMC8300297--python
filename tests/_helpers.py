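"""Shared test utilities."""

import numpy as np

from feedopt import PriceSet, ReducedQuadratic, optimal_inputs


def random_problem(rng):
    """A random concave quadratic + positive prices with an interior
    optimum inside the default evaluation grid; redraws until feasible."""
    while True:
        a11 = rng.uniform(-0.012, -0.003)
        a22 = rng.uniform(-0.006, -0.0015)
        lim = np.sqrt(4 * a11 * a22)
        a12 = rng.uniform(-0.9 * lim, 0.3 * lim)
        q = ReducedQuadratic(
            a0=rng.uniform(0.5, 1.5),
            a1=rng.uniform(0.06, 0.18),
            a2=rng.uniform(0.05, 0.13),
            a11=a11, a22=a22, a12=a12,
        )
        prices = PriceSet(
            conc_price_ton=rng.uniform(200, 450),
            forage_price_ton=rng.uniform(150, 300),
            protein_price=rng.uniform(6, 11),
            fat_price=rng.uniform(3.5, 6),
        )
        plan = optimal_inputs(q, prices)
        if 0.5 < plan.conc_dmi < 11.5 and 0.5 < plan.pf_dmi < 24.5:
            return q, prices
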