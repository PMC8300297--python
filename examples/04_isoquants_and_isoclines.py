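"""Isoquants, the least-cost isocline and marginal products.

Shows the production-economics calculus directly on the reduced
quadratic for the autumn scenario.
"""

from feedopt import (
    ModelCoefficients,
    isoquant_x2,
    least_cost_isocline_x2,
    marginal_products,
    reduce_to_quadratic,
    rts,
)
from feedopt.io import load_packaged_scenario

cfg = load_packaged_scenario("autumn")
coeffs = ModelCoefficients.default()
q = reduce_to_quadratic(coeffs, cfg.state)

mp1, mp2 = marginal_products(q, 2.0, 11.6)
print(f"marginal products at current intakes: "
      f"conc {mp1:.4f}, p+f {mp2:.4f} kg solids per kg DM")

level = float(q(2.0, 11.6))
print(f"\nisoquant at the current yield ({level:.2f} kg/cow/day):")
for conc in (1.0, 2.0, 4.0, 6.0):
    pf = isoquant_x2(q, conc, level)
    print(f"  conc {conc:.1f} -> p+f {pf:5.2f} kg DM "
          f"(RTS {rts(q, conc, pf):+.3f})")

print("\nleast-cost isocline (expansion path) for autumn prices:")
for conc in (2.0, 4.0, 6.0):
    pf = least_cost_isocline_x2(q, cfg.prices, conc)
    print(f"  conc {conc:.1f} -> p+f {pf:5.2f} kg DM")
# Along the isocline -RTS equals the input price ratio p2/p1: swapping
# feeds at those mixes leaves both output and cost unchanged.
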