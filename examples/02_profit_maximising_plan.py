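"""Find the profit-maximising feed allocation for each season.

Runs the four packaged seasonal scenarios (demonstration-farm inputs and
prices) and prints the optimal concentrate / pasture + forage intakes with
the resulting yield, cost, income and profit per cow and day.
"""

from feedopt import run_scenario
from feedopt.io import load_packaged_scenario, packaged_scenario_names

print(f"{'season':8s} {'conc':>5s} {'p+f':>5s} {'yield':>6s} "
      f"{'cost':>6s} {'income':>7s} {'profit':>7s}")
for name in packaged_scenario_names():
    plan = run_scenario(load_packaged_scenario(name)).optimal
    print(
        f"{name:8s} {plan.conc_dmi:5.1f} {plan.pf_dmi:5.1f} "
        f"{plan.yield_kg:6.2f} {plan.feed_cost:6.2f} "
        f"{plan.milk_income:7.2f} {plan.profit:7.2f}"
    )
# Intakes are kg DM/cow/day, yield kg milk protein+fat/cow/day, money
# $/cow/day.  At each optimum the value of the marginal kilogram of each
# feed exactly equals its price (py*MP_i = p_i).
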