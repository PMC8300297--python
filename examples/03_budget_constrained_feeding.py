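"""Feed allocation under a daily feed-spend ceiling.

With a $3/cow·day budget the spring optimum moves down the least-cost
isocline to the point where it crosses the isocost line.
"""

from feedopt import run_scenario
from feedopt.io import load_packaged_scenario

result = run_scenario(load_packaged_scenario("spring", budget=3.0))
unc, con = result.optimal, result.constrained

print("spring, unconstrained:")
print(f"  conc {unc.conc_dmi:.1f} kg, p+f {unc.pf_dmi:.1f} kg DM, "
      f"cost ${unc.feed_cost:.2f}, profit ${unc.profit:.2f}/cow/day")
print("spring, $3/cow/day budget:")
print(f"  conc {con.conc_dmi:.1f} kg, p+f {con.pf_dmi:.1f} kg DM, "
      f"cost ${con.feed_cost:.2f}, profit ${con.profit:.2f}/cow/day")
# The constrained plan keeps the least-cost input *ratio* (the isocline
# condition -RTS = p2/p1) while scaling total spend back to the budget.
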