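# feedopt

Tactical feed-allocation economics for grazing dairy cows.

Dairy farmers in pasture-based systems continually decide how much cereal
concentrate and how much conserved forage to feed on top of grazed
pasture, under volatile feed costs and milk prices. `feedopt` couples an
empirical milk-solids production function — fitted by mixed-model
meta-analysis to Australian grazing experiments — with classical
production-economics theory to answer, for a given herd, season and set
of prices: *what combination of concentrate and pasture + forage
maximises daily profit, with or without a feed budget?*

It is a library first (with a thin `feedopt` CLI), aimed at agricultural
economists, extension modellers and decision-support developers.

## The model

Daily milk protein plus fat yield (kg/cow·day) is a bivariate quadratic
in concentrate DMI (X₁) and pooled pasture + forage DMI (X₂), both in
kg DM/cow·day:

    Y = a₀ + a₁X₁ + a₂X₂ + a₁₁X₁² + a₂₂X₂² + a₁₂X₁X₂

with a₁₁, a₂₂ < 0 (diminishing returns). The packaged coefficients come
from the fixed effects of a random-coefficients meta-analysis across
grazing experiments; a₁ carries a season × concentrate interaction, and
the full fixed-effect equation additionally adjusts for pre-experimental
yield, weeks lactating, season, liveweight group and pasture
digestibility. Predictions for decision-making are *baseline-anchored*:
the quadratic's response is added to the herd's measured current yield,
so herd covariates cancel exactly.

On this surface the package computes marginal products
(MP₁ = a₁ + 2a₁₁X₁ + a₁₂X₂), isoquants, the rate of technical
substitution, the least-cost isocline (−RTS = p₂/p₁), the unconstrained
profit-maximising plan (p_y·MP_i = p_i) and the budget-constrained
optimum (isocline ∩ isocost line).

## Worked example

```python
from feedopt import run_scenario
from feedopt.io import load_packaged_scenario

result = run_scenario(load_packaged_scenario("spring", budget=3.0))
plan = result.optimal
print(f"conc {plan.conc_dmi:.1f} kg, p+f {plan.pf_dmi:.1f} kg DM, "
      f"profit ${plan.profit:.2f}/cow/day")
con = result.constrained
print(f"under $3/day: conc {con.conc_dmi:.1f} kg, p+f {con.pf_dmi:.1f} kg DM")
```

prints

```
conc 2.5 kg, p+f 11.8 kg DM, profit $8.93/cow/day
under $3/day: conc 1.3 kg, p+f 8.6 kg DM
```

i.e. the spring demonstration herd (2.07 kg solids/day at 2 kg
concentrate and 10.6 kg pasture DM) should lift concentrate to ~2.5 kg
and pasture + forage to ~11.8 kg DM for a profit of $8.93/cow·day; a
$3/cow·day feed budget pulls the plan down the least-cost isocline to
1.3 / 8.6 kg DM. The `examples/` directory has one short script per
capability (marginal response prediction, seasonal optimisation,
budgeted feeding, isoquant/isocline analysis, synthetic-database
parameter recovery), and the same functionality is scriptable via
`feedopt scenario|surface|curves|simulate|recover`.

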