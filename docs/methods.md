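# Methods

## Response model

The response variable is daily milk protein plus fat yield ("milk
solids", kg/cow·day). The fitted model is the fixed-effect part of a
mixed-model meta-analysis over treatment means nested within grazing
experiments: a bivariate quadratic in concentrate DMI and pooled
pasture + forage DMI, plus centred covariates —

- pre-experimental (current) milk-solids yield (slope 0.178 kg/kg),
- weeks lactating (−0.006 kg/week),
- season main effects (spring/winter 0, summer −0.174, autumn −0.312 kg),
- a season × concentrate interaction on the centred concentrate DMI
  (spring 0, summer +0.020, autumn +0.030 kg per kg DM),
- liveweight group (≤500 kg reference, >500 kg +0.116 kg),
- pasture dry matter digestibility (+0.014 kg per %).

Every covariate enters centred at its estimation-sample mean, including
the squared and cross-product intake covariates, which are centred at
*their own* means; with all covariates at their means the prediction
equals the intercept (1.465 kg/cow·day). Coefficients and means ship as
CSV tables (`src/feedopt/data/`) and can be replaced by any file with
the same schema.

Pasture and forage DMI are pooled into one input. The underlying
experiments rarely varied forage at more than two rates, so separate
pasture and forage responses are not identifiable; the pooled variable
constrains both to a common trajectory and prices them as substitutes.

### Prediction modes

*Absolute* prediction evaluates the full fixed-effect equation and
needs a pasture digestibility (or metabolisable energy, converted as
DMD% = ME/0.16 — a documented linear convention, overridable by
supplying DMD directly). *Marginal* (baseline-anchored) prediction —
the primary mode, and the one the economics uses — returns

    current_yield + Q(candidate intakes) − Q(current intakes)

where Q is the intake-dependent part of the model. All purely covariate
terms cancel exactly in the difference, which makes the mode insensitive
to the liveweight-coefficient ambiguity and the ME→DMD convention, and
anchors the economics at the herd's measured performance rather than at
the meta-analysis average. `reduce_to_quadratic` expresses this mode in
closed form by choosing a₀ so the quadratic passes through
(current intakes, current yield).

### Calibration envelope

The estimation data span roughly 400–600 kg liveweight and 18–270 days
in milk (3–39 weeks), digestibility 58.7–85.4%, concentrate 0–10.4 and
pasture/forage 0–20.9 / 0–17.7 kg DM/cow·day. States outside the
liveweight or lactation envelope trigger a `CalibrationEnvelopeWarning`
(not an error): predictions there are extrapolation.

### Deliberate gap-filling choices

- **Liveweight coefficient.** The source tables are internally
  inconsistent about the >500 kg group effect (0.116 / 0.030 / 0.01 kg
  in different places). The packaged table uses 0.116; the choice is
  configurable and *never* affects marginal predictions or any economic
  result (the term cancels).
- **Winter.** Winter shares the pooled winter/spring season main effect
  (0). No winter × concentrate interaction was published; the packaged
  default sets it to autumn's value (0.030), the only choice consistent
  with the published winter optimisation results. The substitution is
  logged at load time and recorded in every run manifest.
- **Boundary at exactly 500 kg** maps to the reference (≤500 kg) group.

## Economics

Prices: concentrate at $/tonne delivered ÷ (1000 × DM fraction) →
$/kg DM (p₁); the pooled pasture + forage input is priced at the forage
price per kg DM (p₂) — the marginal cost of extra pooled feed is taken
to be purchased forage, a deliberately conservative convention since
grazed pasture is usually cheaper. The output price p_y per kg solids is
the protein/fat component-price average weighted by an assumed
energy-corrected milk composition of 3.3% protein and 4.0% fat.

Closed forms on the reduced quadratic: marginal products; isoquants
(the rising-branch root, i.e. non-negative marginal product of the
solved input); RTS = −MP_j/MP_i; the least-cost isocline
X₂ = [k·a₂ − a₁ + (k·a₁₂ − 2a₁₁)X₁]/(a₁₂ − 2k·a₂₂) with k = p₁/p₂; the
unconstrained optimum from the linear first-order system
2a₁₁X₁ + a₁₂X₂ = p₁/p_y − a₁, a₁₂X₁ + 2a₂₂X₂ = p₂/p_y − a₂ (requires a
negative-definite Hessian, which the packaged coefficients satisfy:
4a₁₁a₂₂ − a₁₂² > 0); and the budget-constrained optimum as the
isocline ∩ isocost intersection, returned only when the constraint
binds.

The closed forms are unconstrained in sign; non-negativity handling is
added on top: a negative unconstrained solution is clamped to zero and
the remaining input re-optimised on the boundary; a negative
constrained intersection spends the whole budget on the other input.
Both clamps are logged. Income − cost − profit is exactly zero in every
plan by construction.

## Scenario engine and numerical choices

A scenario is one herd state + one price set (+ optional budget + grid).
The default grid spans concentrate 0–12 and pasture + forage
0–25 kg DM/cow·day at 0.1 kg — the envelope of the estimation data and
of the published surface plots. Yield surfaces use the baseline-anchored
mode, so the surface passes through the herd's current point. Curve
sampling omits infeasible isoquant samples (unattainable target or
negative intake) with a log notice. Scenario runs are pure functions of
their config; every run can emit a manifest recording the package
version, a coefficient checksum and all gap-filling flags in effect.

Tolerances: identity-type checks (isoquant round trips, first-order
conditions, isocline tangency) hold to 1e-9; equivalence of the two
prediction modes to 1e-12. Reproduction of the published seasonal table
is expected only within ~5%: the published coefficients are printed to
three decimals, and propagating that rounding through the optimisation
shifts optima by 1–4% (profits least, by the envelope theorem). The
packaged tables therefore reproduce published profits to <1% and intakes
to ≲4%, without any re-tuning.

## Synthetic database and parameter recovery

The original experiment-level database is not public. The generator
emulates its *structure*: experiments with a season, liveweight group,
digestibility, pre-experimental yield and stage of lactation drawn once
per experiment; treatment intakes drawn uniformly over the envelope
ranges above (pasture and forage drawn separately, pooled in the
response); responses = fixed-effect surface + bivariate-normal random
intercept/slope on total DMI per experiment + residual noise. Default
variance components (intercept sd 0.15 kg, slope sd 0.01 kg per kg DMI,
correlation 0, residual sd 0.16 kg) are package assumptions — the
originals were not published — sized so total unexplained spread matches
the reported model RMSE (~0.16 kg). Defaults: 60 experiments × 4
treatments, the estimation-scale problem size used throughout the tests.

What passing recovery tests show: that the estimation machinery
(statsmodels `MixedLM`, REML, random intercept + slope per experiment)
recovers the generating coefficients without bias at realistic noise, to
within ~2 standard errors in ≥90% of seeded replicates. What they do
*not* show: anything about real-data issues the generator omits —
unbalanced designs, correlated covariates (season vs stage of lactation
confounding), non-uniform intake distributions, measurement error in
pasture intake estimates, or model misspecification.

`recover_fixed_effects` returns a `FixedEffectEstimates` record rather
than a coefficient-set object directly: a noisy replicate can
legitimately estimate a non-negative quadratic term, which the
`ModelCoefficients` plausibility invariant (negative quadratics) would
reject; `as_model_coefficients()` performs the checked conversion when
wanted. When the data interpolate the surface exactly, recovery returns
the OLS solution directly (the mixed fit is degenerate there and GLS
coincides with OLS).

Goodness-of-fit statistics (`fit_stats`) use sample (n−1) moments:
Pearson r, Lin's concordance 2s_op/(s_o² + s_p² + (ō−p̄)²), RMSE, and
Nash–Sutcliffe efficiency 1 − Σ(o−p)²/Σ(o−ō)². The statistics of the
original 241-treatment fit cannot be replicated here (database
unavailable); the operations are verified against exact and
hand-computed cases and the inequalities Lin's ≤ |r|, NSE ≤ r².

## Known limitations

- "Milk only" basis: no body-condition, reproduction or animal-health
  value of feeding; no rumen-function limits on feed ratios; no
  multi-period or herd-level optimisation; no price risk.
- The pooled pasture + forage input cannot value pasture and forage
  separately.
- Predictions beyond the calibration envelope (notably >270 days in
  milk, as in the winter demonstration scenario) are extrapolation and
  are flagged.
- The winter × concentrate interaction and the liveweight coefficient
  magnitude are gap-filled as described above.
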