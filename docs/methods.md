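# Methods

## The model

`srbsim` simulates a closed single-region population of individual
agents, one tick per calendar year. Each agent carries an id, sex, birth
year, completed age (0–50), and — for women — son preference `sp ∈ {0,1}`,
parity `p`, living sons `so`, technology access `tech`, and an abortion
count `ab`, plus a link to the mother. Agents leave the simulation at age
50; males are tracked to 50 solely so that a son's death can feed back on
his mother's stopping behavior.

Within a tick the order of operations is fixed:

1. **Willingness update.** Every woman aged 15–49 redraws
   `sp ~ Bernoulli(sp(year))` from the logistic time trend
   `sp(t) = logit⁻¹(δ₀ + δ₁·(year − reference_year))`. The default curve
   passes exactly through survey-style anchors of 48 % in 1985 and 26 %
   in 1994 (reference year 1980).
2. **Ability update.** Ability follows the logistic diffusion
   `Ability(t) = logit⁻¹(ρ(t − ϕ))` with `t = 0` at the scenario start.
   A uniform draw below `Ability(t)` grants access; by default access is
   absorbing (once able, always able).
3. **Mortality.** Each agent dies independently with the schedule's
   `q(age, sex, year)`. A dead son decrements his mother's `so` if she is
   alive, female, and under 50 — reopening differential stopping for her
   the same year.
4. **Reproduction.** Each woman aged 15–49 conceives with the
   DSB-modified hazard: the period rate `h*(x,t)` if `sp = 0`;
   `min{1, h*(x,t)(1+γ)}` while `so < sp`; `h*(x,t)(1−α)` once
   `so ≥ sp` (for `sp ≠ 0`). Sex at conception is male with probability
   `p_male = 0.5122` (natural SRB 105). A female fetus is aborted when
   the woman is willing (`sp > so`), able (`tech`), and a uniform draw
   falls under her readiness
   `min{1, β/TFR(t−1)}` (parity 0) or `min{1, p·σ/TFR(t−1)}` (parity ≥ 1),
   where `TFR(t−1)` is the model-generated period TFR of the previous
   tick (the schedule TFR on the first tick). Male fetuses are never
   aborted; an abortion removes the conception with no retry that year.
5. **Aging.** Ages increment, newborns enter at age 0, agents reaching 50
   are removed.

Conceptions = births + abortions holds exactly by construction each
year.

**Burn-in.** Scenarios start from a stable-population pyramid (leading
eigenvector of the female Leslie matrix built from the first schedule
year, males scaled by the conception sex ratio and relative
survivorship) evolved for `burnin_years` (default 35) under plain
fertility and mortality — no DSB, no abortion — so women entering the
scenario carry realistic parity and son histories.

## Parameters

| parameter | range | default | meaning |
| --- | --- | --- | --- |
| γ | [0, 1] | 0.20 | hazard expansion while son preference unmet |
| α | [0, 1] | 0.075 | hazard reduction once preference met |
| σ | [0, 2.5] | 1.7 | fertility-squeeze scale, parity ≥ 1 |
| β | [0, 0.5] | 0.2 | fertility-squeeze scale, parity 0 |
| ρ | [0, 2] /yr | 0.5 | technology diffusion rate |
| ϕ | [0, 20] yr | 7 | diffusion inflection (years after start) |
| p_male | (0, 1) | 0.5122 | male conception probability (SRB 105) |

The defaults are the parameter combination that reproduces a South
Korea-like transition (rise in the 1980s, peak around 1990, turnaround);
the ranges are the plausibility box explored by calibration.

## Outputs and ensembles

Per year the engine records male/female births (SRB = 100·M/F, reported
missing when F = 0), realized period TFR (sum over single ages of
births-to-women-aged-x over women-aged-x), conceptions, abortions by
parity at decision time (0, 1, 2, 3+), and the proportions willing and
able among women 15–49. A scenario runs `n_replicates` independent
replicates with seeds `base_seed + r`; ensembles carry per-year means
and empirical 2.5/5/95/97.5 percentiles of SRB and TFR, and a smoothed
view applying a centered five-year moving average (shrinking at the
edges, missing values skipped) to each summary column. The default desk
scale is 20,000 agents × 20 replicates; production-scale runs are a
config choice, not a code path.

Counterfactuals: `counterfactual_tfr_gap` compares a run against its
no-abortion twin (σ = β = 0) as `TFR_without − TFR_with` per year and in
percent. `scenario_suite` adds frozen willingness (50 %, 100 %),
constant 50 % ability (redrawn each tick so the proportion able stays at
one half), and weak readiness (σ = 1, β = 0).

## Calibration and sensitivity

The fit measure is `RMSE = sqrt(Σ_t (ref(t) − sim(t))² / (end − start))`
over calendar years `start..end` inclusive. The denominator follows the
printed formula (end − start, e.g. 30 for 1980–2010) even though the sum
then has 31 terms; this off-by-one is kept deliberately for
comparability.

Calibration evaluates the simulator on a Latin hypercube over the
six-parameter box (default 224 points; 44 randomly chosen points flagged
for 5 repetitions each, i.e. 180×1 + 44×5 = 400 planned runs), ranks
points by mean fit, and fits a regression metamodel — main effects,
squares, and pairwise interactions of the design-mean-centered
parameters — for dense interpolation of the fit surface (`argmin`
extraction; default 7 grid levels per parameter) on the raw outcome
scale (log scale behind a flag). Sensitivity analysis decomposes the
metamodel's explained variance with sequential (type-I) sums of squares,
main effects entered first, then squares, then interactions, in a fixed
documented order; centering reduces the order sensitivity of the
decomposition. Shares plus the residual sum to 100 %.

## What the synthetic data emulate — and what they do not

`synthesize_schedule` builds a fertility surface from a fixed unimodal
age shape (discretized Beta(2.5, 4.5) over ages 15–49, peaking near age
25–26) scaled so the period TFR follows a piecewise log-linear path, and
mortality as a child-plus-Gompertz profile whose level declines
monotonically (halving roughly every 35 years). The bundled
`demo_schedule` runs TFR 5.0 → 2.8 (over the 35 burn-in years) → 1.2
(over the next 30), a fast fertility transition of the kind under which
SRB distortions emerged. These surfaces are smooth and noise-free: no
period shocks, no parity-specific rates, no migration, no tempo effects.
Tests passing on them show that the mechanics (hazard modification,
decision flow, accounting, calibration machinery) are correct, not that
any particular country's SRB trajectory is reproduced; matching observed
national series requires supplying WPP-derived rate tables.

## Numerical and design choices

- **Discrete-time hazards.** Period rates are used directly as per-year
  Bernoulli probabilities; the (1+γ) expansion is capped at 1. At most
  one conception per woman per year; no twins.
- **Son preference assignment.** Annual redraw is the default so the
  population proportion tracks the period trend (stated preference fell
  faster than cohort replacement allows); a cohort mode (assign once at
  entry to reproductive age) is available. This is the single most
  consequential under-determined choice in the model.
- **Technology access.** Absorbing by default — under a rising diffusion
  curve, per-tick redraw and absorbing acquisition are statistically
  close, and absorbing matches diffusion saturation. A per-tick redraw
  mode (`tech_absorbing=False`) is available; constant-ability overrides
  always redraw so the proportion able stays at the override.
- **Prevailing TFR fallback.** If a tiny population realizes a TFR below
  0.05, the next tick's readiness uses the schedule TFR instead, keeping
  the squeeze ratio well-defined.
- **Age-group graduation.** 5-year input groups expand
  constant-within-group (exactly mean-preserving); a linear graduation
  with central-difference slopes, clamped to keep rates non-negative and
  still mean-preserving, is available via `graduation="linear"`.
- **Seeds.** One base seed per scenario; replicate `r` uses
  `base_seed + r`; identical configs are bit-reproducible.
- **Metamodel scale.** Raw outcome scale by default; the paper-style
  log-scale fit is behind a flag since the appropriate scale is not
  determined by the data layout.

## Problem sizes used in the checks

The statistical end-to-end checks run at 20,000 agents: the natural-SRB
check pools births over a ten-year window across 20 replicates; the
self-calibration check generates a reference from 10 replicates at known
parameters and evaluates a 224-point hypercube (plus the truth point) at
5 replicates per point, requiring the truth to rank in the top decile.
At this scale the yearly SRB carries Monte Carlo noise of several points
(a few hundred female births per year), which is why per-point
replication matters for stable rankings.

## Known limitations

- One region, no migration, no social-network feedback on son
  preference; the turnaround toward normal SRB emerges solely from the
  declining willingness trend.
- No marriage/partnership structure; fertility is a function of age and
  the woman's own state only, with a single base schedule across
  parities.
- Mortality and fertility stop at age 50 by design; the model is a
  reproductive-behavior model, not a full population projection.
- Abortion is the only sex-selection technology modeled, and only of
  female fetuses.
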