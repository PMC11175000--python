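# Methods

This note records the statistical model behind each module, the default
parameter values, and the reasoning behind design choices that the code alone
does not explain.

## 1. Questionnaire model

A response profile holds, per respondent: weekly consumption frequencies for
39 food items (six sections: vegetables/fruits, cereals, dairy, meat/fish,
drinks, unhealthy foods), an ordered portion label (`small`, `standard`,
`large`, multipliers 0.5 / 1.0 / 1.5) for the 34 items that carry a portion
question, answers to 13 categorical behavior questions, age, and sex.
Frequencies live on a half-serving lattice (0, 0.5, 1, …) because respondents
tick frequency boxes rather than report continuous intakes.

Weekly servings for a scoring row are
`servings = Σ_items frequency × portion_multiplier`, summed over the items
mapped to that row by the aggregation map. A missing portion answer falls back
to the standard multiplier and is surfaced as a validation warning rather than
an error, since portion questions are the most frequently skipped.

Respondents are stratified at age 30: `young_adults` (≤ 30) versus
`adults_elderly` (> 30), the boundary used throughout the reliability and
validity reports.

## 2. Combined adherence score

The scoring matrix has 22 rows. Each row is one of:

- **frequency_range** — a favorable interval of weekly servings (e.g. fruit
  and vegetables ≥ 35/week, i.e. ≥ 5/day; eggs 2–4/week; fast food exactly
  0). Inside the interval the row scores +1, outside −1.
- **comparison** — fresh bread preferred: loaf servings ≤ fresh-bread
  servings scores +1, otherwise −1.
- **categorical** — scored directly from a behavior answer (e.g. regular and
  frequent olive-oil use, spices instead of salt).

Seven rows carry a behavior **modifier** worth ±0.5: the modifier answer
pushes the base point outward, so attainable row values are
{−1.5, −1, +1, +1.5}. The breakfast-pastries row additionally carries a
**gate**: a respondent who reports skipping breakfast cannot earn the
favorable branch regardless of frequency.

Enumerating every branch/modifier combination per row and summing gives exact
raw extrema of ±25.5. Because the instrument's contract is a −20…+20 scale,
raw totals are rescaled linearly, `normalized = raw × 20 / 25.5`. A linear
map was chosen over clipping or per-row reweighting because it preserves
rank order, symmetry about zero, and the interpretation of every row
contributing equally. The MD subscore is the sum of positive row points and
the WD subscore the sum of negative row points, so
`md_subscore + wd_subscore = raw_total` by construction.

## 3. Reference instruments

**MedDietScore (MDS).** Eleven components scored 0–5, maximum 55. Intakes are
converted to monthly servings (weekly × 4) and binned; pro-Mediterranean
components rise with intake, the three anti components (meat products,
poultry, full-fat dairy) use the reversed bins, potatoes peak at 3–4
servings/week, alcohol peaks below 3 glasses/day and falls to 0 above 7.
Olive-oil use is scored from the behavior answer (regular and frequent = 5,
occasional = 2) because the questionnaire records it as a habit, not a
frequency. Monthly bins were used because the component cut-offs are defined
on a monthly scale; weekly inputs are converted rather than re-deriving
weekly cut-offs, so the published bin boundaries apply verbatim.

**MEDILITE.** Nine food groups, each scored 0/1/2 from a three-level
consumption classification (two cut points per group in servings/day or
units/day). Mediterranean-typical groups score 2 at the highest level,
non-Mediterranean groups score 2 at the lowest, and alcohol scores 2 only at
the middle (moderate) level. Maximum 18.

**Concurrent validity.** The MD subscore is correlated with MDS and the
normalized total with MEDILITE (Pearson, two-sided test, Fisher-z 95% CI),
overall and within age strata. Constant score vectors raise a
`DegenerateDataError` instead of returning NaN.

## 4. Reliability statistics

- **Pearson / Spearman** with Fisher-z confidence intervals
  (`tanh(atanh r ± z_{1−α/2}/√(n−3))`); Spearman is Pearson on mid-ranks.
- **ICC(2,1)** — two-way random effects, absolute agreement, single measure,
  computed from the repeated-measures ANOVA decomposition (delegated to
  `pingouin.intraclass_corr`; a manual ANOVA oracle in the test suite checks
  the delegation). ICC(2,1) is the right form for test–retest data because
  administrations are a random sample of occasions and systematic T0→T1
  shifts should count against agreement.
- **Cohen's kappa** — simple, linear-weighted or quadratic-weighted,
  `κ = 1 − Σ w·p_obs / Σ w·p_exp` with `w = |i−j|/(k−1)` (squared for
  quadratic). Linear weights are the default for portion categories: the
  scale is ordered but there is no argument for penalizing a two-step
  disagreement four times as much as a one-step one. The confidence interval
  is a seeded nonparametric percentile bootstrap (default 2000 resamples)
  rather than the asymptotic variance, because portion categories are often
  sparse in small strata and the bootstrap degrades gracefully there.
- **Interpretation bands** — left-closed, right-open intervals with a closed
  top band. Kappa uses the Landis–Koch labels (cuts 0.4/0.6/0.8); test–retest
  correlations use an acceptability range with cuts 0.5/0.7 (below /
  acceptable / above acceptable); a general correlation scale (poor /
  moderate / substantial / optimal at 0.4/0.6/0.8) is also provided.

The test–retest report computes, per item and stratum (minimum 5 complete
pairs): T0/T1 mean and SD, Pearson r with CI, Spearman r, ICC(2,1) and the
acceptability band for frequencies; weighted kappa with bootstrap CI and the
Landis–Koch band for portions. Items that cannot be scored (constant vectors,
too few complete pairs) are reported with an `undefined` band and a warning,
never silently dropped.

## 5. Synthetic cohort generator

The generator exists to exercise the scoring and reliability pipeline, not to
model real dietary behavior. Respondents are drawn from three archetypes:

- `md` — high fruit/vegetable, legume, fish and olive-oil-habit intake,
  favorable behavior probability 0.85;
- `wd` — high processed/fast-food, sweets and soda intake, favorable
  behavior probability 0.15;
- `mixed(λ)` — linear interpolation of the pole means and probabilities
  (λ = 1 is the Mediterranean pole).

Item frequencies are negative-binomial on the half-serving lattice with
`Var = μ + d·μ²` (default dispersion d = 0.5; d = 0 collapses to a point
mass, used by deterministic tests). Ages come from a two-stratum mixture
matching the validation cohort's composition (weights 145:68; young
N(22.9, 2.3²) clipped to [18, 30], older N(56.3, 17.4²) clipped to [31, 95]),
sex is 70% female, and the default per-stratum archetype mixtures tilt the
older stratum toward the Mediterranean pole — the direction of the nutrition
transition.

**Retest model.** The second administration multiplies each frequency by an
independent mean-one lognormal factor `exp(N(−τ²/2, τ))` and re-rounds to the
lattice, switches each portion answer to an adjacent category with
probability 0.25, and flips each behavior answer with probability 0.15. For
the pre-rounding process the attenuation is exact:

```
corr(X, X·M) = 1 / sqrt(1 + v · (1 + μ²/σ²)),   v = exp(τ²) − 1,
```

implemented as `expected_retest_correlation` with the closed-form inverse
`tau_for_target_correlation`. This analytic pair is the independent oracle
for the attenuation-recovery tests. The default τ = 0.8 was calibrated so
that the bulk of item-level test–retest correlations on a default cohort fall
inside the 0.5–0.7 acceptability band (mean ≈ 0.63), i.e. the generator
mimics an instrument of realistic, not idealized, reliability.

**Scope and limits.** Frequencies are drawn independently across items given
the archetype, so within-respondent food substitution patterns, energy
constraints, seasonal effects and correlated measurement error are all out of
scope. The generator should not be used to estimate population dietary
parameters — only to produce structurally valid, reproducible inputs whose
expected statistical behavior is known.

## 6. Numerical choices

- All randomness flows through `numpy.random.Generator` seeded per call;
  identical seeds give byte-identical cohorts and bootstrap intervals.
- Matrix extrema are computed by exact per-rule enumeration, not sampling.
- Exact rational comparisons (e.g. normalized totals at the extrema) are
  asserted as equalities; everything statistical uses explicit tolerances.
- Correlations require n ≥ 4 and non-constant inputs; ICC requires n ≥ 5;
  violations raise typed errors (`DomainError`, `DegenerateDataError`)
  rather than propagating NaN.
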