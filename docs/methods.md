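# Methods

This note documents the statistical machinery in `morbmine`, the design
choices made where several defensible options existed, and what the
synthetic-data tests do and do not establish about real survey data.

## Transactions, items, and counting semantics

Each respondent-year is a transaction; the items are 20 chronic-condition
categories relevant to primary-care multimorbidity (hypertension,
hyperlipidemia, diabetes, arthritis, cardiovascular disease, heart failure,
asthma/COPD, chronic musculoskeletal disorder, thyroid disorder, stomach
problem, urinary problem, anxiety/depression, cancer, kidney disease, liver
disease, dementia, osteoporosis, stroke/TIA, epilepsy, substance use).
Conditions arrive either as per-person 0/1 flags or as 3-character ICD-10-CM
category codes mapped through an editable TSV; the shipped map is a
best-effort reconstruction of that roster from 3-digit categories and should
be replaced by a vetted site map where available. Unmapped codes are tallied,
never fatal. Condition counts refer to the 20 catalog categories only.

Support is **superset-inclusive**: a person holding {hypertension,
hyperlipidemia, diabetes} counts toward every subset of that triple, so
reported prevalences mean "at least these conditions". Condition vectors are
20-bit integers and membership is a vectorized bitwise containment test.

### Mining

Level-wise Apriori: size-(k+1) candidates join frequent size-k sets sharing a
(k−1)-prefix and are pruned by downward closure. The two-stage threshold is
applied as in the study design: the 0.20% floor on *unweighted* support
drives pruning (the "initial pass", before weights), and the ≥ 1 million
weighted-persons floor is a post-filter. Both criteria are anti-monotone, so
the staging is exactly equivalent to brute-force enumeration — a property
the test suite verifies against an exhaustive oracle on universes of up to
12 items with arbitrary thresholds. Combinations with zero observed holders
are never reported even at a zero threshold (their support is not
estimable); singleton records bypass the thresholds and are carried
separately because lift and the improvement filter need them. Ties in every
ranking break by larger weighted count, then lexicographic itemset, making
all outputs order- and label-invariant.

## Design-based estimation

Variances use Taylor linearization with the with-replacement first-stage
approximation (no finite-population correction), the standard convention for
public-use files: per-person influence values are summed to PSU totals
within strata and

Var = Σ_h n_h/(n_h−1) Σ_j (Z_hj − Z̄_h)².

A stratum with a single PSU is an error naming the stratum; an explicit
`single_psu="collapse"` option merges singleton strata instead. Intervals
are t-based on design df = #PSUs − #strata. Influences:

- proportion p̂ = Σwᵢyᵢ/Σwᵢ: zᵢ = wᵢ(yᵢ − p̂)/Σw, CI truncated to [0,1];
- domain mean (ratio estimator) R = Σwᵢdᵢvᵢ/Σwᵢdᵢ: zᵢ = wᵢdᵢ(vᵢ − R)/Σwd —
  non-members have zero influence, so subgroup point estimates equal a run
  on a physically subset file;
- log lift, log L = log p̂_X − Σ_c log p̂_c: the combination's and marginals'
  influences combine by the delta method, and the CI is exponentiated back.
  The log scale is a deliberate choice (the source analysis does not state
  its interval construction): it guarantees positive bounds and produces the
  asymmetric intervals typical of reported lifts.

Weighted quantiles use the **lower quantile without interpolation**
(smallest observed value whose cumulative weight fraction reaches q):
deterministic and invariant to rescaling all weights, at the cost of a
slightly conservative median in tiny samples. An interpolating variant is
available behind a flag. Medians/IQRs carry no CIs. Pooled multi-year files
treat (year, stratum) pairs as distinct strata and divide base weights by
the number of pooled years.

## Minimum-improvement filter and rankings

"Redundant" combinations are pruned per outcome (mean expenditure; percent
in poor health): combination X survives only if its outcome statistic
exceeds the statistic of **every** immediate sub-combination of size |X|−1
that is itself frequent (dyads compare against their single conditions) by a
relative margin τ = 0.10, with strictly positive improvement required — so
τ = 0 keeps exactly the strict improvers, and the retained set shrinks
monotonically in τ. The comparison uses point estimates only, with no
significance test on the improvement. This all-parents, relative, one-sided
reading is interpretive (the minimum-improvement literature admits absolute
and any-parent variants); it is the strictest of the common readings and is
exposed via τ. Rankings report the union of the top-k by mean cost and
top-k by poor-health share, flag membership in each, and sort by prevalence.

## Survey-weighted logistic regression

One model per combination: poor health (self-rated fair/poor) on the
exposure indicator 1{person holds all conditions of X}, a natural cubic
spline in age, race/ethnicity (5 levels, non-Hispanic white reference — the
largest group), and sex (male reference). Coefficients solve the weighted
score equation by IRLS (convergence: relative deviance change < 1e-8 within
25 iterations; separation flagged at max|β| > 15). The covariance is the
sandwich A⁻¹BA⁻¹ with A the weighted Fisher information and B the
stratified between-PSU covariance of score contributions; hence clustering
moves only the SEs, never the point estimates, and both β and SEs are
invariant to weight rescaling. The effect measure is the odds ratio
exp(β_exposure) with a design-df t interval. A log-binomial (prevalence
ratio) variant is deliberately out of scope: odds ratios are the reported
measure. Batch fits report per-combination failures (separation, rank
deficiency) with reasons instead of dropping rows.

The spline is the truncated-power natural cubic basis: df columns (default
df = 4), interior knots at equally spaced *weighted* age quantiles, boundary
knots at the observed age range, linear beyond the boundaries. The basis,
knots and boundaries round-trip through the fit result for scoring new data.

## Synthetic-data generator

The generator is the package's test bed and emulates the structure (not the
exact margins) of a pooled national expenditure survey:

- **Design**: `n_strata` strata × 2 PSUs (the minimal design for Taylor
  variance, and the common PUF layout) × `persons_per_psu` persons. Stratum
  population shares are Dirichlet-distributed; weights are the stratum share
  spread over its sample, perturbed log-normally (σ = 0.3), then
  ratio-calibrated so Σw equals the target of 249,221,000 adults exactly.
  Weights are independent of outcomes (noninformative design).
- **Ages** mix three bands 18–39 / 40–64 / 65+ (0.38/0.41/0.21), uniform
  within band; age enters all condition logits as (age − 50)/25.
- **Conditions**: logit p_ic = base_c + slope_c·age_std + f_i with a single
  shared frailty f_i ~ N(0, σ_f²), σ_f = 0.9 by default. One parameter
  yields positive dependence between all pairs (every true lift > 1),
  the qualitative signature of real multimorbidity data; with σ_f = 0 *and*
  flat age slopes conditions are exactly independent and every true lift is
  1 — shared age dependence alone already induces marginal dependence, so
  the independence configurations used in the calibration tests set both to
  zero. Default baselines/slopes span treated prevalences from roughly 25%
  (hypertension-like) to ~1%, rising with age.
- **Expenditures**: log-normal, log-mean 6.7 + 0.35 × condition count,
  σ = 1.2 — right-skewed, heavy-tailed, mean and median strictly increasing
  with condition count (the dose-response pattern of real data).
  Out-of-pocket spending is a uniform 5–35% share of total.
- **Poor health**: logistic in condition count (intercept −3.3, slope 0.45),
  with optional per-condition extras and a designed combination-exposure
  coefficient. The regression benchmark sets the count slope to 0 and the
  exposure log-odds to log 6.9, making the fitted exposure model correctly
  specified so the true adjusted OR is exactly 6.9. The 5-level self-rated
  health item is drawn consistently (fair/poor for the poor-health draws,
  excellent–good spread uniformly otherwise).
- **Ground truth** is computed by Monte Carlo integration over (age,
  frailty) on a separate seed stream (default 2×10⁵ draws; 10⁶ in the lift
  calibration tests): conditions are independent given both, so true joint
  prevalences are means of probability products — no bit sampling, hence no
  extra binomial noise.

What passing tests show: the estimators are calibrated (93–97% empirical
coverage) under correct model specification, a noninformative design, and
independent sampling within PSUs. What they do not show: robustness to
informative weights, intra-PSU correlation beyond the shared-frailty
structure, measurement error in self-reported conditions, or the treated-vs-
true prevalence gap of real surveys — those properties belong to the data,
not the estimators.

## Problem sizes and numerical choices

The shipped simulations use sizes chosen to make Monte-Carlo error small
relative to the tolerances they check: coverage runs use 1,000 replicates at
n = 10,000 (proportions) and n = 20,000 (lift); the odds-ratio recovery uses
200 replicates of the 50,000-person benchmark; the acceptance run mines a
20,000-person population. Seeds are fixed throughout; every simulation is
reproducible bit-for-bit. Degenerate inputs are first-class: empty domains
return missing-estimate markers, zero marginal prevalence makes lift an
explicit error, exposures held by everyone are rank errors reported per
combination, and all-equal ages cannot support a spline.

## Known limitations

- The ICD-10 map is data, but the shipped default is unvalidated against any
  clinical source; national-survey replications require the official
  category map.
- Replicate-weight (BRR/jackknife) variance is not implemented as a primary
  method; the Taylor estimator assumes ≥ 2 PSUs per (possibly collapsed)
  stratum.
- The minimum-improvement rule compares point estimates; sampling noise in a
  parent's statistic propagates into retention decisions near the margin.
- Lift is estimated marginally; it does not adjust for age or other shared
  risk factors, and a lift above 1 is expected for most chronic-condition
  pairs for that reason alone.
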