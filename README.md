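# morbmine

Survey-weighted association-rule mining of multimorbidity combinations.

Most chronic-disease surveillance counts conditions one at a time, yet a large
share of adults is treated for two or more conditions at once, and the burden
of a *specific* combination (say, heart failure together with cardiovascular
disease) is not the sum of its parts. `morbmine` is a library for
epidemiologists and health-services researchers who want to enumerate **every
combination of chronic conditions above a prevalence floor** in
complex-survey microdata — stratified, clustered, unequally weighted samples
such as national household expenditure surveys — and to attach design-based
estimates of burden to each combination.

## What it computes

Treating each respondent as a transaction and each of 20 primary-care
chronic-condition categories as items, the package:

1. **Mines frequent combinations** with a weighted Apriori search. A person
   counts toward combination *X* iff they hold *all* its conditions
   ("at least", not "exactly"). Two-stage thresholds: unweighted support
   ≥ 0.20% in an initial pass, then weighted count N̂_X ≥ 1 million persons.
2. **Estimates burden per combination** by Taylor-series linearization on the
   stratum/PSU design (with-replacement first stage, t intervals on
   df = #PSUs − #strata):
   - prevalence p̂_X = Σ wᵢ1{i ⊇ X} / Σ wᵢ and weighted count N̂_X;
   - **lift** L = p̂_X / ∏_{c∈X} p̂_c, the observed-to-expected prevalence
     ratio under independence, with a log-scale CI;
   - mean and median (IQR) annual medical and out-of-pocket expenditures and
     the share in fair/poor self-rated health among holders (domain ratio
     estimators).
3. **Prunes redundant combinations** with a 10% minimum-improvement rule: a
   combination is reported for an outcome only if its statistic exceeds every
   immediate parent combination's by ≥ 10%, then ranks the union of the
   top-k by cost and by poor health.
4. **Fits survey-weighted logistic regressions** of poor health on each
   combination exposure, adjusted for age (natural cubic spline), race and
   sex, with linearized sandwich variances: adjusted odds ratios
   exp(β) with design-df t intervals.
5. **Generates synthetic survey data with known ground truth** — shared-
   frailty-correlated condition indicators, log-normal expenditures rising
   with condition count, a logistic poor-health model, weights calibrated to
   249.221 million adults — so every stage is testable without microdata
   downloads.

Weights pooled over k survey years are divided by k so totals estimate a
single-year population.

## Worked example

```python
from morbmine import generate_population, mine_frequent_itemsets
from morbmine.synth import GeneratorConfig

cfg = GeneratorConfig(n_strata=50, psus_per_stratum=2, persons_per_psu=200, seed=1)
ds, truth = generate_population(cfg)
result = mine_frequent_itemsets(ds)   # support >= 0.20%, weighted N >= 1e6
```

Running `python examples/01_simulate_and_mine.py` prints:

```
persons sampled: 20000; weighted population: 249.221 million
frequent combinations (size >= 2): 1713
by size: {2: 168, 3: 584, 4: 694, 5: 251, 6: 16}

most prevalent dyads (weighted persons, millions):
  hypertension + hyperlipidemia                             28.6M  (11.5%)
  hypertension + arthritis                                  19.7M  (7.9%)
  ...
```

i.e. 1,713 condition combinations are each treated in at least one million
weighted persons of this synthetic population; the most common dyad,
hypertension + hyperlipidemia, covers 28.6 million (11.5% of adults).
`examples/02_design_based_estimates.py` reproduces hand-checkable estimates
on an 8-person fixture (prevalence 30.0% with SE 8.49 points; lift 7/6 with
an asymmetric log-scale CI), `examples/03_burden_ranking.py` shows the
minimum-improvement filter and top-burden union, and
`examples/04_adjusted_odds_ratio.py` recovers a designed exposure odds ratio
of 6.9 (estimated 6.86, 95% CI 6.39–7.37) from a 50,000-person benchmark.

A thin CLI mirrors the stages for shell use:

```bash
morbmine simulate --seed 1 --out data.csv --truth truth.json
morbmine mine --input data.csv --min-support 0.002 --min-weighted 1e6 --out itemsets.csv
morbmine run-all --input data.csv --out-dir results/
```

External microdata enter through a documented CSV contract (core person
columns plus 20 condition flags, or a long-format person/ICD-10 file with a
swappable code-map TSV); see `morbmine.ingest`.

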