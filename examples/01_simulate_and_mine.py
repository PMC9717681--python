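"""Generate a survey-like population and mine its frequent condition combinations.

Builds a 20,000-person stratified sample calibrated to 249.221 million adults,
then enumerates every combination of chronic conditions held (at least) by
0.20% of the sample and at least one million weighted persons — the study's
two-stage support threshold.
"""

from morbmine import generate_population, mine_frequent_itemsets
from morbmine.synth import GeneratorConfig

cfg = GeneratorConfig(n_strata=50, psus_per_stratum=2, persons_per_psu=200, seed=1)
ds, truth = generate_population(cfg)
print(f"persons sampled: {ds.n}; weighted population: {ds.weights.sum() / 1e6:.3f} million")

result = mine_frequent_itemsets(ds)  # defaults: support >= 0.20%, weighted N >= 1e6
print(f"frequent combinations (size >= 2): {len(result.frequent)}")
print(f"by size: {result.by_size()}")

print("\nmost prevalent dyads (weighted persons, millions):")
for rec in [r for r in result.frequent if len(r.itemset) == 2][:5]:
    names = " + ".join(ds.catalog.names(rec.itemset))
    print(f"  {names:55s} {rec.weighted_n / 1e6:6.1f}M  ({100 * rec.prevalence:.1f}%)")

# Each line is a combination, the population holding at least those
# conditions, and its share of the weighted adult population.
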