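"""Synthetic complex-survey microdata with known ground truth.

Emulates the structure of a national household expenditure survey: a
stratified design with (by default) two PSUs per stratum — the minimal design
for Taylor variance estimation and the common public-use-file layout —
unequal person weights calibrated to a target adult population total, 20
positively dependent chronic-condition indicators whose treated prevalence
rises with age, right-skewed (log-normal) medical expenditures that grow with
condition count, and a 5-level self-rated health item whose fair/poor
probability follows a logistic model in condition count (plus optional
designated-condition and combination-exposure effects).

Positive dependence between conditions comes from a single shared Gaussian
frailty added to every condition's logit: one parameter drives all pairwise
lifts above 1, mirroring the empirical finding that every highly prevalent
combination co-occurs more than independence predicts. With the frailty SD
at zero AND flat age slopes the conditions are exactly independent and every
true lift is 1 — the generator's null configuration.

Ground truth (marginal prevalences, combination prevalence and lift, the
designed exposure odds ratio) is computed at generation time by Monte Carlo
integration over the (age, frailty) mixing distribution on a separate seed
stream, exploiting that conditions are independent given (age, frailty):
the true joint prevalence of a combination is E[prod_c p_c(age, f)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .catalog import N_CONDITIONS, default_catalog
from .dataset import RACE5_LEVELS, SurveyDataset
from .mining import Itemset, itemset_mask

AGE_BANDS = ((18.0, 40.0), (40.0, 65.0), (65.0, 90.0))
_AGE_CENTER, _AGE_SCALE = 50.0, 25.0  # age enters logits as (age-50)/25


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults give a survey-like population.

    ``base_logodds``/``age_slopes`` have one entry per active condition
    (conditions beyond ``len(base_logodds)`` never occur). ``frailty_sd``
    is the SD of the shared per-person Gaussian frailty; 0 plus zero age
    slopes means independent conditions (all true lifts exactly 1).
    """

    n_strata: int = 25
    psus_per_stratum: int = 2
    persons_per_psu: int = 40
    target_population_total: float = 249_221_000.0
    age_mix: tuple[float, float, float] = (0.38, 0.41, 0.21)  # 18-39 / 40-64 / 65+
    base_logodds: tuple[float, ...] = (
        -1.3, -1.5, -2.2, -2.1, -2.6, -3.6, -2.5, -2.0, -2.5, -2.7,
        -3.0, -2.2, -3.1, -3.6, -4.1, -4.6, -3.5, -3.9, -4.4, -3.3,
    )
    age_slopes: tuple[float, ...] = (
        1.4, 1.5, 1.1, 1.3, 1.5, 1.5, 0.2, 0.8, 0.9, 0.6,
        1.2, -0.3, 1.4, 1.3, 0.5, 2.2, 1.8, 1.6, 0.0, -0.4,
    )
    frailty_sd: float = 0.9
    exp_intercept: float = 6.7        # log-dollars at 0 conditions
    exp_increment: float = 0.35       # added per condition held
    exp_sd: float = 1.2
    oop_fraction_range: tuple[float, float] = (0.05, 0.35)
    ph_intercept: float = -3.3        # poor-health logit at 0 conditions
    ph_count_coef: float = 0.45
    ph_condition_coefs: dict[int, float] = field(default_factory=dict)
    exposure_itemset: Itemset | None = None
    exposure_log_or: float = 0.0
    weight_heterogeneity: float = 0.3  # lognormal sigma of weight perturbation
    female_share: float = 0.517
    race_mix: tuple[float, ...] = (0.163, 0.628, 0.118, 0.061, 0.030)
    year: int = 2019
    pooled_years: int = 1
    truth_draws: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psus_per_stratum < 2:
            raise GeneratorConfigError("psus_per_stratum must be >= 2")
        if self.frailty_sd < 0 or self.exp_sd < 0 or self.weight_heterogeneity < 0:
            raise GeneratorConfigError("standard deviations must be >= 0")
        if len(self.base_logodds) != len(self.age_slopes):
            raise GeneratorConfigError("base_logodds and age_slopes lengths differ")
        if len(self.base_logodds) > N_CONDITIONS:
            raise GeneratorConfigError(f"at most {N_CONDITIONS} conditions")
        if not np.isclose(sum(self.age_mix), 1.0):
            raise GeneratorConfigError("age_mix must sum to 1")
        if not 0 < self.female_share < 1:
            raise GeneratorConfigError("female_share must be in (0,1)")

    @property
    def n_active(self) -> int:
        return len(self.base_logodds)


@dataclass
class TruthRecord:
    """Generator ground truth for parameter-recovery tests.

    ``combination_truth`` maps an itemset to (true prevalence, true lift),
    integrated over the population's (age, frailty) distribution.
    """

    marginal_prevalence: np.ndarray
    combination_truth: dict[Itemset, tuple[float, float]]
    exposure_itemset: Itemset | None
    exposure_or: float | None


def _draw_ages(rng: np.random.Generator, n: int, mix) -> np.ndarray:
    band = rng.choice(3, size=n, p=np.asarray(mix))
    lo = np.array([AGE_BANDS[b][0] for b in band])
    hi = np.array([AGE_BANDS[b][1] for b in band])
    return lo + rng.random(n) * (hi - lo)


def _condition_probs(config: GeneratorConfig, ages: np.ndarray, frailty: np.ndarray):
    """(n, n_active) matrix of per-condition probabilities given age, frailty."""
    a = (ages - _AGE_CENTER) / _AGE_SCALE
    base = np.asarray(config.base_logodds)
    slope = np.asarray(config.age_slopes)
    return expit(base[None, :] + slope[None, :] * a[:, None] + frailty[:, None])


def compute_truth(config: GeneratorConfig, itemsets=None) -> TruthRecord:
    """Monte Carlo ground truth on a seed stream separate from the sample's.

    Integrates over (age, frailty); conditions are independent given both, so
    joint prevalences are means of probability products, with no bit sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 782_143]))
    m = config.truth_draws
    ages = _draw_ages(rng, m, config.age_mix)
    frailty = rng.normal(0.0, config.frailty_sd, size=m) if config.frailty_sd > 0 else np.zeros(m)
    probs = _condition_probs(config, ages, frailty)
    marginals = probs.mean(axis=0)
    if itemsets is None:
        k = config.n_active
        itemsets = [(i, j) for i in range(k) for j in range(i + 1, k)]
        if config.exposure_itemset:
            itemsets.append(tuple(config.exposure_itemset))
    combo: dict[Itemset, tuple[float, float]] = {}
    for it in itemsets:
        joint = probs[:, list(it)].prod(axis=1).mean()
        expected = np.prod(marginals[list(it)])
        combo[tuple(it)] = (float(joint), float(joint / expected))
    return TruthRecord(
        marginal_prevalence=marginals,
        combination_truth=combo,
        exposure_itemset=tuple(config.exposure_itemset) if config.exposure_itemset else None,
        exposure_or=float(np.exp(config.exposure_log_or)) if config.exposure_itemset else None,
    )


def generate_population(
    config: GeneratorConfig, compute_truth_record: bool = True
) -> tuple[SurveyDataset, TruthRecord | None]:
    """Draw one synthetic sample; deterministic given ``config.seed``.

    Weights start at target_population_total x stratum share / persons in
    stratum, are perturbed by a lognormal heterogeneity factor, then
    ratio-calibrated so they sum exactly to the population total. Weights are
    independent of outcomes (a noninformative design), so weighted estimators
    are unbiased for the generator's truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_psu_total = config.n_strata * config.psus_per_stratum
    n = n_psu_total * config.persons_per_psu

    stratum = np.repeat(np.arange(config.n_strata), config.psus_per_stratum * config.persons_per_psu)
    psu = np.repeat(np.arange(n_psu_total), config.persons_per_psu)

    # design weights: stratum share of the population, spread over its sample
    shares = rng.dirichlet(np.full(config.n_strata, 8.0))
    persons_per_stratum = config.psus_per_stratum * config.persons_per_psu
    w = config.target_population_total * shares[stratum] / persons_per_stratum
    if config.weight_heterogeneity > 0:
        w = w * rng.lognormal(0.0, config.weight_heterogeneity, size=n)
    w = w * (config.target_population_total / w.sum())  # ratio calibration

    ages = _draw_ages(rng, n, config.age_mix)
    sex = np.where(rng.random(n) < config.female_share, "female", "male")
    race = rng.choice(np.asarray(RACE5_LEVELS, dtype=object), size=n, p=np.asarray(config.race_mix))
    frailty = (
        rng.normal(0.0, config.frailty_sd, size=n) if config.frailty_sd > 0 else np.zeros(n)
    )
    probs = _condition_probs(config, ages, frailty)
    bits = rng.random(probs.shape) < probs
    mask = np.zeros(n, dtype=np.int64)
    for c in range(config.n_active):
        mask |= bits[:, c].astype(np.int64) << c
    count = bits.sum(axis=1)

    total_exp = np.exp(rng.normal(config.exp_intercept + config.exp_increment * count, config.exp_sd))
    oop_lo, oop_hi = config.oop_fraction_range
    oop_exp = total_exp * rng.uniform(oop_lo, oop_hi, size=n)

    logit_ph = config.ph_intercept + config.ph_count_coef * count
    for c, coef in config.ph_condition_coefs.items():
        logit_ph = logit_ph + coef * bits[:, c]
    if config.exposure_itemset:
        em = itemset_mask(tuple(config.exposure_itemset))
        logit_ph = logit_ph + config.exposure_log_or * ((mask & em) == em)
    poor = rng.random(n) < expit(logit_ph)
    # 5-level self-rated health consistent with the poor-health indicator:
    # poor -> fair(4)/poor(5), else excellent..good spread uniformly.
    srh = np.where(poor, rng.integers(4, 6, size=n), rng.integers(1, 4, size=n))

    table = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "year": config.year,
            "stratum": stratum,
            "psu": psu,
            "weight": w,
            "age": ages,
            "sex": sex,
            "race5": race,
            "srh": srh,
            "poor_health": poor,
            "total_exp": total_exp,
            "oop_exp": oop_exp,
            "cond_mask": mask,
        }
    )
    ds = SurveyDataset(table, default_catalog(), config.pooled_years)
    truth = compute_truth(config) if compute_truth_record else None
    return ds, truth


# ---------------------------------------------------------------------------
# Frozen fixtures
# ---------------------------------------------------------------------------

def _tiny_handcheck() -> SurveyDataset:
    """8 persons, 3 conditions (A,B,C = bits 0,1,2), 2 strata x 2 PSUs.

    Weights 1,2,3,4,1,2,3,4 and condition patterns chosen so every weighted
    support, lift and Taylor variance can be recomputed by hand; the frozen
    values live in the test suite.
    """
    masks = [0b001, 0b011, 0b101, 0b110, 0b010, 0b100, 0b110, 0b000]
    srh = [3, 4, 2, 5, 1, 4, 3, 2]
    table = pd.DataFrame(
        {
            "person_id": range(1, 9),
            "year": 2019,
            "stratum": ["S1"] * 4 + ["S2"] * 4,
            "psu": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
            "weight": [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
            "age": [25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 30.0, 50.0],
            "sex": ["male", "female"] * 4,
            "race5": ["nh_white", "hispanic", "nh_black", "nh_white",
                      "nh_asian", "other", "nh_white", "nh_white"],
            "srh": srh,
            "poor_health": [s >= 4 for s in srh],
            "total_exp": [100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0],
            "oop_exp": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0],
            "cond_mask": masks,
        }
    )
    return SurveyDataset(table, default_catalog(), pooled_years=1)


SMALL_MINING_CONFIG = GeneratorConfig(
    n_strata=5,
    psus_per_stratum=2,
    persons_per_psu=20,
    target_population_total=1_000_000.0,
    base_logodds=(-0.6, -0.9, -1.2, -1.6, -2.0),
    age_slopes=(0.8, 0.6, 0.9, 0.4, 0.7),
    frailty_sd=0.8,
    truth_draws=50_000,
    seed=20160,
)

REGRESSION_BENCH_CONFIG = GeneratorConfig(
    n_strata=25,
    psus_per_stratum=2,
    persons_per_psu=1000,  # 50,000 persons
    base_logodds=(-1.0, -1.3, -1.6, -2.0, -2.4, -2.8),
    age_slopes=(1.0, 0.8, 1.1, 0.7, 0.9, 0.6),
    frailty_sd=0.8,
    ph_intercept=-2.2,
    ph_count_coef=0.0,          # outcome depends only on the designed exposure
    exposure_itemset=(0, 2),
    exposure_log_or=float(np.log(6.9)),
    truth_draws=100_000,
    seed=20190,
)


def make_fixture(name: str, seed: int | None = None):
    """Frozen, versioned study fixtures.

    ``tiny_handcheck``: 8 persons / 3 conditions / 2 strata x 2 PSUs with
    hand-checkable numbers (returns the dataset only). ``small_mining``:
    200 persons, 5 conditions. ``regression_bench``: 50,000 persons with a
    designed combination-exposure odds ratio of 6.9 on poor health. The two
    generated fixtures return (dataset, truth); ``seed`` overrides the frozen
    seed for replicate studies.
    """
    if name == "tiny_handcheck":
        return _tiny_handcheck()
    if name == "small_mining":
        cfg = SMALL_MINING_CONFIG
    elif name == "regression_bench":
        cfg = REGRESSION_BENCH_CONFIG
    else:
        raise ValueError(f"unknown fixture {name!r}")
    if seed is not None:
        from dataclasses import replace

        cfg = replace(cfg, seed=seed)
    return generate_population(cfg)
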