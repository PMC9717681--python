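import numpy as np
import pandas as pd
import pytest

from morbmine import default_catalog, make_fixture
from morbmine.dataset import SurveyDataset
from morbmine.synth import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def tiny():
    """8 persons / 3 conditions / 2 strata x 2 PSUs; all numbers hand-checkable.

    Weights 1,2,3,4,1,2,3,4; total weight 20. Condition bits (A,B,C = 0,1,2):
    persons hold A={1,2,3}, B={2,4,5,7}, C={3,4,6,7}; hence weighted totals
    N_A=6, N_B=10, N_C=12, N_AB=2, N_AC=3, N_BC=7, N_ABC=0.
    """
    return make_fixture("tiny_handcheck")


@pytest.fixture(scope="session")
def small_mining():
    """200 persons, 5 active conditions, with generator ground truth."""
    return make_fixture("small_mining")


def random_dataset(seed: int, n_conditions: int = 8, n: int = 400) -> SurveyDataset:
    """Small random survey dataset for property tests (arbitrary masks)."""
    rng = np.random.default_rng(seed)
    n_strata = 4
    persons_per_stratum = n // n_strata
    stratum = np.repeat(np.arange(n_strata), persons_per_stratum)
    psu = stratum * 2 + (np.arange(n) % 2)
    masks = rng.integers(0, 1 << n_conditions, size=n)
    srh = rng.integers(1, 6, size=n)
    table = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "year": 2019,
            "stratum": stratum,
            "psu": psu,
            "weight": rng.lognormal(8.0, 0.6, size=n),
            "age": rng.uniform(18, 90, size=n),
            "sex": rng.choice(["male", "female"], size=n),
            "race5": rng.choice(
                ["hispanic", "nh_white", "nh_black", "nh_asian", "other"], size=n
            ),
            "srh": srh,
            "poor_health": srh >= 4,
            "total_exp": rng.lognormal(8, 1.2, size=n),
            "oop_exp": rng.lognormal(5, 1.0, size=n),
            "cond_mask": masks,
        }
    )
    return SurveyDataset(table, default_catalog(), pooled_years=1)


@pytest.fixture()
def srs_dataset():
    """Equal-weight SRS: one stratum, each person its own PSU."""

    def build(y: np.ndarray, weights=None) -> SurveyDataset:
        n = len(y)
        table = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "year": 2019,
                "stratum": 0,
                "psu": np.arange(n),
                "weight": np.ones(n) if weights is None else weights,
                "age": 50.0,
                "sex": "male",
                "race5": "nh_white",
                "srh": 3,
                "poor_health": False,
                "total_exp": 0.0,
                "oop_exp": 0.0,
                "cond_mask": np.asarray(y, dtype=np.int64),
            }
        )
        return SurveyDataset(table, default_catalog(), pooled_years=1)

    return build


@pytest.fixture(scope="session")
def independence_config():
    """Flat age slopes and zero frailty: conditions exactly independent."""
    return GeneratorConfig(
        n_strata=10,
        psus_per_stratum=2,
        persons_per_psu=100,
        base_logodds=(-0.85, -1.4, -1.9),
        age_slopes=(0.0, 0.0, 0.0),
        frailty_sd=0.0,
        truth_draws=100_000,
        seed=1234,
    )


@pytest.fixture(scope="session")
def regression_bench():
    return make_fixture("regression_bench")


@pytest.fixture(scope="session")
def medium_population():
    """One mid-sized draw from the default survey-like configuration."""
    cfg = GeneratorConfig(
        n_strata=30, psus_per_stratum=2, persons_per_psu=100, seed=99, truth_draws=50_000
    )
    return generate_population(cfg)
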