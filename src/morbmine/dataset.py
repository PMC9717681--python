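"""Survey dataset container: person-level microdata plus complex-survey design.

The central object is :class:`SurveyDataset` — a pandas table of respondents
(one row per person-year) carrying the design metadata (stratum, PSU, weight),
demographics, outcomes, and a 20-bit chronic-condition vector — together with
the :class:`~morbmine.catalog.ConditionCatalog` that fixes the bit layout and
the number of pooled survey years used to annualize weights.

In itemset-mining terms each person is a transaction and each condition an
item; the analysis weight (base weight / pooled years) makes weighted totals
estimate a single-year population.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog, N_CONDITIONS, default_catalog

SEX_LEVELS = ("male", "female")
RACE5_LEVELS = ("hispanic", "nh_white", "nh_black", "nh_asian", "other")

#: Canonical column order of the delimited interchange format.
CORE_COLUMNS = [
    "person_id",
    "year",
    "stratum",
    "psu",
    "weight",
    "age",
    "sex",
    "race5",
    "srh",
    "poor_health",
    "total_exp",
    "oop_exp",
]


class DatasetError(ValueError):
    pass


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def condition_columns(catalog: ConditionCatalog) -> list[str]:
    """Per-condition 0/1 column names used in the delimited format."""
    return [f"c_{_slug(name)}" for name in catalog.categories]


@dataclass(frozen=True)
class SurveyDataset:
    """Person-level complex-survey microdata ready for mining and estimation.

    Attributes
    ----------
    table:
        DataFrame with ``CORE_COLUMNS`` plus ``cond_mask`` (20-bit integer
        condition vector). Strata and PSUs are opaque labels; every PSU label
        must occur within a single stratum.
    catalog:
        The 20-condition roster defining the bit layout of ``cond_mask``.
    pooled_years:
        Number of pooled survey years k >= 1. Analysis weights are
        base weight / k so that weighted totals estimate an annual population.
    """

    table: pd.DataFrame
    catalog: ConditionCatalog
    pooled_years: int = 1

    def __post_init__(self) -> None:
        if self.pooled_years < 1:
            raise DatasetError(f"pooled_years must be >= 1, got {self.pooled_years}")
        missing = [c for c in CORE_COLUMNS + ["cond_mask"] if c not in self.table.columns]
        if missing:
            raise DatasetError(f"table missing columns: {missing}")
        if len(self.table) == 0:
            raise DatasetError("dataset is empty")

    # -- array views used throughout the estimators ------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def weights(self) -> np.ndarray:
        """Analysis weights: base weights divided by pooled_years."""
        return self.table["weight"].to_numpy(dtype=float) / self.pooled_years

    @property
    def base_weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    @property
    def strata(self) -> np.ndarray:
        return self.table["stratum"].to_numpy()

    @property
    def psus(self) -> np.ndarray:
        return self.table["psu"].to_numpy()

    @property
    def cond_masks(self) -> np.ndarray:
        return self.table["cond_mask"].to_numpy(dtype=np.int64)

    @property
    def condition_counts(self) -> np.ndarray:
        """Number of the 20 catalog conditions each person holds."""
        masks = self.cond_masks
        counts = np.zeros(len(masks), dtype=np.int64)
        for b in range(N_CONDITIONS):
            counts += (masks >> b) & 1
        return counts

    def holds_mask(self, mask: int) -> np.ndarray:
        """Boolean: person's condition vector contains ALL bits of ``mask``."""
        return (self.cond_masks & mask) == mask

    def with_table(self, table: pd.DataFrame) -> "SurveyDataset":
        return replace(self, table=table.reset_index(drop=True))


def validate_dataset(ds: SurveyDataset) -> list[str]:
    """Check all dataset invariants; return a (possibly empty) list of violations.

    Reporting only — never raises. An empty list means the dataset satisfies
    every structural invariant (design nesting, weight sign, outcome coding,
    condition-vector range).
    """
    t = ds.table
    out: list[str] = []
    if (t["weight"] < 0).any():
        out.append(f"{int((t['weight'] < 0).sum())} negative weights")
    psu_strata = t.groupby("psu", sort=False)["stratum"].nunique()
    bad_psu = psu_strata[psu_strata > 1]
    for psu in bad_psu.index:
        out.append(f"PSU {psu!r} appears in {psu_strata[psu]} strata")
    srh = t["srh"]
    if srh.isna().any():
        out.append(f"{int(srh.isna().sum())} persons with missing srh")
    else:
        bad = ~srh.isin([1, 2, 3, 4, 5])
        if bad.any():
            out.append(f"{int(bad.sum())} persons with srh outside 1..5")
        mism = t["poor_health"].astype(bool) != srh.isin([4, 5])
        if mism.any():
            out.append(f"{int(mism.sum())} persons where poor_health != (srh in {{4,5}})")
    for col in ("total_exp", "oop_exp"):
        if t[col].isna().any():
            out.append(f"{int(t[col].isna().sum())} persons with missing {col}")
        elif (t[col] < 0).any():
            out.append(f"{int((t[col] < 0).sum())} negative {col}")
    if (t["age"] < 18).any():
        out.append(f"{int((t['age'] < 18).sum())} persons younger than 18")
    masks = t["cond_mask"]
    if ((masks < 0) | (masks >= (1 << N_CONDITIONS))).any():
        out.append("condition masks outside 20-bit range")
    bad_sex = ~t["sex"].isin(SEX_LEVELS)
    if bad_sex.any():
        out.append(f"{int(bad_sex.sum())} persons with unknown sex level")
    bad_race = ~t["race5"].isin(RACE5_LEVELS)
    if bad_race.any():
        out.append(f"{int(bad_race.sum())} persons with unknown race5 level")
    return out


def drop_incomplete(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Exclude persons with missing self-rated health or expenditures.

    Returns the filtered table and the number of exclusions (for the run
    manifest; the study protocol excludes such persons rather than imputing).
    """
    ok = (
        table["srh"].notna()
        & table["total_exp"].notna()
        & table["oop_exp"].notna()
    )
    return table.loc[ok].reset_index(drop=True), int((~ok).sum())


# ---------------------------------------------------------------------------
# Delimited-format round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SurveyDataset, path, sep: str = ",") -> None:
    """Write the canonical delimited format: core columns + one 0/1 column
    per catalog condition (bit layout expanded; ``cond_mask`` is derived)."""
    t = ds.table.copy()
    cols = condition_columns(ds.catalog)
    masks = ds.cond_masks
    for b, col in enumerate(cols):
        t[col] = (masks >> b) & 1
    t["poor_health"] = t["poor_health"].astype(int)
    t[CORE_COLUMNS + cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_dataset(
    path,
    catalog: ConditionCatalog | None = None,
    pooled_years: int = 1,
    sep: str = ",",
) -> SurveyDataset:
    """Read the canonical delimited format written by :func:`write_dataset`."""
    catalog = catalog or default_catalog()
    t = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = condition_columns(catalog)
    missing = [c for c in cols if c not in t.columns]
    if missing:
        raise DatasetError(f"input lacks condition columns: {missing[:3]}...")
    mask = np.zeros(len(t), dtype=np.int64)
    for b, col in enumerate(cols):
        mask |= t[col].to_numpy(dtype=np.int64) << b
    t = t.drop(columns=cols)
    t["cond_mask"] = mask
    t["poor_health"] = t["poor_health"].astype(bool)
    return SurveyDataset(t, catalog, pooled_years)
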