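"""Cohort assembly: derive analysis variables and build a validated dataset.

Takes person-level microdata (delimited text), an optional long-format
condition file of (person_id, 3-character ICD-10 category) rows, and a code
map TSV, and produces a :class:`~morbmine.dataset.SurveyDataset` with

* poor perceived health derived from the 5-level self-rated health item,
* expenditures inflated to base-year (2019) dollars via supplied deflators,
* condition vectors mapped onto the 20-category roster,
* persons with missing health or expenditure data excluded (and counted).

Deflator tables are configuration, not computation: total expenditures use a
health-price index (PCE-health), out-of-pocket a medical-care CPI, both
expressed as multipliers to base-year dollars. Defaults of 1.0 mean synthetic
runs need no economic series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .catalog import ConditionCatalog, default_catalog, load_code_map, map_icd_to_conditions
from .dataset import CORE_COLUMNS, SurveyDataset, DatasetError, drop_incomplete

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def dichotomize_health(srh: int) -> bool:
    """Collapse 5-level self-rated health to the poor-health outcome.

    Levels are excellent (1) .. poor (5); fair (4) or poor (5) counts as poor
    perceived health.
    """
    if srh not in (1, 2, 3, 4, 5):
        raise ValueError(f"self-rated health must be in 1..5, got {srh!r}")
    return srh >= 4


def adjust_inflation(amount: float, year: int, index_table: dict[int, float]) -> float:
    """Convert a nominal dollar amount to base-year dollars.

    ``index_table`` maps year -> deflator (multiplier to base-year dollars);
    the base year's deflator is 1 by construction.
    """
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    if year not in index_table:
        raise ConfigError(f"no deflator for year {year}")
    return amount * index_table[year]


def annualize_weights(ds: SurveyDataset, pooled_years: int | None = None) -> SurveyDataset:
    """Set the annualization divisor so weighted totals estimate one year.

    With k pooled survey years each base weight is divided by k (lazily, via
    the ``weights`` property), so the sum of analysis weights estimates the
    annual population rather than k times it.
    """
    k = ds.pooled_years if pooled_years is None else pooled_years
    if k < 1:
        raise ConfigError(f"pooled_years must be >= 1, got {k}")
    return SurveyDataset(ds.table, ds.catalog, k)


@dataclass
class IngestConfig:
    """Column names, pooling, and deflators for reading external microdata."""

    columns: dict[str, str] = field(default_factory=dict)  # canonical -> file column
    pooled_years: int = 1
    total_deflators: dict[int, float] = field(default_factory=dict)
    oop_deflators: dict[int, float] = field(default_factory=dict)
    year_specific_strata: bool = True
    sep: str = ","
    catalog_file: str | None = None  # code-map TSV; None -> shipped map

    @classmethod
    def from_yaml(cls, path) -> "IngestConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            columns=raw.get("columns", {}),
            pooled_years=int(raw.get("pooled_years", 1)),
            total_deflators={int(k): float(v) for k, v in raw.get("total_deflators", {}).items()},
            oop_deflators={int(k): float(v) for k, v in raw.get("oop_deflators", {}).items()},
            year_specific_strata=bool(raw.get("year_specific_strata", True)),
            sep=raw.get("sep", ","),
            catalog_file=raw.get("catalog_file"),
        )
        if cfg.pooled_years < 1:
            raise ConfigError("pooled_years must be >= 1")
        return cfg


def assemble_dataset(
    persons: pd.DataFrame,
    conditions: pd.DataFrame | None,
    config: IngestConfig,
    catalog: ConditionCatalog | None = None,
) -> tuple[SurveyDataset, dict]:
    """Build a SurveyDataset from raw person rows and long-format conditions.

    Parameters
    ----------
    persons:
        One row per person-year with (possibly renamed, see
        ``config.columns``) core columns. ``srh`` drives ``poor_health``;
        a pre-existing ``poor_health`` column is ignored and re-derived.
    conditions:
        Long-format (person_id, icd10_3) rows; full ICD-10-CM codes are
        truncated to their 3-character category before lookup. ``None`` means
        ``persons`` already carries per-condition 0/1 columns.
    config:
        Column mapping, pooled years, deflators.

    Returns
    -------
    (dataset, manifest):
        ``manifest`` records exclusions and unmapped-code tallies.
    """
    if catalog is None:
        if config.catalog_file:
            from .catalog import DEFAULT_CATEGORIES

            code_map = load_code_map(config.catalog_file, DEFAULT_CATEGORIES)
            catalog = ConditionCatalog(DEFAULT_CATEGORIES, code_map)
        else:
            catalog = default_catalog()

    t = persons.rename(columns={v: k for k, v in config.columns.items()}).copy()
    needed = [c for c in CORE_COLUMNS if c not in ("poor_health",)]
    missing = [c for c in needed if c not in t.columns]
    if missing:
        raise DatasetError(f"person file missing columns: {missing}")

    # Derived variables -----------------------------------------------------
    srh = t["srh"]
    valid_srh = srh.isin([1, 2, 3, 4, 5]) | srh.isna()
    if not valid_srh.all():
        bad = srh[~valid_srh].unique()
        raise ValueError(f"unmapped self-rated health responses: {bad[:5]}")
    t["poor_health"] = srh.isin([4, 5])

    years = t["year"].astype(int)
    for col, table in (("total_exp", config.total_deflators),
                       ("oop_exp", config.oop_deflators)):
        if table:
            missing_years = sorted(set(years.unique()) - set(table))
            if missing_years:
                raise ConfigError(f"no {col} deflator for years {missing_years}")
            t[col] = t[col] * years.map(table)

    if config.year_specific_strata and years.nunique() > 1:
        # Pooled-year analyses treat (year, stratum) pairs as distinct strata.
        t["stratum"] = years.astype(str) + ":" + t["stratum"].astype(str)
        t["psu"] = years.astype(str) + ":" + t["psu"].astype(str)

    # Condition vectors -----------------------------------------------------
    unmapped_total = 0
    if conditions is not None:
        cond = conditions.rename(columns={v: k for k, v in config.columns.items()})
        if not {"person_id", "icd10_3"} <= set(cond.columns):
            raise DatasetError("condition file needs person_id and icd10_3 columns")
        codes3 = cond["icd10_3"].astype(str).str.upper().str.slice(0, 3)
        mask_by_person: dict = {}
        for pid, grp in codes3.groupby(cond["person_id"]):
            mask, unmapped = map_icd_to_conditions(list(grp), catalog)
            mask_by_person[pid] = mask
            unmapped_total += unmapped
        t["cond_mask"] = t["person_id"].map(mask_by_person).fillna(0).astype(np.int64)
    elif "cond_mask" not in t.columns:
        from .dataset import condition_columns

        cols = condition_columns(catalog)
        missing = [c for c in cols if c not in t.columns]
        if missing:
            raise DatasetError(
                "no condition file and person file lacks condition columns: "
                f"{missing[:3]}..."
            )
        mask = np.zeros(len(t), dtype=np.int64)
        for b, col in enumerate(cols):
            mask |= t[col].to_numpy(dtype=np.int64) << b
        t["cond_mask"] = mask

    t, n_excluded = drop_incomplete(t)
    if n_excluded:
        log.info("excluded %d persons with missing health or expenditure data", n_excluded)

    zero_w = int((t["weight"] <= 0).sum())
    if zero_w:
        t = t.loc[t["weight"] > 0].reset_index(drop=True)
        log.info("excluded %d persons with non-positive weights", zero_w)

    ds = SurveyDataset(t, catalog, config.pooled_years)
    manifest = {
        "n_persons": int(ds.n),
        "n_excluded_missing": n_excluded,
        "n_excluded_zero_weight": zero_w,
        "n_unmapped_codes": unmapped_total,
        "pooled_years": config.pooled_years,
    }
    return ds, manifest
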