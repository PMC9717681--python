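"""End-to-end orchestration: ingest -> mine -> estimate -> filter -> regress.

Every number in the written reports is the untouched output of one library
operation; the pipeline only assembles tables, rounds for display, and
records a machine-readable run manifest (inputs, thresholds, seed, row
counts per stage) so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import SurveyDataset, read_dataset, validate_dataset
from .estimators import design_of, estimate_itemsets, estimates_to_frame, weighted_median_iqr
from .filtering import (
    OUTCOMES,
    exclude_conditions_variant,
    min_improvement_filter,
    sex_subgroup_pipeline,
    top_k_union,
)
from .mining import condition_count_bands, mine_frequent_itemsets
from .regression import batch_adjusted_or

log = logging.getLogger(__name__)

AGE_BAND_LABELS = ("18-39", "40-64", "65+")


@dataclass
class PipelineConfig:
    """Paths, thresholds and variant flags for one full analysis run."""

    input_path: str | None = None
    output_dir: str = "morbmine_out"
    pooled_years: int = 1
    min_unweighted_support: float = 0.0020
    min_weighted_total: float = 1_000_000.0
    tau: float = 0.10
    spline_df: int = 4
    ci_level: float = 0.95
    top_k: int = 20
    seed: int = 0
    exclude_conditions: list[str] = field(default_factory=list)
    sex_subgroups: bool = True
    single_psu: str = "error"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")
        for name in ("min_unweighted_support", "min_weighted_total", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _age_band(ages: pd.Series) -> pd.Series:
    return pd.cut(
        ages, bins=[18, 40, 65, np.inf], right=False, labels=AGE_BAND_LABELS
    )


def table1_report(ds: SurveyDataset) -> dict[str, pd.DataFrame]:
    """Condition-count-band table by demographics, plus expenditures by band.

    ``demographics``: one row per group (total, age bands, sex, race,
    poor health) with weighted N and cumulative row percentages of 0 / 1+ /
    2+ / 3+ / 4+ treated conditions. ``expenditures``: weighted median and
    IQR of total and out-of-pocket spending per condition-count band.
    """
    t = ds.table
    work = ds.with_table(t.assign(age_band=_age_band(t["age"]).astype(str)))
    blocks = [condition_count_bands(ds)]
    for col in ("age_band", "sex", "race5"):
        b = condition_count_bands(work, by=col)
        b["group"] = f"{col}:" + b["group"].astype(str)
        blocks.append(b)
    poor = ds.table["poor_health"].to_numpy()
    if poor.any():
        sub = ds.with_table(t.loc[poor])
        b = condition_count_bands(sub)
        b["group"] = "poor_health"
        blocks.append(b)
    demo = pd.concat(blocks, ignore_index=True)

    counts = ds.condition_counts
    w = ds.weights
    exp_rows = []
    for label, sel in [("0", counts == 0)] + [
        (f"{b}+", counts >= b) for b in (1, 2, 3, 4)
    ]:
        if not sel.any():
            exp_rows.append({"band": label})
            continue
        med, q25, q75 = weighted_median_iqr(t["total_exp"].to_numpy()[sel], w[sel])
        omed, oq25, oq75 = weighted_median_iqr(t["oop_exp"].to_numpy()[sel], w[sel])
        exp_rows.append(
            {
                "band": label,
                "median_exp": med, "exp_q25": q25, "exp_q75": q75,
                "median_oop": omed, "oop_q25": oq25, "oop_q75": oq75,
            }
        )
    return {"demographics": demo, "expenditures": pd.DataFrame(exp_rows)}


def run_full_pipeline(
    config: PipelineConfig, dataset: SurveyDataset | None = None
) -> dict:
    """Execute the whole analysis and write CSV reports plus a JSON manifest.

    ``dataset`` may be passed directly (e.g. fresh from the generator);
    otherwise ``config.input_path`` is read in the canonical delimited
    format. Identical inputs and config give byte-identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": {
        k: v for k, v in vars(config).items()
    }}

    stage = "ingest"
    try:
        if dataset is None:
            if not config.input_path:
                raise ValueError("no dataset and no input_path configured")
            dataset = read_dataset(config.input_path, pooled_years=config.pooled_years)
        violations = validate_dataset(dataset)
        manifest["n_persons"] = int(dataset.n)
        manifest["validation_violations"] = violations
        if violations:
            raise ValueError(f"dataset invariants violated: {violations[:3]}")
        if config.exclude_conditions:
            dataset = exclude_conditions_variant(dataset, config.exclude_conditions)

        stage = "design"
        design = design_of(dataset, single_psu=config.single_psu)
        manifest["design"] = {
            "n_strata": design.n_strata, "n_psus": design.n_psus, "df": design.df
        }

        stage = "table1"
        t1 = table1_report(dataset)
        t1["demographics"].to_csv(outdir / "table1_demographics.csv", index=False)
        t1["expenditures"].to_csv(outdir / "table1_expenditures.csv", index=False)

        stage = "mine"
        mined = mine_frequent_itemsets(
            dataset,
            config.min_unweighted_support,
            config.min_weighted_total,
        )
        manifest["n_frequent_itemsets"] = len(mined.frequent)
        manifest["itemsets_by_size"] = {str(k): v for k, v in sorted(mined.by_size().items())}

        stage = "estimate"
        estimates = estimate_itemsets(
            mined.singletons + mined.frequent, dataset, design, level=config.ci_level
        )
        frame = estimates_to_frame(estimates, dataset.catalog)
        frame.to_csv(outdir / "estimates.csv", index=False)

        stage = "filter"
        decisions = {
            outcome: min_improvement_filter(estimates, outcome, tau=config.tau)
            for outcome in OUTCOMES
        }
        for outcome, dec in decisions.items():
            manifest[f"n_retained_{outcome}"] = sum(d.retained for d in dec)
        ranked = top_k_union(decisions, estimates, dataset.catalog, k=config.top_k)
        ranked.to_csv(outdir / "top_burden.csv", index=False)

        stage = "regress"
        union_items = [
            tuple(dataset.catalog.index(n) for n in row.split("|"))
            for row in ranked["items"]
        ]
        ors = batch_adjusted_or(dataset, union_items, spline_df=config.spline_df, design=design)
        ors.to_csv(outdir / "odds_ratios.csv", index=False)
        manifest["n_or_fits"] = int(len(ors))
        manifest["n_or_failures"] = int((ors["reason"] != "").sum())

        if config.sex_subgroups:
            stage = "sex_subgroups"
            for sex in ("male", "female"):
                try:
                    top, _ = sex_subgroup_pipeline(
                        dataset, sex,
                        config.min_unweighted_support, config.min_weighted_total,
                    )
                    top.to_csv(outdir / f"top_prevalence_{sex}.csv", index=False)
                except ValueError as e:
                    manifest[f"subgroup_{sex}_error"] = str(e)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {
        "dataset": dataset,
        "mined": mined,
        "estimates": estimates,
        "estimates_frame": frame,
        "decisions": decisions,
        "top_burden": ranked,
        "odds_ratios": ors,
        "table1": t1,
        "manifest": manifest,
    }


def format_for_display(frame: pd.DataFrame) -> pd.DataFrame:
    """Round report columns to the publication precision: percentages to one
    decimal, dollars to whole units, lifts/ORs to one decimal, population
    counts in millions to one decimal."""
    out = frame.copy()
    for col in out.columns:
        if col.endswith("pct") or "pct_" in col:
            out[col] = out[col].astype(float).round(1)
        elif col.startswith(("mean_", "median_", "exp_", "oop_")) or col.endswith("_exp"):
            out[col] = out[col].astype(float).round(0)
        elif "lift" in col or col.startswith("aor"):
            out[col] = out[col].astype(float).round(1)
        elif col.startswith("weighted_n"):
            out[col] = (out[col].astype(float) / 1e6).round(1)
            out = out.rename(columns={col: col.replace("weighted_n", "weighted_n_millions")})
    return out
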