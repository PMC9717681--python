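"""Redundancy filtering and burden rankings of combinations.

A larger combination is only worth reporting for an outcome (mean expenditure
or poor-health share) if it adds information over every more parsimonious
combination it extends — its population is a subset of each immediate
sub-combination's population, so the sub-combination is the more parsimonious
description. The minimum-improvement rule keeps a combination only when its
outcome statistic exceeds each immediate frequent parent's by at least a
relative margin tau (default 10%); dyads are compared against their single
conditions. Improvement is one-sided (only a higher burden counts) and uses
point estimates, with strictly positive improvement required, so tau = 0
keeps exactly the strict improvers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .estimators import ItemsetEstimate, design_of, estimate_itemsets, estimates_to_frame
from .mining import Itemset, mine_frequent_itemsets

log = logging.getLogger(__name__)

OUTCOMES = ("mean_exp", "poor_health_pct")


def _outcome_stat(est: ItemsetEstimate, outcome: str) -> float | None:
    if outcome == "mean_exp":
        return est.mean_exp.point if est.mean_exp else None
    if outcome == "poor_health_pct":
        return 100 * est.poor_health.point if est.poor_health else None
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


@dataclass(frozen=True)
class FilterDecision:
    itemset: Itemset
    outcome: str
    retained: bool
    best_parent: Itemset | None   # parent with the largest outcome statistic
    improvement: float | None     # (stat_X - stat_best_parent)/stat_best_parent


def min_improvement_filter(
    estimates: list[ItemsetEstimate],
    outcome: str,
    tau: float = 0.10,
) -> list[FilterDecision]:
    """Apply the minimum-improvement rule to every size >= 2 combination.

    ``estimates`` must include the singleton records (the miner keeps them
    for exactly this purpose). A combination is retained iff its outcome
    statistic improves on EVERY immediate frequent parent by >= tau
    relatively, with strictly positive improvement. Parents with a missing
    outcome statistic are skipped with a warning. Purely a membership
    decision: no estimate is altered, and re-filtering a filtered set is
    idempotent.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    by_itemset = {e.itemset: e for e in estimates}
    decisions: list[FilterDecision] = []
    for e in estimates:
        X = e.itemset
        if len(X) < 2:
            continue
        stat = _outcome_stat(e, outcome)
        if stat is None:
            decisions.append(FilterDecision(X, outcome, False, None, None))
            continue
        parent_stats: list[tuple[Itemset, float]] = []
        for sub in combinations(X, len(X) - 1):
            parent = by_itemset.get(sub)
            if parent is None:
                continue  # parent not frequent: imposes no constraint
            ps = _outcome_stat(parent, outcome)
            if ps is None:
                log.warning("parent %s lacks %s; skipped in filter", sub, outcome)
                continue
            parent_stats.append((sub, ps))
        if not parent_stats:
            decisions.append(FilterDecision(X, outcome, True, None, None))
            continue
        best_parent, best_stat = max(parent_stats, key=lambda t: t[1])
        if best_stat <= 0:
            improvement = np.inf if stat > best_stat else 0.0
        else:
            improvement = (stat - best_stat) / best_stat
        retained = improvement > 0 and improvement >= tau
        decisions.append(FilterDecision(X, outcome, retained, best_parent, improvement))
    return decisions


def top_k_union(
    decisions_by_outcome: dict[str, list[FilterDecision]],
    estimates: list[ItemsetEstimate],
    catalog,
    k: int = 20,
) -> pd.DataFrame:
    """Union of the top-k retained combinations per outcome, ranked report.

    Takes the top-k retained combinations by mean expenditure and the top-k
    by poor-health share, flags each member of the union (cost_top,
    health_top, both), and sorts by prevalence descending. If fewer than k
    combinations survive a filter the union is over what exists.
    """
    by_itemset = {e.itemset: e for e in estimates}
    tops: dict[str, list[Itemset]] = {}
    for outcome, decisions in decisions_by_outcome.items():
        retained = [d.itemset for d in decisions if d.retained]
        scored = [
            (it, _outcome_stat(by_itemset[it], outcome))
            for it in retained
            if _outcome_stat(by_itemset[it], outcome) is not None
        ]
        scored.sort(key=lambda t: (-t[1], -by_itemset[t[0]].record.weighted_n, t[0]))
        if len(scored) < k:
            log.info("only %d retained combinations for %s (k=%d)", len(scored), outcome, k)
        tops[outcome] = [it for it, _ in scored[:k]]

    union = sorted(set().union(*tops.values())) if tops else []
    rows = []
    for it in union:
        e = by_itemset[it]
        in_cost = it in tops.get("mean_exp", [])
        in_health = it in tops.get("poor_health_pct", [])
        rows.append(
            {
                "items": "|".join(catalog.names(it)),
                "size": len(it),
                "prevalence_pct": 100 * e.prevalence.point,
                "weighted_n": e.weighted_n.point,
                "mean_exp": e.mean_exp.point if e.mean_exp else np.nan,
                "poor_health_pct": 100 * e.poor_health.point if e.poor_health else np.nan,
                "cost_top": in_cost,
                "health_top": in_health,
                "both": in_cost and in_health,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("prevalence_pct", ascending=False, kind="stable").reset_index(drop=True)
    return out


def sex_subgroup_pipeline(
    ds,
    sex: str,
    min_unweighted_support: float = 0.0020,
    min_weighted_total: float = 1_000_000.0,
    top: int = 10,
):
    """Mine -> estimate within one sex, as domain estimation on the full design.

    Weights are kept and non-members are simply excluded from numerators and
    domain denominators, so point estimates equal a run on a physically
    subset file while variances still see the whole design.

    Returns (top-``top``-by-prevalence DataFrame, all subgroup estimates).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    domain = (ds.table["sex"] == sex).to_numpy()
    if not domain.any():
        raise ValueError(f"empty subgroup: no {sex} respondents")
    design = design_of(ds)
    result = mine_frequent_itemsets(
        ds, min_unweighted_support, min_weighted_total, domain=domain
    )
    estimates = estimate_itemsets(result.frequent, ds, design, domain=domain)
    frame = estimates_to_frame(estimates, ds.catalog)
    frame = frame.sort_values(
        ["prevalence_pct", "items"], ascending=[False, True], kind="stable"
    ).head(top).reset_index(drop=True)
    return frame, estimates


def exclude_conditions_variant(ds, drop_names):
    """Clear the named condition bits everywhere (e.g. the analysis variant
    without hypertension and hyperlipidemia); the catalog itself is unchanged
    so bit positions stay stable."""
    drop_mask = ds.catalog.mask(drop_names)  # raises on unknown names
    if drop_mask == 0:
        return ds
    t = ds.table.copy()
    t["cond_mask"] = t["cond_mask"].to_numpy(dtype=np.int64) & ~drop_mask
    return ds.with_table(t)
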