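"""Weighted frequent-itemset mining over condition vectors (Apriori).

Each person is a transaction and each of the 20 chronic conditions an item;
a combination's support is the fraction of persons whose condition vector
contains ALL its items — "at least", not "exactly", so a person treated for
hypertension, hyperlipidemia and diabetes counts toward hypertension +
diabetes as well.

The study's two-stage threshold is mirrored exactly: an initial pass keeps
combinations with unweighted support >= 0.20%, then combinations whose
survey-weighted count falls below one million persons are dropped. Both
criteria are anti-monotone (a superset can never out-support a subset), so
level-wise candidate generation with downward-closure pruning on the
unweighted criterion plus a weighted post-filter enumerates exactly the same
set as brute force.

Condition vectors are stored as 20-bit integers; support counting is a
vectorized bitwise-containment test, so the full 2^20 search space never
needs materializing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .catalog import N_CONDITIONS

Itemset = tuple[int, ...]


def itemset_mask(itemset: Itemset) -> int:
    """Bitmask of an itemset (tuple of strictly increasing condition indices)."""
    m = 0
    for c in itemset:
        m |= 1 << c
    return m


def search_space_size(n_items: int = N_CONDITIONS) -> int:
    """Number of subsets of n items the miner's search space spans (2^n)."""
    return 1 << n_items


@dataclass(frozen=True)
class SupportRecord:
    """Support of one combination: unweighted and survey-weighted."""

    itemset: Itemset
    n: int                 # unweighted count of holders
    support: float         # n / sample size
    weighted_n: float      # sum of analysis weights over holders (persons)
    prevalence: float      # weighted_n / total weight

    def __post_init__(self) -> None:
        if len(self.itemset) < 1:
            raise ValueError("itemset must be non-empty")
        if any(b <= a for a, b in zip(self.itemset, self.itemset[1:])):
            raise ValueError(f"itemset indices must be strictly increasing: {self.itemset}")


def weighted_support(itemset: Itemset, ds, domain=None) -> SupportRecord:
    """Unweighted and weighted support of one combination.

    A person counts iff their condition vector contains every item (bitwise
    superset). ``domain`` restricts both numerator and denominator to a
    subgroup without touching the design.
    """
    if len(itemset) == 0:
        raise ValueError("itemset must be non-empty")
    w = ds.weights
    member = ds.holds_mask(itemset_mask(itemset))
    if domain is not None:
        d = np.asarray(domain, dtype=bool)
        member = member & d
        n_base = int(d.sum())
        w_base = float(w[d].sum())
    else:
        n_base = ds.n
        w_base = float(w.sum())
    n_x = int(member.sum())
    wn = float(w[member].sum())
    return SupportRecord(
        itemset=tuple(itemset),
        n=n_x,
        support=n_x / n_base if n_base else 0.0,
        weighted_n=wn,
        prevalence=wn / w_base if w_base else 0.0,
    )


@dataclass
class MiningResult:
    """Frequent combinations (size >= 2) plus the flagged singleton records."""

    frequent: list[SupportRecord]
    singletons: list[SupportRecord]  # all 20 marginals, kept for lift/filtering
    min_unweighted_support: float
    min_weighted_total: float

    def by_size(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.frequent:
            out[len(r.itemset)] = out.get(len(r.itemset), 0) + 1
        return out


def _sort_records(records: list[SupportRecord]) -> list[SupportRecord]:
    # deterministic order: size, then larger weighted N, then lexicographic
    return sorted(records, key=lambda r: (len(r.itemset), -r.weighted_n, r.itemset))


def mine_frequent_itemsets(
    ds,
    min_unweighted_support: float = 0.0020,
    min_weighted_total: float = 1_000_000.0,
    max_size: int = N_CONDITIONS,
    domain=None,
) -> MiningResult:
    """Enumerate every combination passing the two-stage support thresholds.

    Level-wise (Apriori) search: size-(k+1) candidates are joined from
    frequent size-k sets and pruned by downward closure on the unweighted
    support criterion; the weighted >= ``min_weighted_total`` cut is applied
    as a post-filter. Returns all size >= 2 survivors plus all 20 singleton
    marginal records (flagged separately; these always bypass the thresholds
    because lift and improvement filtering need them).

    Combinations never observed in the sample (support exactly zero) are
    never reported, even at a zero threshold: their support is not estimable
    and admitting them would expand the output to the full powerset of
    unobserved conditions. This strengthens, and so preserves, downward
    closure.
    """
    if min_unweighted_support < 0 or min_weighted_total < 0:
        raise ValueError("thresholds must be non-negative")
    masks = ds.cond_masks
    w = ds.weights
    if domain is not None:
        d = np.asarray(domain, dtype=bool)
        masks = masks[d]
        w = w[d]
    n = len(masks)
    w_total = float(w.sum())
    if n == 0:
        raise ValueError("empty mining domain")

    def record(itemset: Itemset) -> SupportRecord:
        m = itemset_mask(itemset)
        member = (masks & m) == m
        n_x = int(member.sum())
        wn = float(w[member].sum())
        return SupportRecord(itemset, n_x, n_x / n, wn, wn / w_total if w_total else 0.0)

    singletons = [record((c,)) for c in range(N_CONDITIONS)]
    # initial pass: unweighted support threshold (observed at least once)
    frontier = {
        r.itemset: r
        for r in singletons
        if r.n > 0 and r.support >= min_unweighted_support
    }
    passed: list[SupportRecord] = []
    level = 1
    while frontier and level < max_size:
        keys = sorted(frontier)
        candidates = set()
        for a, b in combinations(keys, 2):
            if a[:-1] == b[:-1]:  # join on shared (k-1)-prefix
                cand = a + (b[-1],)
                # downward closure: every size-k subset must be frequent
                if all(cand[:i] + cand[i + 1:] in frontier for i in range(len(cand))):
                    candidates.add(cand)
        next_frontier: dict[Itemset, SupportRecord] = {}
        for cand in sorted(candidates):
            r = record(cand)
            if r.n > 0 and r.support >= min_unweighted_support:
                next_frontier[cand] = r
        passed.extend(next_frontier.values())
        frontier = next_frontier
        level += 1

    frequent = [r for r in passed if r.weighted_n >= min_weighted_total]
    return MiningResult(
        frequent=_sort_records(frequent),
        singletons=singletons,
        min_unweighted_support=min_unweighted_support,
        min_weighted_total=min_weighted_total,
    )


def brute_force_itemsets(
    ds,
    min_unweighted_support: float = 0.0,
    min_weighted_total: float = 0.0,
    max_size: int = N_CONDITIONS,
    items=None,
    domain=None,
) -> list[SupportRecord]:
    """Exhaustive enumeration oracle (use only for small item universes)."""
    items = list(range(N_CONDITIONS)) if items is None else list(items)
    out = []
    for k in range(2, min(max_size, len(items)) + 1):
        for comb in combinations(items, k):
            r = weighted_support(comb, ds, domain=domain)
            if (
                r.n > 0
                and r.support >= min_unweighted_support
                and r.weighted_n >= min_weighted_total
            ):
                out.append(r)
    return _sort_records(out)


def condition_count_bands(ds, by: str | None = None) -> pd.DataFrame:
    """Weighted percentage of persons with 0, 1+, 2+, 3+, 4+ conditions.

    Bands are cumulative ("2+" contains "3+"). ``by`` names a grouping column
    of the dataset table (e.g. ``sex``); ``None`` gives the overall row.
    Returns one row per group with the unweighted n, weighted N and the five
    row percentages.
    """
    t = ds.table
    counts = ds.condition_counts
    w = ds.weights
    groups = [("total", np.ones(ds.n, dtype=bool))]
    if by is not None:
        for val in pd.unique(t[by]):
            groups.append((val, (t[by] == val).to_numpy()))
        groups = groups[1:]
    rows = []
    for name, sel in groups:
        wsel = w[sel]
        tot = wsel.sum()
        row = {"group": name, "n_unweighted": int(sel.sum()), "weighted_n": float(tot)}
        row["pct_0"] = 100 * float(wsel[counts[sel] == 0].sum()) / tot if tot else np.nan
        for b in (1, 2, 3, 4):
            row[f"pct_{b}plus"] = (
                100 * float(wsel[counts[sel] >= b].sum()) / tot if tot else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
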