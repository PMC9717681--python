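"""Minimum-improvement filtering, burden rankings, subgroup and variant runs."""

import numpy as np
import pytest

from morbmine import (
    exclude_conditions_variant,
    min_improvement_filter,
    mine_frequent_itemsets,
    sex_subgroup_pipeline,
    top_k_union,
)
from morbmine.catalog import CatalogError, default_catalog
from morbmine.estimators import (
    ItemsetEstimate,
    LinearizedEstimate,
    design_of,
    estimate_itemsets,
)
from morbmine.mining import SupportRecord


def _lin(x: float) -> LinearizedEstimate:
    return LinearizedEstimate(x, 0.0, x, x, 2, "mean")


def make_estimate(itemset, mean_exp, poor_pct=50.0, weighted_n=1e6, prevalence=0.1) -> ItemsetEstimate:
    """Minimal estimate bundle with prescribed outcome statistics."""
    rec = SupportRecord(tuple(itemset), 10, 0.1, weighted_n, prevalence)
    return ItemsetEstimate(
        record=rec,
        prevalence=_lin(prevalence),
        weighted_n=_lin(weighted_n),
        lift=_lin(2.0) if len(itemset) >= 2 else None,
        mean_exp=_lin(mean_exp),
        mean_oop=_lin(mean_exp / 10),
        median_exp=mean_exp,
        iqr_exp=(mean_exp / 2, mean_exp * 2),
        poor_health=_lin(poor_pct / 100),
    )


@pytest.fixture
def hand_estimates():
    """Singles A,B,C; dyads; and a triad whose cost equals its best dyad."""
    return [
        make_estimate((0,), 1000.0),
        make_estimate((1,), 2000.0),
        make_estimate((2,), 1500.0),
        make_estimate((0, 1), 2400.0),   # 20% over best single (B: 2000)
        make_estimate((0, 2), 1500.0),   # ties best single C -> dropped
        make_estimate((1, 2), 2100.0),   # 5% over B -> dropped at tau=0.10
        make_estimate((0, 1, 2), 2400.0),  # equals best dyad -> dropped
    ]


class TestMinImprovementFilter:
    def test_hand_fixture_at_default_tau(self, hand_estimates):
        decisions = {d.itemset: d for d in min_improvement_filter(hand_estimates, "mean_exp")}
        assert decisions[(0, 1)].retained
        assert decisions[(0, 1)].improvement == pytest.approx(0.20)
        assert not decisions[(0, 2)].retained    # zero improvement
        assert not decisions[(1, 2)].retained    # 5% < 10%
        assert not decisions[(0, 1, 2)].retained
        assert decisions[(0, 1, 2)].best_parent == (0, 1)

    def test_triad_twenty_percent_over_dyads_retained(self):
        ests = [
            make_estimate((0,), 100.0),
            make_estimate((1,), 100.0),
            make_estimate((2,), 100.0),
            make_estimate((0, 1), 500.0),
            make_estimate((0, 2), 400.0),
            make_estimate((1, 2), 300.0),
            make_estimate((0, 1, 2), 600.0),  # 1.2 x max(dyads)
        ]
        decisions = {d.itemset: d for d in min_improvement_filter(ests, "mean_exp")}
        assert decisions[(0, 1, 2)].retained
        assert decisions[(0, 1, 2)].improvement == pytest.approx(0.20)

    def test_tau_zero_keeps_only_strict_improvers(self, hand_estimates):
        decisions = {d.itemset: d for d in min_improvement_filter(hand_estimates, "mean_exp", tau=0.0)}
        assert decisions[(1, 2)].retained        # any positive improvement
        assert not decisions[(0, 2)].retained    # equality is not improvement
        assert not decisions[(0, 1, 2)].retained

    def test_tau_huge_drops_everything_with_parents(self, hand_estimates):
        decisions = min_improvement_filter(hand_estimates, "mean_exp", tau=1e9)
        assert not any(d.retained for d in decisions)

    def test_monotone_in_tau(self, hand_estimates):
        taus = [0.0, 0.05, 0.10, 0.20, 0.50, 2.0]
        kept = [
            {d.itemset for d in min_improvement_filter(hand_estimates, "mean_exp", tau=t) if d.retained}
            for t in taus
        ]
        for bigger, smaller in zip(kept, kept[1:]):
            assert smaller <= bigger

    def test_membership_only_and_idempotent(self, hand_estimates):
        first = min_improvement_filter(hand_estimates, "mean_exp")
        again = min_improvement_filter(hand_estimates, "mean_exp")
        assert first == again
        # inputs untouched
        assert hand_estimates[3].mean_exp.point == 2400.0


class TestTopKUnion:
    def _decisions(self, itemsets):
        from morbmine.filtering import FilterDecision

        return [FilterDecision(it, "x", True, None, None) for it in itemsets]

    def test_identical_rankings_flag_both(self):
        ests = [make_estimate((0, i), 1000.0 * i, poor_pct=min(i * 10.0, 99.0)) for i in range(1, 6)]
        sets = [e.itemset for e in ests]
        dec = {"mean_exp": self._decisions(sets), "poor_health_pct": self._decisions(sets)}
        out = top_k_union(dec, ests, default_catalog(), k=5)
        assert len(out) == 5
        assert out["both"].all()

    def test_disjoint_rankings_union_2k(self):
        cost = [make_estimate((0, i), 5000.0 + i, poor_pct=1.0) for i in range(1, 4)]
        health = [make_estimate((1, i), 10.0, poor_pct=80.0 + i) for i in range(2, 5)]
        dec = {
            "mean_exp": self._decisions([e.itemset for e in cost]),
            "poor_health_pct": self._decisions([e.itemset for e in health]),
        }
        out = top_k_union(dec, cost + health, default_catalog(), k=3)
        assert len(out) == 6
        assert not out["both"].any()

    def test_sorted_by_prevalence_descending(self):
        ests = [
            make_estimate((0, 1), 100.0, weighted_n=5e6, prevalence=0.05),
            make_estimate((0, 2), 200.0, weighted_n=9e6, prevalence=0.09),
            make_estimate((1, 2), 150.0, weighted_n=7e6, prevalence=0.07),
        ]
        dec = {"mean_exp": self._decisions([e.itemset for e in ests]), "poor_health_pct": []}
        out = top_k_union(dec, ests, default_catalog(), k=3)
        assert list(out["prevalence_pct"]) == sorted(out["prevalence_pct"], reverse=True)


class TestSexSubgroup:
    def test_single_sex_dataset_errors_on_other(self, small_mining):
        ds, _ = small_mining
        females_only = ds.with_table(ds.table[ds.table["sex"] == "female"])
        with pytest.raises(ValueError, match="male"):
            sex_subgroup_pipeline(females_only, "male")

    def test_domain_point_estimates_match_physical_subset(self, small_mining):
        """Domain estimation on the full design vs a physically subset file:
        point estimates must agree exactly (SEs may differ)."""
        ds, _ = small_mining
        top_domain, est_domain = sex_subgroup_pipeline(ds, "female", 0.0, 0.0)
        subset = ds.with_table(ds.table[ds.table["sex"] == "female"])
        mined = mine_frequent_itemsets(subset, 0.0, 0.0)
        est_subset = estimate_itemsets(mined.frequent, subset)
        by_set_dom = {e.itemset: e for e in est_domain}
        by_set_sub = {e.itemset: e for e in est_subset}
        assert set(by_set_dom) == set(by_set_sub)
        for it, e_dom in by_set_dom.items():
            e_sub = by_set_sub[it]
            assert e_dom.prevalence.point == pytest.approx(e_sub.prevalence.point, rel=1e-12)
            assert e_dom.weighted_n.point == pytest.approx(e_sub.weighted_n.point, rel=1e-12)
            if e_dom.lift:
                assert e_dom.lift.point == pytest.approx(e_sub.lift.point, rel=1e-12)
            assert e_dom.mean_exp.point == pytest.approx(e_sub.mean_exp.point, rel=1e-12)


class TestExcludeVariant:
    def test_empty_drop_is_identity(self, small_mining):
        ds, _ = small_mining
        assert exclude_conditions_variant(ds, []) is ds

    def test_dropped_condition_never_mined(self, small_mining):
        ds, _ = small_mining
        cat = ds.catalog
        variant = exclude_conditions_variant(ds, ["hypertension"])
        idx = cat.index("hypertension")
        res = mine_frequent_itemsets(variant, 0.0, 0.0)
        assert all(idx not in r.itemset for r in res.frequent)

    def test_drop_all_leaves_nothing(self, small_mining):
        ds, _ = small_mining
        variant = exclude_conditions_variant(ds, list(ds.catalog.categories))
        assert (variant.cond_masks == 0).all()
        assert mine_frequent_itemsets(variant, 0.0, 0.0).frequent == []

    def test_unknown_name_rejected(self, small_mining):
        ds, _ = small_mining
        with pytest.raises(CatalogError):
            exclude_conditions_variant(ds, ["gout"])
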