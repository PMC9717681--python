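"""Taylor-linearization estimators: hand checks, closed forms, invariances."""

import numpy as np
import pytest

from morbmine import (
    domain_mean,
    estimate_lift,
    estimate_proportion,
    estimate_total,
    taylor_variance,
    weighted_quantile,
)
from morbmine.estimators import DesignError, design_of, estimate_itemset

from conftest import random_dataset


class TestTaylorVariance:
    def test_tiny_hand_computation(self, tiny):
        """Influences of the prevalence-of-A estimator, aggregated by hand.

        p_A = 0.3; PSU influence totals are (0.105, 0.045) in stratum 1 and
        (-0.045, -0.105) in stratum 2, giving 2*(2*0.03^2) per stratum and a
        total variance of 0.0072.
        """
        w = tiny.base_weights
        y = tiny.holds_mask(1 << 0).astype(float)
        z = w * (y - 0.3) / w.sum()
        var = taylor_variance(z, tiny.strata, tiny.psus)
        assert var == pytest.approx(0.0072)

    def test_equal_psu_totals_give_zero_variance(self):
        strata = np.array([0, 0, 0, 0])
        psus = np.array([0, 0, 1, 1])
        z = np.array([1.0, 2.0, 2.5, 0.5])  # PSU totals both 3.0
        assert taylor_variance(z, strata, psus) == pytest.approx(0.0)

    def test_matches_with_replacement_srs_closed_form(self):
        """Each person their own PSU, one stratum: (n/(n-1)) * sum (z-zbar)^2."""
        rng = np.random.default_rng(5)
        z = rng.normal(size=57)
        n = len(z)
        var = taylor_variance(z, np.zeros(n, dtype=int), np.arange(n))
        expected = n / (n - 1) * np.sum((z - z.mean()) ** 2)
        assert var == pytest.approx(expected, rel=1e-12)

    def test_single_psu_stratum_is_named(self):
        with pytest.raises(DesignError, match="lonely"):
            taylor_variance(np.ones(3), np.array(["a", "a", "lonely"]), np.array([0, 1, 2]))

    def test_single_psu_collapse_option(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        var = taylor_variance(
            z, np.array(["a", "a", "b", "c"]), np.array([0, 1, 2, 3]),
            single_psu="collapse",
        )
        assert var > 0


class TestProportion:
    def test_constant_indicator(self, tiny):
        est = estimate_proportion(np.ones(tiny.n), tiny)
        assert est.point == 1.0
        assert est.se == pytest.approx(0.0)
        assert est.lo <= est.point <= est.hi <= 1.0

    def test_tiny_hand_values(self, tiny):
        est = estimate_proportion(tiny.holds_mask(1 << 0).astype(float), tiny)
        assert est.point == pytest.approx(0.3)
        assert est.se == pytest.approx(np.sqrt(0.0072))
        t_crit = 4.302652729911275  # t_{2, 0.975}: df = 4 PSUs - 2 strata
        assert est.df == 2
        assert est.hi == pytest.approx(0.3 + t_crit * est.se)
        assert est.lo == pytest.approx(0.0)  # truncated at 0

    def test_zero_total_weight_errors(self, srs_dataset):
        ds = srs_dataset(np.array([0, 1, 0]))
        with pytest.raises(DesignError):
            estimate_proportion(np.ones(3), ds, domain=np.zeros(3))


class TestLift:
    def test_independence_point_gives_one(self, srs_dataset):
        # persons: A only, B only, A+B, neither -> p_A = p_B = 1/2, p_AB = 1/4
        ds = srs_dataset(np.array([0b01, 0b10, 0b11, 0b00]))
        est = estimate_lift((0, 1), ds)
        assert est.point == pytest.approx(1.0)

    def test_tiny_hand_ratio(self, tiny):
        # lift(B,C) = 0.35 / (0.5 * 0.6) = 7/6
        est = estimate_lift((1, 2), tiny)
        assert est.point == pytest.approx(7 / 6)
        assert est.lo < est.point < est.hi
        # asymmetric on the raw scale: built on the log scale
        assert est.hi - est.point > est.point - est.lo

    def test_zero_marginal_is_undefined(self, tiny):
        with pytest.raises(DesignError):
            estimate_lift((3, 4), tiny)  # conditions nobody holds

    def test_requires_size_two(self, tiny):
        with pytest.raises(ValueError):
            estimate_lift((0,), tiny)


class TestDomainMean:
    def test_full_domain_constant(self, tiny):
        est = domain_mean(np.full(tiny.n, 42.0), np.ones(tiny.n), tiny)
        assert est.point == pytest.approx(42.0)
        assert est.se == pytest.approx(0.0)

    def test_tiny_hand_value(self, tiny):
        # expenditure mean over holders of A (persons 1,2,3; weights 1,2,3):
        # (1*100 + 2*200 + 3*300) / 6 = 1400/6
        d = tiny.holds_mask(1 << 0).astype(float)
        est = domain_mean(tiny.table["total_exp"].to_numpy(), d, tiny)
        assert est.point == pytest.approx(1400 / 6)

    def test_empty_domain_returns_marker(self, tiny):
        assert domain_mean(np.ones(tiny.n), np.zeros(tiny.n), tiny) is None

    def test_agrees_with_proportion_on_full_sample(self, small_mining):
        ds, _ = small_mining
        y = ds.holds_mask(1 << 1).astype(float)
        a = estimate_proportion(y, ds)
        b = domain_mean(y, np.ones(ds.n), ds)
        assert a.point == pytest.approx(b.point, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestWeightedQuantile:
    def test_examples(self):
        assert weighted_quantile([1, 2, 3, 4, 5], np.ones(5), 0.5) == 3
        assert weighted_quantile([0, 10], [1, 9], 0.5) == 10
        assert weighted_quantile([0, 10], [9, 1], 0.5) == 0

    def test_quartiles_never_inverted(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            v = rng.normal(size=30)
            w = rng.uniform(0.1, 5.0, size=30)
            q25 = weighted_quantile(v, w, 0.25)
            q50 = weighted_quantile(v, w, 0.5)
            q75 = weighted_quantile(v, w, 0.75)
            assert q25 <= q50 <= q75

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_quantile([1.0], [1.0], 0.0)
        with pytest.raises(ValueError):
            weighted_quantile([1.0, 2.0], [0.0, 0.0], 0.5)


class TestScaleInvariance:
    def test_weight_rescaling(self):
        """x7 weights: proportions, lifts, means, quantiles and SEs fixed;
        totals scale by 7."""
        ds = random_dataset(21, n_conditions=5, n=200)
        scaled = ds.with_table(ds.table.assign(weight=ds.table["weight"] * 7))
        y = ds.holds_mask(1 << 0).astype(float)
        v = ds.table["total_exp"].to_numpy()

        p1, p2 = estimate_proportion(y, ds), estimate_proportion(y, scaled)
        assert p2.point == pytest.approx(p1.point, rel=1e-12)
        assert p2.se == pytest.approx(p1.se, rel=1e-12)

        l1, l2 = estimate_lift((0, 1), ds), estimate_lift((0, 1), scaled)
        assert l2.point == pytest.approx(l1.point, rel=1e-12)
        assert l2.se == pytest.approx(l1.se, rel=1e-12)

        m1 = domain_mean(v, y, ds)
        m2 = domain_mean(v, y, scaled)
        assert m2.point == pytest.approx(m1.point, rel=1e-12)
        assert m2.se == pytest.approx(m1.se, rel=1e-12)

        assert weighted_quantile(v, scaled.weights, 0.5) == weighted_quantile(v, ds.weights, 0.5)

        t1, t2 = estimate_total(y, ds), estimate_total(y, scaled)
        assert t2.point == pytest.approx(7 * t1.point, rel=1e-12)
        assert t2.se == pytest.approx(7 * t1.se, rel=1e-12)


def test_itemset_estimate_bundle_consistency(small_mining):
    ds, _ = small_mining
    est = estimate_itemset((0, 1), ds)
    assert est.lift is not None and est.lift.point > 0
    q25, q75 = est.iqr_exp
    assert q25 <= est.median_exp <= q75
    total_w = ds.weights.sum()
    assert est.prevalence.point == pytest.approx(est.weighted_n.point / total_w)
    assert 0 <= est.poor_health.point <= 1
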