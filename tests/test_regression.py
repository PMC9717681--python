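"""Survey-weighted logistic regression and the age spline basis."""

import numpy as np
import pytest
import statsmodels.api as sm

from morbmine import batch_adjusted_or, fit_survey_logistic, spline_basis
from morbmine.dataset import SurveyDataset
from morbmine.regression import ConvergenceError, ModelSpec, RankError, build_design_matrix

from conftest import random_dataset


class TestSplineBasis:
    def test_linear_function_in_span(self):
        ages = np.linspace(18, 90, 200)
        basis, _ = spline_basis(ages, df=2)
        design = np.column_stack([np.ones_like(ages), basis])
        target = 3.0 + 0.5 * ages
        coef, res, *_ = np.linalg.lstsq(design, target, rcond=None)
        fitted = design @ coef
        np.testing.assert_allclose(fitted, target, rtol=1e-8)

    def test_second_derivative_continuous_at_knots(self):
        ages = np.linspace(18, 90, 500)
        basis, info = spline_basis(ages, df=4)
        h = 1e-4
        for knot in info["knots"]:
            for j in range(basis.shape[1]):
                def f(x):
                    b, _ = spline_basis(
                        np.array([x]), df=4, knots=info["knots"], boundary=info["boundary"]
                    )
                    return b[0, j]
                d2_left = (f(knot - 2 * h) - 2 * f(knot - h) + f(knot)) / h**2
                d2_right = (f(knot) - 2 * f(knot + h) + f(knot + 2 * h)) / h**2
                assert d2_left == pytest.approx(d2_right, abs=2e-2)

    def test_natural_linearity_beyond_boundaries(self):
        ages = np.linspace(18, 90, 300)
        _, info = spline_basis(ages, df=4)
        # second differences vanish outside the boundary knots
        xs = np.array([95.0, 100.0, 105.0])
        b, _ = spline_basis(xs, df=4, knots=info["knots"], boundary=info["boundary"])
        second_diff = b[2] - 2 * b[1] + b[0]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-8)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(RankError):
            spline_basis(np.full(10, 50.0), df=4)
        with pytest.raises(ValueError):
            spline_basis(np.linspace(18, 90, 10), df=1)

    def test_reproducible_from_returned_knots(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 90, 100)
        b1, info = spline_basis(ages, df=4)
        b2, _ = spline_basis(ages, df=4, knots=info["knots"], boundary=info["boundary"])
        np.testing.assert_array_equal(b1, b2)


class TestSurveyLogistic:
    def test_matches_ml_under_trivial_design(self):
        """Equal weights, one stratum, each person their own PSU: coefficients
        equal the ordinary maximum-likelihood logistic fit to <= 1e-6."""
        ds = random_dataset(7, n_conditions=4, n=600)
        t = ds.table.assign(weight=1.0, stratum=0, psu=np.arange(ds.n))
        ds = ds.with_table(t)
        spec = ModelSpec(exposure=(0, 1))
        fit = fit_survey_logistic(ds, spec)
        X, _, _ = build_design_matrix(ds, spec)
        ml = sm.GLM(
            ds.table["poor_health"].astype(float), X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.beta, ml.params.to_numpy(), atol=1e-6)

    def test_weight_scale_invariance(self):
        ds = random_dataset(8, n_conditions=4, n=500)
        scaled = ds.with_table(ds.table.assign(weight=ds.table["weight"] * 13.7))
        spec = ModelSpec(exposure=(0,))
        f1, f2 = fit_survey_logistic(ds, spec), fit_survey_logistic(scaled, spec)
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-8)
        np.testing.assert_allclose(np.diag(f1.cov), np.diag(f2.cov), rtol=1e-8)

    def test_flipping_outcome_negates_coefficients(self):
        ds = random_dataset(9, n_conditions=4, n=500)
        spec = ModelSpec(exposure=(1,))
        f1 = fit_survey_logistic(ds, spec)
        flipped = ds.with_table(
            ds.table.assign(
                poor_health=~ds.table["poor_health"],
                srh=6 - ds.table["srh"],  # keep srh <-> poor_health consistent
            )
        )
        f2 = fit_survey_logistic(flipped, spec)
        np.testing.assert_allclose(f1.beta, -f2.beta, atol=1e-7)

    def test_declustering_changes_ses_not_betas(self):
        ds = random_dataset(10, n_conditions=4, n=500)
        spec = ModelSpec(exposure=(0,))
        f1 = fit_survey_logistic(ds, spec)
        ds2 = ds.with_table(ds.table.assign(stratum=0, psu=np.arange(ds.n)))
        f2 = fit_survey_logistic(ds2, spec)
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-10)

    def test_separation_detected(self, srs_dataset):
        rng = np.random.default_rng(2)
        n = 200
        ds = srs_dataset(np.where(np.arange(n) < 100, 1, 0))
        t = ds.table.assign(
            poor_health=np.arange(n) < 100,  # outcome == exposure: separated
            srh=np.where(np.arange(n) < 100, 5, 1),
            age=rng.uniform(18, 90, n),
        )
        ds = ds.with_table(t)
        with pytest.raises((ConvergenceError, RankError)):
            fit_survey_logistic(ds, ModelSpec(exposure=(0,)))

    def test_requires_both_outcome_classes(self, srs_dataset):
        ds = srs_dataset(np.array([1, 0, 1, 0]))
        with pytest.raises(ValueError):
            fit_survey_logistic(ds, ModelSpec(exposure=(0,)))


class TestBatch:
    def test_degenerate_exposure_reported_not_fatal(self):
        ds = random_dataset(12, n_conditions=3, n=400)
        t = ds.table.copy()
        t["cond_mask"] = t["cond_mask"] | 1  # everyone holds condition 0
        ds = ds.with_table(t)
        out = batch_adjusted_or(ds, [(0,), (1, 2)])
        assert len(out) == 2
        assert out.loc[0, "reason"] != "" and np.isnan(out.loc[0, "aor"])
        assert out.loc[1, "reason"] == "" and np.isfinite(out.loc[1, "aor"])

    def test_rows_in_input_order(self):
        ds = random_dataset(13, n_conditions=5, n=400)
        itemsets = [(0,), (1,), (0, 1), (2, 3), (4,), (1, 2), (0, 3), (2,), (3,), (1, 4)]
        out = batch_adjusted_or(ds, itemsets)
        assert len(out) == 10
        expected = ["|".join(ds.catalog.names(it)) for it in itemsets]
        assert list(out["items"]) == expected
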