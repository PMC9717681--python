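"""Survey-weighted logistic regression with design-based sandwich variances.

Each multimorbidity combination is modelled one at a time: poor perceived
health is regressed on an exposure indicator (holds ALL conditions of the
combination), adjusting for age via a natural cubic spline, race/ethnicity
(five levels, non-Hispanic white reference) and sex (male reference).

Coefficients solve the weighted score equation

    sum_i w_i x_i (y_i - expit(x_i' beta)) = 0

by iteratively reweighted least squares; they are invariant to rescaling the
weights. The covariance is the linearized sandwich A^-1 B A^-1 with
A = sum_i w_i mu_i (1 - mu_i) x_i x_i' and B the stratified between-PSU
(Taylor) covariance of the per-person score contributions, so both the
clustering and the stratification feed the standard errors while leaving the
point estimates untouched. Intervals use t critical values on the design
degrees of freedom, and the exposure's adjusted odds ratio is exp(beta) with
its interval exponentiated from the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import RACE5_LEVELS, SurveyDataset
from .estimators import SurveyDesign, _t_crit, design_of, weighted_quantile
from .mining import Itemset, itemset_mask


class RankError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def spline_basis(
    ages,
    df: int = 4,
    weights=None,
    knots=None,
    boundary: tuple[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Natural cubic spline basis (no intercept column), df columns.

    Interior knots default to equally spaced weighted quantiles of age —
    df-1 of them at fractions i/df — with boundary knots at the observed
    range. The basis is the usual truncated-power natural construction: it is
    linear beyond the boundary knots (second derivative zero there) and has a
    continuous second derivative everywhere. Passing the returned knots back
    in reproduces the basis exactly on new data.
    """
    if df < 2:
        raise ValueError(f"spline df must be >= 2, got {df}")
    x = np.asarray(ages, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if boundary is None:
        boundary = (float(x.min()), float(x.max()))
    if knots is None:
        if np.ptp(x) == 0:
            raise RankError("degenerate age distribution (all values equal)")
        qs = [i / df for i in range(1, df)]
        knots = [weighted_quantile(x, w, q, interpolate=True) for q in qs]
    all_knots = np.unique(np.r_[boundary[0], knots, boundary[1]])
    if len(all_knots) != df + 1:
        raise RankError(f"knots collapse to {len(all_knots)} distinct values; need {df + 1}")

    k = all_knots
    K = len(k)

    def d(j, t):
        return (np.maximum(t - k[j], 0.0) ** 3 - np.maximum(t - k[-1], 0.0) ** 3) / (
            k[-1] - k[j]
        )

    cols = [x]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    basis = np.column_stack(cols)
    return basis, {"knots": [float(v) for v in all_knots[1:-1]], "boundary": boundary}


@dataclass
class ModelSpec:
    """Covariate layout for one exposure fit."""

    exposure: Itemset
    spline_df: int = 4
    race_reference: str = "nh_white"
    knots: list | None = None
    boundary: tuple[float, float] | None = None


@dataclass
class LogisticFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    n: int
    design_df: int
    iterations: int
    converged: bool
    score_norm: float
    or_point: float = field(init=False)
    or_lo: float = field(init=False)
    or_hi: float = field(init=False)

    def __post_init__(self) -> None:
        i = self.names.index("exposure")
        se = float(np.sqrt(self.cov[i, i]))
        t = _t_crit(self.design_df, 0.95)
        self.or_point = float(np.exp(self.beta[i]))
        self.or_lo = float(np.exp(self.beta[i] - t * se))
        self.or_hi = float(np.exp(self.beta[i] + t * se))

    @property
    def log_or_se(self) -> float:
        i = self.names.index("exposure")
        return float(np.sqrt(self.cov[i, i]))


def build_design_matrix(ds: SurveyDataset, spec: ModelSpec):
    """Intercept + exposure + age spline + race dummies + female indicator."""
    t = ds.table
    exposure = ds.holds_mask(itemset_mask(spec.exposure)).astype(float)
    basis, info = spline_basis(
        t["age"].to_numpy(dtype=float),
        df=spec.spline_df,
        weights=ds.weights,
        knots=spec.knots,
        boundary=spec.boundary,
    )
    cols = [np.ones(ds.n), exposure] + [basis[:, j] for j in range(basis.shape[1])]
    names = ["intercept", "exposure"] + [f"age_s{j + 1}" for j in range(basis.shape[1])]
    for level in RACE5_LEVELS:
        if level == spec.race_reference:
            continue
        cols.append((t["race5"] == level).to_numpy(dtype=float))
        names.append(f"race_{level}")
    cols.append((t["sex"] == "female").to_numpy(dtype=float))
    names.append("sex_female")
    return np.column_stack(cols), names, info


def _irls(X, y, w, tol=1e-8, max_iter=25, max_abs_beta=15.0):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankError("singular design matrix")
    beta = np.zeros(p)
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        score = X.T @ (w * (y - mu))
        wt = w * mu * (1 - mu)
        A = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(A, score)
        except np.linalg.LinAlgError as e:
            raise RankError(f"information matrix singular: {e}") from e
        beta = beta + step
        if np.max(np.abs(beta)) > max_abs_beta:
            raise ConvergenceError(
                f"separation suspected: max|beta| = {np.max(np.abs(beta)):.1f} "
                f"after {it} iterations"
            )
        mu_new = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(np.sum(w * (y * np.log(mu_new) + (1 - y) * np.log(1 - mu_new))))
        if np.isfinite(dev_old) and abs(dev_old - dev) <= tol * (abs(dev_old) + 1e-12):
            return beta, it, True, float(np.linalg.norm(score))
        dev_old = dev
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return beta, max_iter, False, float(np.linalg.norm(X.T @ (w * (y - mu))))


def fit_survey_logistic(
    ds: SurveyDataset,
    spec: ModelSpec,
    design: SurveyDesign | None = None,
) -> LogisticFit:
    """Fit one combination-exposure model of poor health; see module docstring."""
    design = design or design_of(ds)
    y = ds.table["poor_health"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one non-case")
    w = ds.weights
    X, names, _ = build_design_matrix(ds, spec)
    beta, iters, converged, score_norm = _irls(X, y, w)
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {iters} iterations (|score| = {score_norm:.3g})"
        )
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    A = X.T @ (X * (w * mu * (1 - mu))[:, None])
    U = X * (w * (y - mu))[:, None]  # per-person score contributions
    B = design.variance(U)
    A_inv = np.linalg.inv(A)
    cov = A_inv @ B @ A_inv
    cov = (cov + cov.T) / 2
    return LogisticFit(
        names=names,
        beta=beta,
        cov=cov,
        n=ds.n,
        design_df=design.df,
        iterations=iters,
        converged=converged,
        score_norm=score_norm,
    )


def batch_adjusted_or(
    ds: SurveyDataset,
    itemsets,
    spline_df: int = 4,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """One adjusted-OR fit per combination, rows in input order.

    Fits that fail (separation, rank deficiency, degenerate exposure) are
    reported with a reason and NaN estimates, never dropped.
    """
    design = design or design_of(ds)
    rows = []
    for it in itemsets:
        it = tuple(it)
        row = {"items": "|".join(ds.catalog.names(it)), "size": len(it)}
        try:
            fit = fit_survey_logistic(ds, ModelSpec(exposure=it, spline_df=spline_df), design)
            row.update(
                aor=fit.or_point, aor_lo=fit.or_lo, aor_hi=fit.or_hi,
                log_or_se=fit.log_or_se, n=fit.n, reason="",
            )
        except (RankError, ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
            row.update(aor=np.nan, aor_lo=np.nan, aor_hi=np.nan,
                       log_or_se=np.nan, n=ds.n, reason=str(e))
        rows.append(row)
    return pd.DataFrame(rows)
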