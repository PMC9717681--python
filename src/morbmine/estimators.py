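"""Design-based (Taylor linearization) estimation for complex-survey data.

All variances follow the standard with-replacement first-stage approximation:
per-person influence values z_i are summed to PSU totals within strata, and

    Var = sum_h  n_h/(n_h - 1) * sum_j (Z_hj - Zbar_h)^2

where n_h is the number of PSUs in stratum h. No finite-population correction
is applied (the public-use-file convention). Confidence intervals are t-based
with design degrees of freedom = (#PSUs - #strata); ratio-type estimands
(lift) get their interval on the log scale and are exponentiated back, which
yields the familiar asymmetric intervals.

Nonlinear estimators are linearized: a proportion p = sum(w y)/sum(w) has
influence z_i = w_i (y_i - p)/sum(w); a domain ratio R = sum(w d v)/sum(w d)
has z_i = w_i d_i (v_i - R)/sum(w d); the log observed-to-expected prevalence
ratio (lift) of a combination X, log L = log p_X - sum_c log p_c, combines the
influences of its component proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurveyDataset
from .mining import Itemset, SupportRecord, itemset_mask


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class LinearizedEstimate:
    """A point estimate with linearized SE and t-based confidence interval."""

    point: float
    se: float
    lo: float
    hi: float
    df: int
    tag: str  # total | proportion | ratio | mean | log-lift

    def __iter__(self):
        yield from (self.point, self.se, self.lo, self.hi)


class SurveyDesign:
    """Precomputed stratum/PSU codes for fast repeated Taylor aggregation."""

    def __init__(self, strata, psus, single_psu: str = "error"):
        strata = np.asarray(strata)
        psus = np.asarray(psus)
        # PSU labels are only meaningful within a stratum: code the pair.
        pair = pd.MultiIndex.from_arrays([strata, psus])
        self.psu_code, uniq = pd.factorize(pair, sort=False)
        psu_stratum = np.asarray([p[0] for p in uniq], dtype=object)
        self.stratum_of_psu, strat_uniq = pd.factorize(psu_stratum, sort=False)
        self.n_psus = len(uniq)
        self.n_strata = len(strat_uniq)
        n_h = np.bincount(self.stratum_of_psu, minlength=self.n_strata)
        if (n_h < 2).any():
            if single_psu == "error":
                bad = [str(strat_uniq[i]) for i in np.flatnonzero(n_h < 2)]
                raise DesignError(
                    f"strata with a single PSU (no variance estimate): {bad[:5]}"
                    " — pass single_psu='collapse' to merge them"
                )
            elif single_psu == "collapse":
                # Merge all singleton strata into one synthetic stratum.
                single = n_h < 2
                remap = np.where(single[self.stratum_of_psu], -1, self.stratum_of_psu)
                _, self.stratum_of_psu = np.unique(remap, return_inverse=True)
                self.n_strata = self.stratum_of_psu.max() + 1
                n_h = np.bincount(self.stratum_of_psu, minlength=self.n_strata)
                if (n_h < 2).any():
                    raise DesignError("collapse left a singleton stratum")
            else:
                raise ValueError(f"unknown single_psu policy {single_psu!r}")
        self._n_h = n_h
        self._factor = (n_h / np.maximum(n_h - 1, 1))  # n_h/(n_h-1) per stratum

    @property
    def df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psus - self.n_strata

    def variance(self, z: np.ndarray):
        """Taylor variance of sum(z) for influence values z (n,) or (n,p).

        Returns a scalar for vector input, a (p,p) covariance for matrix input.
        """
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            psu_tot = np.bincount(self.psu_code, weights=z, minlength=self.n_psus)
            strat_sum = np.bincount(
                self.stratum_of_psu, weights=psu_tot, minlength=self.n_strata
            )
            dev = psu_tot - (strat_sum / self._n_h)[self.stratum_of_psu]
            per_stratum = np.bincount(
                self.stratum_of_psu, weights=dev * dev, minlength=self.n_strata
            )
            return float(np.sum(self._factor * per_stratum))
        p = z.shape[1]
        psu_tot = np.zeros((self.n_psus, p))
        for j in range(p):
            psu_tot[:, j] = np.bincount(
                self.psu_code, weights=z[:, j], minlength=self.n_psus
            )
        cov = np.zeros((p, p))
        for h in range(self.n_strata):
            rows = psu_tot[self.stratum_of_psu == h]
            dev = rows - rows.mean(axis=0)
            cov += self._factor[h] * dev.T @ dev
        return cov


def design_of(ds: SurveyDataset, single_psu: str = "error") -> SurveyDesign:
    return SurveyDesign(ds.strata, ds.psus, single_psu=single_psu)


def taylor_variance(z, strata, psus, single_psu: str = "error"):
    """Taylor (linearization) variance of sum(z) under a stratified PSU design."""
    return SurveyDesign(strata, psus, single_psu=single_psu).variance(z)


def _t_crit(df: int, level: float) -> float:
    return float(stats.t.ppf(0.5 + level / 2, max(df, 1)))


def _ci(point, se, df, level, lo_clip=None, hi_clip=None):
    t = _t_crit(df, level)
    lo, hi = point - t * se, point + t * se
    if lo_clip is not None:
        lo = max(lo, lo_clip)
    if hi_clip is not None:
        hi = min(hi, hi_clip)
    return lo, hi


def estimate_total(
    y, ds: SurveyDataset, design: SurveyDesign | None = None, level: float = 0.95
) -> LinearizedEstimate:
    """Weighted population total of y with linearized CI."""
    design = design or design_of(ds)
    w = ds.weights
    z = w * np.asarray(y, dtype=float)
    total = float(z.sum())
    se = float(np.sqrt(design.variance(z)))
    lo, hi = _ci(total, se, design.df, level)
    return LinearizedEstimate(total, se, lo, hi, design.df, "total")


def estimate_proportion(
    y,
    ds: SurveyDataset,
    design: SurveyDesign | None = None,
    domain=None,
    level: float = 0.95,
) -> LinearizedEstimate:
    """Weighted proportion of a 0/1 indicator, optionally within a domain.

    The domain version is the ratio estimator sum(w d y)/sum(w d) with
    ratio-linearized influences; non-members contribute zero influence, so
    point estimates equal those from a physically subset file.
    """
    design = design or design_of(ds)
    w = ds.weights
    y = np.asarray(y, dtype=float)
    d = np.ones_like(w) if domain is None else np.asarray(domain, dtype=float)
    denom = float(np.sum(w * d))
    if denom <= 0:
        raise DesignError("zero total weight in domain")
    p = float(np.sum(w * d * y) / denom)
    z = w * d * (y - p) / denom
    se = float(np.sqrt(design.variance(z)))
    lo, hi = _ci(p, se, design.df, level, lo_clip=0.0, hi_clip=1.0)
    return LinearizedEstimate(p, se, lo, hi, design.df, "proportion")


def domain_mean(
    values,
    domain,
    ds: SurveyDataset,
    design: SurveyDesign | None = None,
    level: float = 0.95,
) -> LinearizedEstimate | None:
    """Design-based mean of ``values`` among domain members (ratio estimator).

    Returns ``None`` for an empty domain (missing-estimate marker).
    """
    design = design or design_of(ds)
    w = ds.weights
    d = np.asarray(domain, dtype=float)
    denom = float(np.sum(w * d))
    if denom <= 0:
        return None
    v = np.asarray(values, dtype=float)
    r = float(np.sum(w * d * v) / denom)
    z = w * d * (v - r) / denom
    se = float(np.sqrt(design.variance(z)))
    lo, hi = _ci(r, se, design.df, level)
    return LinearizedEstimate(r, se, lo, hi, design.df, "mean")


def estimate_lift(
    itemset: Itemset,
    ds: SurveyDataset,
    design: SurveyDesign | None = None,
    domain=None,
    level: float = 0.95,
) -> LinearizedEstimate:
    """Observed-to-expected prevalence ratio of a condition combination.

    L = p_X / prod_c p_c where p_X is the weighted prevalence of holding all
    conditions in X at once and p_c the marginal prevalence of each component.
    Equals 1 when the components co-occur exactly as often as independence
    predicts. The CI is computed on log L by linearization and exponentiated.
    """
    if len(itemset) < 2:
        raise ValueError("lift requires an itemset of size >= 2")
    design = design or design_of(ds)
    w = ds.weights
    d = np.ones_like(w) if domain is None else np.asarray(domain, dtype=float)
    denom = float(np.sum(w * d))
    if denom <= 0:
        raise DesignError("zero total weight in domain")

    joint = (ds.holds_mask(itemset_mask(itemset)) & (d > 0)).astype(float)
    p_joint = float(np.sum(w * d * joint) / denom)
    margins = []
    for c in itemset:
        ind = (ds.holds_mask(1 << c) & (d > 0)).astype(float)
        margins.append((ind, float(np.sum(w * d * ind) / denom)))
    if p_joint <= 0 or any(p <= 0 for _, p in margins):
        raise DesignError(f"lift undefined: zero prevalence in {itemset}")

    lift = p_joint / np.prod([p for _, p in margins])
    # influence of log L = log p_X - sum_c log p_c
    z = w * d * (joint - p_joint) / (p_joint * denom)
    for ind, p in margins:
        z -= w * d * (ind - p) / (p * denom)
    se_log = float(np.sqrt(design.variance(z)))
    t = _t_crit(design.df, level)
    lo = float(lift * np.exp(-t * se_log))
    hi = float(lift * np.exp(t * se_log))
    return LinearizedEstimate(float(lift), se_log, lo, hi, design.df, "log-lift")


def weighted_quantile(values, weights, q: float, interpolate: bool = False) -> float:
    """Lower weighted quantile: smallest observed value whose cumulative
    weight fraction reaches q.

    No interpolation by default, which makes the estimator invariant to weight
    rescaling and fully deterministic; ``interpolate=True`` switches to linear
    interpolation of the weighted CDF between observed values.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    if not keep.any():
        raise ValueError("no positive weights")
    v, w = v[keep], w[keep]
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    if not interpolate:
        idx = int(np.searchsorted(cum, q, side="left"))
        return float(v[min(idx, len(v) - 1)])
    return float(np.interp(q, cum, v))


def weighted_median_iqr(values, weights) -> tuple[float, float, float]:
    """(median, q25, q75) under the lower weighted quantile rule."""
    return (
        weighted_quantile(values, weights, 0.5),
        weighted_quantile(values, weights, 0.25),
        weighted_quantile(values, weights, 0.75),
    )


# ---------------------------------------------------------------------------
# Per-itemset estimate bundles
# ---------------------------------------------------------------------------

@dataclass
class ItemsetEstimate:
    """Every design-based estimate for one condition combination."""

    record: SupportRecord
    prevalence: LinearizedEstimate          # proportion, 0..1 scale
    weighted_n: LinearizedEstimate          # persons
    lift: LinearizedEstimate | None         # None for singletons
    mean_exp: LinearizedEstimate | None
    mean_oop: LinearizedEstimate | None
    median_exp: float | None
    iqr_exp: tuple[float, float] | None     # (q25, q75)
    poor_health: LinearizedEstimate | None  # proportion among holders

    @property
    def itemset(self) -> Itemset:
        return self.record.itemset


def estimate_itemset(
    itemset: Itemset,
    ds: SurveyDataset,
    design: SurveyDesign | None = None,
    domain=None,
    level: float = 0.95,
) -> ItemsetEstimate:
    """All burden estimates for one combination: prevalence, weighted count,
    lift, mean/median expenditures, out-of-pocket, and poor-health share
    among holders."""
    design = design or design_of(ds)
    w = ds.weights
    mask = itemset_mask(itemset)
    member = ds.holds_mask(mask)
    d = np.ones(ds.n) if domain is None else np.asarray(domain, dtype=float)
    member_d = member & (d > 0)
    ind = member_d.astype(float)

    prev = estimate_proportion(ind, ds, design, domain=domain, level=level)
    denom = float(np.sum(w * d))
    total = float(np.sum(w * ind))
    z = w * ind
    se_tot = float(np.sqrt(design.variance(z)))
    lo, hi = _ci(total, se_tot, design.df, level)
    weighted_n = LinearizedEstimate(total, se_tot, lo, hi, design.df, "total")

    lift = None
    if len(itemset) >= 2:
        lift = estimate_lift(itemset, ds, design, domain=domain, level=level)

    t = ds.table
    texp = t["total_exp"].to_numpy(dtype=float)
    oexp = t["oop_exp"].to_numpy(dtype=float)
    poor = t["poor_health"].to_numpy(dtype=float)
    mean_exp = domain_mean(texp, ind, ds, design, level=level)
    mean_oop = domain_mean(oexp, ind, ds, design, level=level)
    poor_pct = domain_mean(poor, ind, ds, design, level=level)
    if member_d.any():
        med, q25, q75 = weighted_median_iqr(texp[member_d], w[member_d])
        median_exp, iqr = med, (q25, q75)
    else:
        median_exp, iqr = None, None

    n_x = int(member_d.sum())
    record = SupportRecord(
        itemset=itemset,
        n=n_x,
        support=n_x / max(int((d > 0).sum()), 1),
        weighted_n=total,
        prevalence=total / denom if denom > 0 else float("nan"),
    )
    return ItemsetEstimate(
        record, prev, weighted_n, lift, mean_exp, mean_oop, median_exp, iqr, poor_pct
    )


def estimate_itemsets(
    records,
    ds: SurveyDataset,
    design: SurveyDesign | None = None,
    domain=None,
    level: float = 0.95,
) -> list[ItemsetEstimate]:
    """Estimate every combination in ``records`` (a SupportRecord iterable)."""
    design = design or design_of(ds)
    return [
        estimate_itemset(r.itemset, ds, design, domain=domain, level=level)
        for r in records
    ]


def estimates_to_frame(estimates, catalog) -> pd.DataFrame:
    """Flatten ItemsetEstimates to one row per combination (report format)."""
    rows = []
    for e in estimates:
        items = "|".join(catalog.names(e.itemset))
        row = {
            "items": items,
            "size": len(e.itemset),
            "n": e.record.n,
            "support": e.record.support,
            "weighted_n": e.weighted_n.point,
            "weighted_n_lo": e.weighted_n.lo,
            "weighted_n_hi": e.weighted_n.hi,
            "prevalence_pct": 100 * e.prevalence.point,
            "prevalence_lo_pct": 100 * e.prevalence.lo,
            "prevalence_hi_pct": 100 * e.prevalence.hi,
        }
        for name, est in (
            ("lift", e.lift),
            ("mean_exp", e.mean_exp),
            ("mean_oop", e.mean_oop),
        ):
            row[name] = est.point if est else np.nan
            row[f"{name}_lo"] = est.lo if est else np.nan
            row[f"{name}_hi"] = est.hi if est else np.nan
        row["median_exp"] = e.median_exp if e.median_exp is not None else np.nan
        row["exp_q25"] = e.iqr_exp[0] if e.iqr_exp else np.nan
        row["exp_q75"] = e.iqr_exp[1] if e.iqr_exp else np.nan
        row["poor_health_pct"] = 100 * e.poor_health.point if e.poor_health else np.nan
        row["poor_health_lo_pct"] = 100 * e.poor_health.lo if e.poor_health else np.nan
        row["poor_health_hi_pct"] = 100 * e.poor_health.hi if e.poor_health else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
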