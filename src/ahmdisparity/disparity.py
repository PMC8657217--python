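"""Prevalence-rate-ratio (PRR) disparity index.

The PRR for a county is the Black/African-American (BAA) prevalence of
antihypertensive-medication non-adherence divided by the non-Hispanic White
(nHW) prevalence; values above 1 indicate a disparity disadvantaging BAAs.
Overall and regional summaries default to the geometric mean of county PRRs
with a t-interval on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PRRDomainError",
    "AggregateEstimate",
    "DisparityResult",
    "county_prr",
    "aggregate_prr",
    "compute_disparity",
    "region_stratified_regression",
]


class PRRDomainError(ValueError):
    """A prevalence is zero or negative, so the ratio is undefined."""


def county_prr(baa_prev, nhw_prev):
    """BAA/nHW prevalence ratio; accepts scalars or arrays (element-wise)."""
    baa = np.asarray(baa_prev, dtype=float)
    nhw = np.asarray(nhw_prev, dtype=float)
    if np.any(baa <= 0) or np.any(nhw <= 0):
        raise PRRDomainError("prevalences must be strictly positive")
    out = baa / nhw
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AggregateEstimate:
    estimate: float
    ci_low: float | None
    ci_high: float | None
    n: int

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None


@dataclass
class DisparityResult:
    per_county: pd.DataFrame  # columns: fips, prr
    overall: AggregateEstimate
    by_region: dict[str, AggregateEstimate]
    n_counties: int
    n_excluded: int
    excluded_fips: list[str] = field(default_factory=list)
    method: str = "geometric"

    def tidy(self) -> pd.DataFrame:
        """Long-format summary table (group, label, estimate, ci, n)."""
        rows = [
            {
                "group": "overall",
                "label": "overall",
                "estimate": self.overall.estimate,
                "ci_low": self.overall.ci_low,
                "ci_high": self.overall.ci_high,
                "n": self.overall.n,
            }
        ]
        for region, est in sorted(self.by_region.items()):
            rows.append(
                {
                    "group": "region",
                    "label": region,
                    "estimate": est.estimate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": est.n,
                }
            )
        return pd.DataFrame(rows)


def _aggregate(ratios: np.ndarray, method: str, alpha: float) -> AggregateEstimate:
    n = ratios.size
    if method == "geometric":
        logs = np.log(ratios)
        center = float(np.exp(logs.mean()))
        if n < 2:
            return AggregateEstimate(center, None, None, n)
        se = logs.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        lo, hi = np.exp(logs.mean() - tcrit * se), np.exp(logs.mean() + tcrit * se)
        return AggregateEstimate(center, float(lo), float(hi), n)
    if method == "arithmetic":
        center = float(ratios.mean())
        if n < 2:
            return AggregateEstimate(center, None, None, n)
        se = ratios.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        return AggregateEstimate(
            center, center - float(tcrit * se), center + float(tcrit * se), n
        )
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_prr(
    ratios,
    groups=None,
    method: str = "geometric",
    alpha: float = 0.05,
):
    """Aggregate county PRRs to a point estimate with a 95% CI.

    With ``groups=None`` returns a single :class:`AggregateEstimate`;
    otherwise a dict mapping group label to estimate.  Groups with fewer than
    two counties get a point estimate with the CI flagged unavailable.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise PRRDomainError("PRRs must be strictly positive")
    if groups is None:
        return _aggregate(ratios, method, alpha)
    groups = np.asarray(groups)
    return {
        g: _aggregate(ratios[groups == g], method, alpha)
        for g in pd.unique(groups)
    }


def compute_disparity(
    records: pd.DataFrame,
    method: str = "geometric",
    alpha: float = 0.05,
) -> DisparityResult:
    """Per-county PRRs plus overall and regional aggregates.

    Counties with a missing or non-positive race-specific prevalence are
    excluded from aggregation and counted in ``n_excluded``.  ``method`` is
    one of ``geometric`` (default), ``arithmetic`` (mean of ratios), or
    ``pooled`` (ratio of mean prevalences; CI by the log-scale delta method is
    not attempted — the pooled estimate is reported without a CI).
    """
    baa = pd.to_numeric(records["baa_nonadh_pct"], errors="coerce")
    nhw = pd.to_numeric(records["nhw_nonadh_pct"], errors="coerce")
    ok = (baa > 0) & (nhw > 0)
    excluded = records.loc[~ok, "fips"].astype(str).tolist()
    sub = records.loc[ok]
    ratios = county_prr(baa[ok].to_numpy(), nhw[ok].to_numpy())
    per_county = pd.DataFrame({"fips": sub["fips"].to_numpy(), "prr": ratios})

    if method == "pooled":
        overall = AggregateEstimate(
            float(baa[ok].mean() / nhw[ok].mean()), None, None, int(ok.sum())
        )
        by_region = {}
        for region, idx in sub.groupby("region").groups.items():
            b, w = baa.loc[idx], nhw.loc[idx]
            by_region[region] = AggregateEstimate(
                float(b.mean() / w.mean()), None, None, len(idx)
            )
    else:
        overall = _aggregate(ratios, method, alpha)
        by_region = aggregate_prr(
            ratios, groups=sub["region"].to_numpy(), method=method, alpha=alpha
        )
    return DisparityResult(
        per_county=per_county,
        overall=overall,
        by_region=by_region,
        n_counties=int(ok.sum()),
        n_excluded=int((~ok).sum()),
        excluded_fips=excluded,
        method=method,
    )


def region_stratified_regression(
    records: pd.DataFrame,
    race: str,
    predictor: str = "se_score",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region OLS of race-specific non-adherence on one domain score.

    Returns a table (region, slope, ci_low, ci_high, n).  Used to probe
    geographic variation in the association between, e.g., social & economic
    conditions and non-adherence.  Regions need at least three counties; a
    constant predictor within a region is an error.
    """
    if race not in ("baa", "nhw"):
        raise ValueError("race must be 'baa' or 'nhw'")
    ycol = f"{race}_nonadh_pct"
    rows = []
    for region, grp in records.groupby("region"):
        if len(grp) < 3:
            raise ValueError(f"region {region!r} has fewer than 3 counties")
        x = grp[predictor].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(
                f"predictor {predictor!r} is constant within region {region!r}"
            )
        y = grp[ycol].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        if fit.df_resid > 0:
            lo, hi = fit.conf_int(alpha=alpha)[1]
        else:  # saturated (n == 2 would be caught above; exact fits)
            lo = hi = fit.params[1]
        slope = fit.params[1]
        if fit.ssr <= max(1e-12 * np.sum(y**2), 1e-300):
            lo = hi = slope  # exact linear relationship: zero-width CI
        rows.append(
            {
                "region": region,
                "slope": float(slope),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)
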