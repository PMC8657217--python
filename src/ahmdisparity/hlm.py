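"""Hierarchical linear models for the county disparity index.

Fits the county PRR (BAA/nHW non-adherence ratio) with a state random
intercept and county-level fixed effects, in the canonical four-model
sequence:

* M1 — one determinants-of-health domain score at a time (bivariate);
* M2 — domain score plus percent aged >= 65 (age-adjusted);
* M3 — all four domain scores;
* M4 — all four domain scores plus the demographic confounders
  (% BAA, % >= 65, % female, % rural).

A variance-component pseudo-R^2 compares the sum of the state-intercept and
residual variances of a fitted model against the intercept-only null: the
proportional reduction in total variance (Snijders-Bosker style).
Estimation is by maximum likelihood by default so that variance components
are comparable across nested fixed-effect rosters; REML is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .disparity import county_prr

__all__ = [
    "HLMFit",
    "PseudoR2",
    "RandomInterceptModel",
    "fit_random_intercept",
    "pseudo_r2",
    "model_sequence",
    "MODEL_ROSTERS",
]

DOMAINS = ("hb_score", "cc_score", "se_score", "pe_score")
DEMOGS = ("pct_baa", "pct_over65", "pct_female", "pct_rural")

MODEL_ROSTERS = {
    "M1": lambda domain: (domain,),
    "M2": lambda domain: (domain, "pct_over65"),
    "M3": lambda domain: DOMAINS,
    "M4": lambda domain: DOMAINS + DEMOGS,
}


@dataclass
class HLMFit:
    """Fixed effects and variance components of one random-intercept fit."""

    fixed_effects: dict[str, tuple[float, float, float]]  # coef, se, p
    sigma2_state: float
    sigma2_resid: float
    loglik: float
    n_counties: int
    n_states: int
    model_label: str = ""
    converged: bool = True
    method: str = "ml"

    @property
    def total_variance(self) -> float:
        return self.sigma2_state + self.sigma2_resid

    def coef(self, name: str) -> float:
        return self.fixed_effects[name][0]

    def se(self, name: str) -> float:
        return self.fixed_effects[name][1]

    def pvalue(self, name: str) -> float:
        return self.fixed_effects[name][2]


@dataclass
class PseudoR2:
    value: float
    null_fit: HLMFit = field(repr=False, default=None)
    full_fit: HLMFit = field(repr=False, default=None)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns linearly dependent on the preceding ones."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        scale = np.linalg.norm(X[:, j]) or 1.0
        if np.linalg.norm(resid) < 1e-8 * scale:
            bad.append(names[j])
    return bad


class RandomInterceptModel(BaseEstimator):
    """Linear mixed model with a single grouping-level random intercept.

    sklearn-style estimator: ``fit(X, y, groups=...)`` stores the fixed-effect
    coefficients in ``coef_``/``intercept_`` and the variance components in
    ``sigma2_group_`` and ``sigma2_resid_``.  Backed by maximum-likelihood
    estimation (``reml=False``) unless ``reml=True``.
    """

    def __init__(self, reml: bool = False):
        self.reml = reml

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if groups is None:
            raise ValueError("groups is required")
        groups = np.asarray(groups)
        if X.shape[0] != y.size or groups.size != y.size:
            raise ValueError("X, y and groups must have matching lengths")
        names = ["intercept"] + [f"x{j}" for j in range(X.shape[1])]
        if hasattr(X, "columns"):
            names = ["intercept"] + list(X.columns)
        self._fit = _fit_mixedlm(y, X, groups, names, reml=self.reml)
        coefs = np.array([self._fit.coef(n) for n in names])
        self.intercept_ = coefs[0]
        self.coef_ = coefs[1:]
        self.sigma2_group_ = self._fit.sigma2_state
        self.sigma2_resid_ = self._fit.sigma2_resid
        self.loglik_ = self._fit.loglik
        self.fit_ = self._fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


def _fit_mixedlm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    reml: bool = False,
    model_label: str = "",
) -> HLMFit:
    n_states = len(np.unique(groups))
    exog = np.column_stack([np.ones(y.size), X])
    full_names = names if len(names) == exog.shape[1] else ["intercept"] + list(names)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = _collinear_columns(exog, full_names)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    def _ols_fallback(reason: str) -> HLMFit:
        ols = sm.OLS(y, exog).fit()
        fe = {
            nm: (float(ols.params[j]), float(ols.bse[j]), float(ols.pvalues[j]))
            for j, nm in enumerate(full_names)
        }
        warnings.warn(f"falling back to OLS: {reason}", stacklevel=3)
        return HLMFit(
            fixed_effects=fe,
            sigma2_state=0.0,
            sigma2_resid=float(ols.scale),
            loglik=float(ols.llf),
            n_counties=y.size,
            n_states=n_states,
            model_label=model_label,
            converged=True,
            method="ols",
        )

    if n_states < 2:
        return _ols_fallback("only one state in the data")

    # Noise-free outcomes break the ML profile likelihood; detect an exact
    # linear relationship first and report zero variance components directly.
    ols0 = sm.OLS(y, exog).fit()
    if ols0.ssr <= max(1e-12 * float(np.sum(y**2)), 1e-300):
        fe = {
            nm: (float(ols0.params[j]), 0.0, 0.0) for j, nm in enumerate(full_names)
        }
        return HLMFit(
            fixed_effects=fe,
            sigma2_state=0.0,
            sigma2_resid=0.0,
            loglik=float("inf"),
            n_counties=y.size,
            n_states=n_states,
            model_label=model_label,
            method="exact",
        )

    # lbfgs can spuriously park the variance component at the zero
    # boundary; bfgs/powell are reliable here, so try them in order
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        for method in ("bfgs", "powell", "cg"):
            try:
                result = model.fit(reml=reml, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if result is None:
        # singular information at every optimizer: variance component at
        # the zero boundary, where the ML solution coincides with OLS
        return _ols_fallback("state variance estimated at zero boundary")
    fe = {}
    for j, nm in enumerate(full_names):
        fe[nm] = (
            float(result.params[j]),
            float(result.bse[j]),
            float(result.pvalues[j]),
        )
    return HLMFit(
        fixed_effects=fe,
        sigma2_state=float(np.asarray(result.cov_re)[0, 0]),
        sigma2_resid=float(result.scale),
        loglik=float(result.llf),
        n_counties=y.size,
        n_states=n_states,
        model_label=model_label,
        converged=bool(result.converged),
        method="reml" if reml else "ml",
    )


def fit_random_intercept(
    y,
    X,
    groups,
    names: list[str] | None = None,
    reml: bool = False,
    model_label: str = "",
) -> HLMFit:
    """ML fit of ``y = intercept + X b + u_group + eps`` with Wald p-values.

    ``X`` should not contain an intercept column; one is added.  Raises on a
    rank-deficient design (naming the collinear columns) and falls back to
    OLS with a warning when only one group is present.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return _fit_mixedlm(
        y, X, np.asarray(groups), ["intercept"] + list(names), reml=reml,
        model_label=model_label,
    )


def fit_null(y, groups, reml: bool = False) -> HLMFit:
    """Intercept-plus-random-intercept null model."""
    y = np.asarray(y, dtype=float).ravel()
    return _fit_mixedlm(
        y,
        np.empty((y.size, 0)),
        np.asarray(groups),
        ["intercept"],
        reml=reml,
        model_label="null",
    )


def pseudo_r2(null_fit: HLMFit, full_fit: HLMFit) -> PseudoR2:
    """Proportional reduction in total (state + residual) variance."""
    if null_fit.n_counties != full_fit.n_counties:
        raise ValueError("null and full fits are on different data sizes")
    value = 1.0 - full_fit.total_variance / null_fit.total_variance
    return PseudoR2(value=float(value), null_fit=null_fit, full_fit=full_fit)


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def model_sequence(
    records: pd.DataFrame,
    outcome: str = "prr",
    standardize: bool = True,
    reml: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Fit the M1-M4 sequence on county PRR and tabulate coefficients.

    Returns ``(table, fits)`` where ``table`` has one row per domain score
    with columns ``m1_beta, m1_star, ..., m4_beta, m4_star`` plus attached
    pseudo-R^2 values for M3 and M4 (``table.attrs['pseudo_r2']``), and
    ``fits`` maps model label (plus domain for M1/M2) to :class:`HLMFit`.

    ``outcome``: ``"prr"`` (natural scale, default) or ``"log_prr"``.
    Covariates are standardized to mean 0 / sd 1 by default.
    """
    y = county_prr(
        records["baa_nonadh_pct"].to_numpy(), records["nhw_nonadh_pct"].to_numpy()
    )
    if outcome == "log_prr":
        y = np.log(y)
    elif outcome != "prr":
        raise ValueError("outcome must be 'prr' or 'log_prr'")
    groups = records["state_id"].to_numpy()

    cols = {}
    for name in DOMAINS + DEMOGS:
        x = records[name].to_numpy(dtype=float)
        if standardize:
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"covariate {name!r} has zero variance")
            x = (x - x.mean()) / sd
        cols[name] = x

    fits: dict[str, HLMFit] = {}
    null = fit_null(y, groups, reml=reml)
    fits["null"] = null

    rows = {domain: {"domain": domain} for domain in DOMAINS}
    for label in ("M1", "M2"):
        for domain in DOMAINS:
            roster = MODEL_ROSTERS[label](domain)
            X = np.column_stack([cols[c] for c in roster])
            fit = fit_random_intercept(
                y, X, groups, names=list(roster), reml=reml,
                model_label=f"{label}:{domain}",
            )
            fits[f"{label}:{domain}"] = fit
            rows[domain][f"{label.lower()}_beta"] = fit.coef(domain)
            rows[domain][f"{label.lower()}_star"] = _stars(fit.pvalue(domain))
    for label in ("M3", "M4"):
        roster = MODEL_ROSTERS[label](None)
        X = np.column_stack([cols[c] for c in roster])
        fit = fit_random_intercept(
            y, X, groups, names=list(roster), reml=reml, model_label=label
        )
        fits[label] = fit
        for domain in DOMAINS:
            rows[domain][f"{label.lower()}_beta"] = fit.coef(domain)
            rows[domain][f"{label.lower()}_star"] = _stars(fit.pvalue(domain))

    table = pd.DataFrame([rows[d] for d in DOMAINS])
    table.attrs["pseudo_r2"] = {
        "M3": pseudo_r2(null, fits["M3"]).value,
        "M4": pseudo_r2(null, fits["M4"]).value,
    }
    return table, fits
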