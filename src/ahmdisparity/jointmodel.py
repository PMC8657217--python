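"""Bayesian shared-component factor model for race-specific mortality.

Jointly fits the four county-level outcomes — log heart-disease and stroke
mortality rates per 100,000 for Black/African Americans (BAA) and
non-Hispanic Whites (nHW) — with:

* a county-level latent factor per race, shared across that race's two
  outcomes and correlated across races within a county;
* a state-level latent factor shared by all outcomes in a state;
* factor loadings per outcome, with the county-factor loading on heart
  disease fixed at 1 per race and the state-factor loading on BAA heart
  disease fixed at 1, for identifiability;
* race-matched AHM non-adherence, four determinants-of-health domain scores
  and four demographic confounders as standardized covariates, optionally
  with non-adherence x domain-score interaction (moderation) terms.

Inference is MCMC (conjugate Gibbs updates with slice steps for scales and
the cross-race correlation; see :mod:`ahmdisparity._gibbs`).  Summaries are
the posterior mean, central 95% credible interval and the posterior
probability that an effect is positive, plus split-R-hat and effective
sample size per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _gibbs
from .synthdata import DEMOG_COLUMNS, DISEASES, DOMAIN_COLUMNS, RACES

__all__ = [
    "MCMCSettings",
    "PriorSettings",
    "JointModelSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "SharedComponentFactorModel",
    "standardize_covariates",
    "sample_posterior",
    "summarize",
    "interaction_effects",
    "county_factor_report",
]

SHARED_COVARIATES = DOMAIN_COLUMNS + DEMOG_COLUMNS


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0


@dataclass(frozen=True)
class PriorSettings:
    coef_sd: float = 10.0  # normal prior sd for coefficients and loadings
    sigma_scale: float = 1.0  # half-normal scale for all sds


@dataclass(frozen=True)
class JointModelSpec:
    """Structure, priors and MCMC settings of one joint-model fit."""

    interactions: bool = False
    interaction_standardize: bool = True
    races: tuple[str, ...] = RACES
    fix_rho: float | None = None
    fix_sigma_g: float | None = None
    priors: PriorSettings = field(default_factory=PriorSettings)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def outcome_names(self) -> list[str]:
        return [f"{r}_{d}" for r in self.races for d in DISEASES]


@dataclass
class PosteriorDraws:
    """Retained draws plus per-county running summaries.

    ``scalars`` maps parameter name (``"baa_hd:nonadh"``, ``"rho"``, ...) to
    a (chains, draws) array.  County factors and the BAA-nHW log-rate
    differences are accumulated during sampling (posterior mean and count of
    positive draws) instead of being stored draw-by-draw.
    """

    scalars: dict[str, np.ndarray]
    factor_mean: np.ndarray  # (n, R)
    factor_p_gt0: np.ndarray  # (n, R)
    diff_mean: np.ndarray | None  # (n, 2): hd, st
    diff_p_gt0: np.ndarray | None
    fips: np.ndarray
    spec: JointModelSpec
    n_draws_total: int

    def constrained(self) -> dict[str, float]:
        """Loadings fixed at 1 for identifiability."""
        out = {f"lambda:{r}_hd": 1.0 for r in self.spec.races}
        if self.spec.fix_sigma_g is None or self.spec.fix_sigma_g > 0:
            out[f"kappa:{self.spec.outcome_names()[0]}"] = 1.0
        return out


@dataclass
class PosteriorSummary:
    params: pd.DataFrame  # name, mean, sd, ci_low, ci_high, p_gt0, rhat, ess
    county_factors: pd.DataFrame  # fips, race, factor_mean, p_above_zero
    county_differences: pd.DataFrame | None  # fips, disease, diff_mean, p_gt0
    diagnostics: dict

    def param(self, name: str) -> pd.Series:
        return self.params.set_index("name").loc[name]


def standardize_covariates(
    records: pd.DataFrame, roster
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale each rostered column to mean 0, sd 1 (sample sd).

    Returns the standardized design and the (mean, sd) pair per covariate so
    coefficients can be mapped back to the natural scale.
    """
    out = {}
    stats = {}
    for name in roster:
        x = pd.to_numeric(records[name], errors="raise").to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        out[name] = (x - mean) / sd
        stats[name] = (mean, sd)
    return pd.DataFrame(out, index=records.index), stats


def _validate_rates(records: pd.DataFrame, races) -> None:
    for race in races:
        for d in DISEASES:
            col = f"{race}_{d}_rate"
            vals = records[col].to_numpy(dtype=float)
            bad = ~(np.isfinite(vals) & (vals > 0))
            if bad.any():
                fips = records.loc[bad, "fips"].astype(str).tolist()[:5]
                raise ValueError(
                    f"non-positive or non-finite rate in {col} for counties "
                    f"{fips}; log rate is undefined"
                )


def _build_model_data(
    spec: JointModelSpec, records: pd.DataFrame
) -> tuple[_gibbs.ModelData, dict]:
    _validate_rates(records, spec.races)
    roster = list(SHARED_COVARIATES) + [
        f"{race}_nonadh_pct" for race in spec.races
    ]
    Z, stats = standardize_covariates(records, roster)

    states, state_idx = np.unique(records["state_id"].to_numpy(), return_inverse=True)
    if len(states) >= 2:
        _, counts = np.unique(state_idx, return_counts=True)
        if counts.min() < 2:
            warnings.warn(
                "some states contain a single county; the state factor is "
                "weakly informed there",
                stacklevel=3,
            )

    shared = Z[list(SHARED_COVARIATES)].to_numpy()
    n = len(records)
    y_cols, X_list, names, races_idx, diseases, outcome_names = (
        [],
        [],
        [],
        [],
        [],
        [],
    )
    for r_i, race in enumerate(spec.races):
        nonadh = Z[f"{race}_nonadh_pct"].to_numpy()
        cols = [np.ones(n), nonadh, *shared.T]
        colnames = ["intercept", "nonadh", *SHARED_COVARIATES]
        if spec.interactions:
            for m in DOMAIN_COLUMNS:
                prod = nonadh * Z[m].to_numpy()
                if spec.interaction_standardize:
                    sd = prod.std(ddof=1)
                    if sd == 0:
                        raise ValueError(
                            f"interaction nonadh x {m} has zero variance"
                        )
                    prod = (prod - prod.mean()) / sd
                cols.append(prod)
                colnames.append(f"nonadh_x_{m}")
        X = np.column_stack(cols)
        for d in DISEASES:
            out = f"{race}_{d}"
            outcome_names.append(out)
            y_cols.append(np.log(records[f"{out}_rate"].to_numpy(dtype=float)))
            X_list.append(X)
            names.append(list(colnames))
            races_idx.append(r_i)
            diseases.append(d)

    data = _gibbs.ModelData(
        y=np.column_stack(y_cols),
        X=X_list,
        names=names,
        outcome_names=outcome_names,
        outcome_race=np.asarray(races_idx),
        outcome_disease=diseases,
        races=tuple(spec.races),
        state_idx=state_idx,
        n_states=len(states),
    )
    return data, {"standardization": stats, "states": states}


def sample_posterior(
    spec: JointModelSpec, records: pd.DataFrame
) -> PosteriorDraws:
    """Run the MCMC and return retained draws (seed-reproducible)."""
    data, _meta = _build_model_data(spec, records)
    cfg = _gibbs.SamplerConfig(
        chains=spec.mcmc.chains,
        draws=spec.mcmc.draws,
        warmup=spec.mcmc.warmup,
        thin=spec.mcmc.thin,
        coef_sd=spec.priors.coef_sd,
        sigma_scale=spec.priors.sigma_scale,
        fix_rho=spec.fix_rho,
        fix_sigma_g=spec.fix_sigma_g,
        seed=spec.mcmc.seed,
    )
    chains = _gibbs.run_sampler(data, cfg)

    scalars = {
        nm: np.stack([c.scalars[nm] for c in chains])
        for nm in chains[0].scalars
    }
    n_total = sum(c.n_kept for c in chains)
    f_sum = sum(c.f_sum for c in chains)
    f_pos = sum(c.f_pos for c in chains)
    if chains[0].diff_sum is not None:
        diff_mean = sum(c.diff_sum for c in chains) / n_total
        diff_p = sum(c.diff_pos for c in chains) / n_total
    else:
        diff_mean = diff_p = None
    return PosteriorDraws(
        scalars=scalars,
        factor_mean=f_sum / n_total,
        factor_p_gt0=f_pos / n_total,
        diff_mean=diff_mean,
        diff_p_gt0=diff_p,
        fips=records["fips"].astype(str).to_numpy(),
        spec=spec,
        n_draws_total=n_total,
    )


def _diagnostics_tables(scalars: dict[str, np.ndarray]) -> pd.DataFrame:
    import arviz as az

    # constant chains (e.g. a fixed rho) make rank-normalized R-hat NaN;
    # compute diagnostics only for genuinely sampled parameters
    varying = {
        nm: v for nm, v in scalars.items() if np.ptp(v) > 0
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=varying)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = {}
    for nm in scalars:
        if nm in varying:
            rows[nm] = (float(rhat[nm].values), float(ess[nm].values))
        else:
            rows[nm] = (np.nan, np.nan)
    return rows


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean, 95% credible interval, P(>0) and diagnostics."""
    diag = _diagnostics_tables(draws.scalars)
    rows = []
    for nm, arr in draws.scalars.items():
        flat = arr.reshape(-1)
        rhat, ess = diag[nm]
        rows.append(
            {
                "name": nm,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "ci_low": float(np.percentile(flat, 2.5)),
                "ci_high": float(np.percentile(flat, 97.5)),
                "p_gt0": float(np.mean(flat > 0)),
                "rhat": rhat,
                "ess": ess,
                "constrained": False,
            }
        )
    for nm, val in draws.constrained().items():
        rows.append(
            {
                "name": nm,
                "mean": val,
                "sd": 0.0,
                "ci_low": val,
                "ci_high": val,
                "p_gt0": 1.0 if val > 0 else 0.0,
                "rhat": np.nan,
                "ess": np.nan,
                "constrained": True,
            }
        )
    params = pd.DataFrame(rows)

    fac_rows = []
    for r_i, race in enumerate(draws.spec.races):
        fac_rows.append(
            pd.DataFrame(
                {
                    "fips": draws.fips,
                    "race": race,
                    "factor_mean": draws.factor_mean[:, r_i],
                    "p_above_zero": draws.factor_p_gt0[:, r_i],
                }
            )
        )
    county_factors = pd.concat(fac_rows, ignore_index=True)

    county_differences = None
    if draws.diff_mean is not None:
        diff_rows = []
        for d_i, disease in enumerate(DISEASES):
            diff_rows.append(
                pd.DataFrame(
                    {
                        "fips": draws.fips,
                        "disease": disease,
                        "diff_mean": draws.diff_mean[:, d_i],
                        "p_gt0": draws.diff_p_gt0[:, d_i],
                    }
                )
            )
        county_differences = pd.concat(diff_rows, ignore_index=True)

    sampled = params.loc[~params["constrained"]]
    max_rhat = float(np.nanmax(sampled["rhat"].to_numpy()))
    min_ess = float(np.nanmin(sampled["ess"].to_numpy()))
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "converged": bool(max_rhat < 1.05 and min_ess > 200),
        "nonconverged_flag": bool(max_rhat > 1.1),
        "n_draws": draws.n_draws_total,
    }
    if diagnostics["nonconverged_flag"]:
        warnings.warn(
            f"MCMC convergence suspect: max R-hat {max_rhat:.3f}", stacklevel=2
        )
    return PosteriorSummary(
        params=params,
        county_factors=county_factors,
        county_differences=county_differences,
        diagnostics=diagnostics,
    )


def main_effects_table(summary: PosteriorSummary, spec: JointModelSpec) -> pd.DataFrame:
    """Per-outcome non-adherence effect: mean, 95% CI, P(>0)."""
    rows = []
    p = summary.params.set_index("name")
    for out in spec.outcome_names():
        s = p.loc[f"{out}:nonadh"]
        rows.append(
            {
                "outcome": out,
                "parameter": "nonadh",
                "mean": s["mean"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "p_gt0": s["p_gt0"],
            }
        )
    return pd.DataFrame(rows)


def interaction_effects(
    summary: PosteriorSummary, spec: JointModelSpec
) -> pd.DataFrame:
    """Moderation table: per outcome x domain, the posterior of gamma."""
    if not spec.interactions:
        raise ValueError("fit has no interaction terms; use interactions=True")
    p = summary.params.set_index("name")
    rows = []
    for out in spec.outcome_names():
        for m in DOMAIN_COLUMNS:
            s = p.loc[f"{out}:nonadh_x_{m}"]
            rows.append(
                {
                    "outcome": out,
                    "domain": m,
                    "mean": s["mean"],
                    "ci_low": s["ci_low"],
                    "ci_high": s["ci_high"],
                    "p_gt0": s["p_gt0"],
                }
            )
    return pd.DataFrame(rows)


def county_factor_report(
    draws_or_summary: PosteriorDraws | PosteriorSummary,
) -> pd.DataFrame:
    """Tidy per-county, per-race latent-factor summary."""
    if isinstance(draws_or_summary, PosteriorSummary):
        return draws_or_summary.county_factors.copy()
    rows = []
    for r_i, race in enumerate(draws_or_summary.spec.races):
        rows.append(
            pd.DataFrame(
                {
                    "fips": draws_or_summary.fips,
                    "race": race,
                    "factor_mean": draws_or_summary.factor_mean[:, r_i],
                    "p_above_zero": draws_or_summary.factor_p_gt0[:, r_i],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class SharedComponentFactorModel(BaseEstimator):
    """sklearn-style estimator wrapping the shared-component factor model.

    Parameters mirror :class:`JointModelSpec`; ``fit`` accepts a county table
    (the canonical CSV schema) and populates ``summary_``, ``draws_``,
    ``county_factors_``, ``county_differences_`` and ``diagnostics_``.
    """

    def __init__(
        self,
        interactions: bool = False,
        interaction_standardize: bool = True,
        races: tuple[str, ...] = RACES,
        fix_rho: float | None = None,
        fix_sigma_g: float | None = None,
        coef_sd: float = 10.0,
        sigma_scale: float = 1.0,
        chains: int = 4,
        draws: int = 2000,
        warmup: int = 1000,
        thin: int = 1,
        random_state: int = 0,
    ):
        self.interactions = interactions
        self.interaction_standardize = interaction_standardize
        self.races = races
        self.fix_rho = fix_rho
        self.fix_sigma_g = fix_sigma_g
        self.coef_sd = coef_sd
        self.sigma_scale = sigma_scale
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.thin = thin
        self.random_state = random_state

    def spec(self) -> JointModelSpec:
        return JointModelSpec(
            interactions=self.interactions,
            interaction_standardize=self.interaction_standardize,
            races=tuple(self.races),
            fix_rho=self.fix_rho,
            fix_sigma_g=self.fix_sigma_g,
            priors=PriorSettings(
                coef_sd=self.coef_sd, sigma_scale=self.sigma_scale
            ),
            mcmc=MCMCSettings(
                chains=self.chains,
                draws=self.draws,
                warmup=self.warmup,
                thin=self.thin,
                seed=self.random_state,
            ),
        )

    def fit(self, X: pd.DataFrame, y=None):
        spec = self.spec()
        _, meta = _build_model_data(spec, X)
        self.standardization_ = meta["standardization"]
        self.posterior_ = sample_posterior(spec, X)
        self.summary_obj_ = summarize(self.posterior_)
        self.summary_ = self.summary_obj_.params
        self.draws_ = self.posterior_.scalars
        self.county_factors_ = self.summary_obj_.county_factors
        self.county_differences_ = self.summary_obj_.county_differences
        self.diagnostics_ = self.summary_obj_.diagnostics
        return self

    def main_effects_(self) -> pd.DataFrame:
        return main_effects_table(self.summary_obj_, self.spec())

    def interaction_effects_(self) -> pd.DataFrame:
        return interaction_effects(self.summary_obj_, self.spec())
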