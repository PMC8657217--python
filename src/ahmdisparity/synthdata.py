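"""Synthetic county-level data with known ground truth.

Generates tables shaped like a linkage of county cardiovascular-mortality
surveillance data with county health-ranking composite scores: one row per
county (keyed by 5-digit FIPS), carrying race-specific antihypertensive-
medication (AHM) non-adherence prevalence, four determinants-of-health domain
scores, demographic confounders, and race-specific heart-disease and stroke
mortality rates per 100,000.

The mortality rates are generated from the same shared-component factor model
the :mod:`ahmdisparity.jointmodel` module fits — log rates are a linear
function of standardized covariates plus a county-level latent factor per race
(cross-race correlated), a state-level latent factor shared by all outcomes,
and Gaussian residual noise — so every downstream stage can be tested for
parameter recovery against a saved truth record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RACES",
    "DISEASES",
    "OUTCOMES",
    "REGIONS",
    "CSV_COLUMNS",
    "DOMAIN_COLUMNS",
    "DEMOG_COLUMNS",
    "CountyRecord",
    "NonadherenceModel",
    "JointModelTruth",
    "GeneratorConfig",
    "SyntheticTruth",
    "ConfigurationError",
    "CountyCSVError",
    "generate_dataset",
    "write_county_csv",
    "read_county_csv",
]

RACES = ("baa", "nhw")
DISEASES = ("hd", "st")
OUTCOMES = ("baa_hd", "baa_st", "nhw_hd", "nhw_st")
REGIONS = ("Midwest", "Northeast", "South", "West")

DOMAIN_COLUMNS = ("hb_score", "cc_score", "se_score", "pe_score")
DEMOG_COLUMNS = ("pct_baa", "pct_over65", "pct_female", "pct_rural")
RATE_COLUMNS = ("baa_hd_rate", "baa_st_rate", "nhw_hd_rate", "nhw_st_rate")

CSV_COLUMNS = (
    "fips",
    "state_id",
    "region",
    "baa_nonadh_pct",
    "nhw_nonadh_pct",
    *DOMAIN_COLUMNS,
    *DEMOG_COLUMNS,
    *RATE_COLUMNS,
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class CountyCSVError(ValueError):
    """Raised when a county CSV file cannot be parsed against the schema."""


@dataclass(frozen=True)
class CountyRecord:
    """One county's covariates, prevalences and mortality rates."""

    fips: str
    state_id: str
    region: str
    baa_nonadh_pct: float
    nhw_nonadh_pct: float
    hb_score: float
    cc_score: float
    se_score: float
    pe_score: float
    pct_baa: float
    pct_over65: float
    pct_female: float
    pct_rural: float
    baa_hd_rate: float
    baa_st_rate: float
    nhw_hd_rate: float
    nhw_st_rate: float


@dataclass(frozen=True)
class NonadherenceModel:
    """Generative law for race-specific non-adherence prevalence (percent).

    Prevalence is linear-Gaussian on the percent scale by default (``scale =
    "percent"``), with coefficients applied to sample-standardized domain
    scores and an optional state-level random intercept per race:

        prev_r = intercept_r + z' coef_r + u_state + eps,   clamped to clamp.

    The BAA intercept is ``nhw_intercept + race_gap``.  A ``"logit"`` scale is
    available, in which case the linear predictor is interpreted on the logit
    of prevalence/100.
    """

    nhw_intercept: float = 25.5
    race_gap: float = 9.1
    nhw_coefs: tuple[float, float, float, float] = (0.0, -0.5, -0.3, 0.0)
    baa_coefs: tuple[float, float, float, float] = (0.0, -1.5, -1.0, 0.0)
    nhw_state_sd: float = 1.0
    baa_state_sd: float = 1.0
    nhw_county_sd: float = 2.5
    baa_county_sd: float = 2.5
    scale: str = "percent"
    clamp: tuple[float, float] = (1.0, 99.0)

    def intercept(self, race: str) -> float:
        return self.nhw_intercept + (self.race_gap if race == "baa" else 0.0)


def _default_beta() -> dict[str, dict[str, float]]:
    # Modest covariate effects at log-rate scale; non-adherence effect 0.05
    # per standardized unit for every outcome.
    beta = {}
    for out in OUTCOMES:
        beta[out] = {
            "nonadh": 0.05,
            "hb_score": 0.03,
            "cc_score": -0.04,
            "se_score": 0.03,
            "pe_score": 0.0,
            "pct_baa": 0.02,
            "pct_over65": 0.05,
            "pct_female": -0.01,
            "pct_rural": 0.01,
        }
    return beta


def _default_gamma() -> dict[str, dict[str, float]]:
    return {out: {m: 0.0 for m in DOMAIN_COLUMNS} for out in OUTCOMES}


@dataclass(frozen=True)
class JointModelTruth:
    """Generating parameters of the shared-component mortality model.

    ``alpha`` are per-outcome intercepts on the log rate-per-100,000 scale;
    ``beta`` maps outcome -> covariate -> coefficient on the standardized
    covariate; ``gamma`` maps outcome -> domain -> moderation coefficient on
    the (standardized) non-adherence x domain product.  County factor loadings
    on heart disease are fixed at 1 per race, and the state-factor loading on
    the BAA heart-disease outcome is fixed at 1, for identifiability; the
    remaining loadings are free.
    """

    alpha: dict[str, float] = field(
        default_factory=lambda: {
            "baa_hd": 5.45,
            "baa_st": 3.95,
            "nhw_hd": 5.20,
            "nhw_st": 3.70,
        }
    )
    beta: dict[str, dict[str, float]] = field(default_factory=_default_beta)
    gamma: dict[str, dict[str, float]] = field(default_factory=_default_gamma)
    sigma_f: dict[str, float] = field(
        default_factory=lambda: {"baa": 0.3, "nhw": 0.3}
    )
    rho: float = 0.5
    sigma_g: float = 0.2
    lambda_st: dict[str, float] = field(
        default_factory=lambda: {"baa": 0.8, "nhw": 0.8}
    )
    kappa: dict[str, float] = field(
        default_factory=lambda: {"baa_st": 0.7, "nhw_hd": 0.9, "nhw_st": 0.6}
    )
    sigma_resid: dict[str, float] = field(
        default_factory=lambda: {out: 0.1 for out in OUTCOMES}
    )

    def loading_f(self, race: str, disease: str) -> float:
        """County-factor loading for outcome (race, disease)."""
        return 1.0 if disease == "hd" else self.lambda_st[race]

    def loading_g(self, outcome: str) -> float:
        """State-factor loading for a named outcome."""
        return 1.0 if outcome == "baa_hd" else self.kappa[outcome]

    def validate(self) -> None:
        for r, s in self.sigma_f.items():
            if s < 0:
                raise ConfigurationError(f"sigma_f[{r}] must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must lie in [-1, 1]")
        if self.sigma_g < 0:
            raise ConfigurationError("sigma_g must be >= 0")
        for out, s in self.sigma_resid.items():
            if s < 0:
                raise ConfigurationError(f"sigma_resid[{out}] must be >= 0")


def _default_region_assignment(n_states: int) -> dict[str, str]:
    # Southern states dominate the analytic sample of counties with
    # releasable race-specific rates; weight the default split accordingly.
    quota = {"South": 0.53, "Midwest": 0.21, "Northeast": 0.13, "West": 0.13}
    counts = {reg: int(round(q * n_states)) for reg, q in quota.items()}
    while sum(counts.values()) < n_states:
        counts["South"] += 1
    while sum(counts.values()) > n_states:
        counts["South"] -= 1
    assignment: dict[str, str] = {}
    idx = 0
    for reg in ("South", "Midwest", "Northeast", "West"):
        for _ in range(counts[reg]):
            assignment[f"S{idx:02d}"] = reg
            idx += 1
    return assignment


def _default_domain_cov() -> np.ndarray:
    sds = np.array([0.68, 0.56, 0.69, 0.39])
    corr = np.full((4, 4), 0.4)
    np.fill_diagonal(corr, 1.0)
    return np.outer(sds, sds) * corr


@dataclass(frozen=True)
class GeneratorConfig:
    """Free parameters of the synthetic county generator.

    Defaults target the descriptive scale typical of U.S. county samples
    restricted to counties with releasable race-specific mortality rates:
    875 counties in 38 states; BAA non-adherence mean 34.6%, nHW 25.5%;
    domain-score means (0.06, 0.02, 0.21, 0.18) with sds (0.68, 0.56, 0.69,
    0.39); demographic means/sds (20.5/16.0, 15.9/4.1, 50.7/1.9, 39.5/29.1).
    """

    n_states: int = 38
    n_counties: int = 875
    counties_per_state: int | tuple[int, int] | None = None
    region_assignment: dict[str, str] | None = None
    domain_score_mean: tuple[float, ...] = (0.06, 0.02, 0.21, 0.18)
    domain_score_cov: np.ndarray = field(default_factory=_default_domain_cov)
    demog_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pct_baa": (20.5, 16.0),
            "pct_over65": (15.9, 4.1),
            "pct_female": (50.7, 1.9),
            "pct_rural": (39.5, 29.1),
        }
    )
    nonadh_model: NonadherenceModel = field(default_factory=NonadherenceModel)
    mortality_truth: JointModelTruth = field(default_factory=JointModelTruth)
    seed: int = 20211202

    def validate(self) -> None:
        if self.n_states < 1:
            raise ConfigurationError("n_states must be positive")
        cov = np.asarray(self.domain_score_cov, dtype=float)
        if cov.shape != (4, 4):
            raise ConfigurationError("domain_score_cov must be 4x4")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "domain_score_cov is not positive definite"
            ) from exc
        for name, (_, sd) in self.demog_params.items():
            if sd < 0:
                raise ConfigurationError(f"demog sd for {name} must be >= 0")
        nm = self.nonadh_model
        for sd in (
            nm.nhw_state_sd,
            nm.baa_state_sd,
            nm.nhw_county_sd,
            nm.baa_county_sd,
        ):
            if sd < 0:
                raise ConfigurationError("non-adherence sds must be >= 0")
        if nm.scale not in ("percent", "logit"):
            raise ConfigurationError("nonadh_model.scale must be percent|logit")
        self.mortality_truth.validate()
        if self.counties_per_state is not None:
            cps = self.counties_per_state
            if isinstance(cps, int):
                if cps < 1:
                    raise ConfigurationError("counties_per_state must be >= 1")
            else:
                lo, hi = cps
                if lo < 1 or hi < lo:
                    raise ConfigurationError(
                        "counties_per_state range must satisfy 1 <= lo <= hi"
                    )
        elif self.n_counties < self.n_states:
            raise ConfigurationError("need at least one county per state")


@dataclass
class SyntheticTruth:
    """Generating configuration plus the realized latent variables."""

    config: GeneratorConfig
    county_factors: pd.DataFrame  # columns: fips, f_baa, f_nhw
    state_factors: pd.DataFrame  # columns: state_id, g
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": _config_to_jsonable(self.config),
            "county_factors": self.county_factors.to_dict(orient="list"),
            "state_factors": self.state_factors.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return SyntheticTruth(
            config=_config_from_jsonable(payload["config"]),
            county_factors=pd.DataFrame(payload["county_factors"]),
            state_factors=pd.DataFrame(payload["state_factors"]),
            seed=payload["seed"],
        )


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    out = dataclasses.asdict(config)
    out["domain_score_cov"] = np.asarray(config.domain_score_cov).tolist()
    return out


def _config_from_jsonable(payload: dict) -> GeneratorConfig:
    payload = dict(payload)
    payload["domain_score_cov"] = np.asarray(payload["domain_score_cov"])
    if payload.get("counties_per_state") is not None and not isinstance(
        payload["counties_per_state"], int
    ):
        payload["counties_per_state"] = tuple(payload["counties_per_state"])
    payload["nonadh_model"] = NonadherenceModel(
        **{
            **payload["nonadh_model"],
            "nhw_coefs": tuple(payload["nonadh_model"]["nhw_coefs"]),
            "baa_coefs": tuple(payload["nonadh_model"]["baa_coefs"]),
            "clamp": tuple(payload["nonadh_model"]["clamp"]),
        }
    )
    payload["mortality_truth"] = JointModelTruth(**payload["mortality_truth"])
    payload["domain_score_mean"] = tuple(payload["domain_score_mean"])
    payload["demog_params"] = {
        k: tuple(v) for k, v in payload["demog_params"].items()
    }
    return GeneratorConfig(**payload)


def _state_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    S = config.n_states
    cps = config.counties_per_state
    if cps is None:
        base = config.n_counties // S
        extra = config.n_counties - base * S
        sizes = np.full(S, base, dtype=int)
        sizes[:extra] += 1
        return sizes
    if isinstance(cps, int):
        return np.full(S, cps, dtype=int)
    lo, hi = cps
    return rng.integers(lo, hi + 1, size=S)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a county table and its truth record from ``config``.

    Returns a DataFrame with the canonical CSV schema (one row per
    :class:`CountyRecord`) and a :class:`SyntheticTruth` holding the echoed
    configuration and the realized county/state latent factors.  The same
    config and seed always reproduce the same table bit-for-bit.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = _state_sizes(config, rng)
    n = int(sizes.sum())
    state_ids = [f"S{i:02d}" for i in range(config.n_states)]
    regions = config.region_assignment or _default_region_assignment(
        config.n_states
    )
    missing = [s for s in state_ids if s not in regions]
    if missing:
        raise ConfigurationError(f"region_assignment missing states: {missing}")

    state_idx = np.repeat(np.arange(config.n_states), sizes)
    fips = [f"{i + 1001:05d}" for i in range(n)]

    # Domain scores: multivariate normal with configured mean/covariance.
    scores = rng.multivariate_normal(
        np.asarray(config.domain_score_mean, dtype=float),
        np.asarray(config.domain_score_cov, dtype=float),
        size=n,
        method="cholesky",
    )

    # Demographics: independent normals clamped to the valid percent range.
    # Canonical column order keeps the RNG stream stable regardless of the
    # ordering of the configured dict (e.g. after a JSON round-trip).
    demog = {}
    for name in DEMOG_COLUMNS:
        mean, sd = config.demog_params[name]
        demog[name] = np.clip(rng.normal(mean, sd, size=n), 0.0, 100.0)

    # Non-adherence prevalence per race.
    nm = config.nonadh_model
    z_scores = np.column_stack([_standardize(scores[:, j]) for j in range(4)])
    prev = {}
    for race in RACES:
        coefs = np.asarray(
            nm.baa_coefs if race == "baa" else nm.nhw_coefs, dtype=float
        )
        state_sd = nm.baa_state_sd if race == "baa" else nm.nhw_state_sd
        county_sd = nm.baa_county_sd if race == "baa" else nm.nhw_county_sd
        u = rng.normal(0.0, state_sd, size=config.n_states)[state_idx]
        eps = rng.normal(0.0, county_sd, size=n)
        lin = nm.intercept(race) + z_scores @ coefs + u + eps
        if nm.scale == "logit":
            # intercept/coefs interpreted on logit(prev/100)
            p = 100.0 / (1.0 + np.exp(-lin))
        else:
            p = lin
        prev[race] = np.clip(p, nm.clamp[0], nm.clamp[1])

    # Latent factors for the mortality model.
    truth = config.mortality_truth
    sf = np.array([truth.sigma_f["baa"], truth.sigma_f["nhw"]])
    cov_f = np.array(
        [
            [sf[0] ** 2, truth.rho * sf[0] * sf[1]],
            [truth.rho * sf[0] * sf[1], sf[1] ** 2],
        ]
    )
    if np.all(sf > 0):
        f = rng.multivariate_normal(np.zeros(2), cov_f, size=n, method="cholesky")
    else:
        f = np.column_stack(
            [rng.normal(0.0, sf[0], size=n), rng.normal(0.0, sf[1], size=n)]
        )
    g = rng.normal(0.0, truth.sigma_g, size=config.n_states)

    # Standardized covariates entering the mortality linear predictor use the
    # realized sample mean/sd, mirroring what the fitting stage will do.
    z_cov = {
        "hb_score": z_scores[:, 0],
        "cc_score": z_scores[:, 1],
        "se_score": z_scores[:, 2],
        "pe_score": z_scores[:, 3],
        **{name: _standardize(demog[name]) for name in DEMOG_COLUMNS},
    }
    z_nonadh = {race: _standardize(prev[race]) for race in RACES}

    rates = {}
    for race in RACES:
        f_r = f[:, 0] if race == "baa" else f[:, 1]
        for disease in DISEASES:
            out = f"{race}_{disease}"
            beta = truth.beta[out]
            lin = np.full(n, truth.alpha[out])
            lin += beta.get("nonadh", 0.0) * z_nonadh[race]
            for name in (*DOMAIN_COLUMNS, *DEMOG_COLUMNS):
                lin += beta.get(name, 0.0) * z_cov[name]
            for m in DOMAIN_COLUMNS:
                gam = truth.gamma[out].get(m, 0.0)
                if gam != 0.0:
                    inter = _standardize(z_nonadh[race] * z_cov[m])
                    lin += gam * inter
            lin += truth.loading_f(race, disease) * f_r
            lin += truth.loading_g(out) * g[state_idx]
            lin += rng.normal(0.0, truth.sigma_resid[out], size=n)
            rates[f"{out}_rate"] = np.exp(lin)

    frame = pd.DataFrame(
        {
            "fips": fips,
            "state_id": [state_ids[s] for s in state_idx],
            "region": [regions[state_ids[s]] for s in state_idx],
            "baa_nonadh_pct": prev["baa"],
            "nhw_nonadh_pct": prev["nhw"],
            "hb_score": scores[:, 0],
            "cc_score": scores[:, 1],
            "se_score": scores[:, 2],
            "pe_score": scores[:, 3],
            **{name: demog[name] for name in DEMOG_COLUMNS},
            **{name: rates[name] for name in RATE_COLUMNS},
        },
        columns=list(CSV_COLUMNS),
    )

    truth_record = SyntheticTruth(
        config=config,
        county_factors=pd.DataFrame(
            {"fips": fips, "f_baa": f[:, 0], "f_nhw": f[:, 1]}
        ),
        state_factors=pd.DataFrame({"state_id": state_ids, "g": g}),
        seed=config.seed,
    )
    return frame, truth_record


def write_county_csv(records: pd.DataFrame | Sequence[CountyRecord], path) -> None:
    """Write county records to CSV with the canonical column order."""
    frame = _as_frame(records)
    frame.to_csv(path, index=False, columns=list(CSV_COLUMNS))


def read_county_csv(path) -> pd.DataFrame:
    """Read and validate a county CSV, preserving FIPS zero-padding."""
    try:
        frame = pd.read_csv(
            path, dtype={"fips": str, "state_id": str, "region": str}
        )
    except Exception as exc:  # malformed file
        raise CountyCSVError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CountyCSVError(f"missing column(s): {missing}")
    frame = frame[list(CSV_COLUMNS)]
    numeric = [c for c in CSV_COLUMNS if c not in ("fips", "state_id", "region")]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((frame.index[coerced.isna()])[0])
            raise CountyCSVError(f"non-numeric value in column {col!r}, row {row}")
        frame[col] = coerced.astype(float)
    dup = frame["fips"][frame["fips"].duplicated()]
    if len(dup):
        raise CountyCSVError(f"duplicate FIPS code(s): {sorted(set(dup))}")
    return frame.reset_index(drop=True)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def records_from_frame(frame: pd.DataFrame) -> list[CountyRecord]:
    """Typed row view of a county table."""
    return [CountyRecord(**row) for row in frame[list(CSV_COLUMNS)].to_dict("records")]
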