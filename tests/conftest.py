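"""Shared fixtures: small synthetic scenarios reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ahmdisparity.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_scenario():
    """150 counties / 10 states from the default generating law."""
    cfg = GeneratorConfig(n_states=10, n_counties=150, seed=7)
    frame, truth = generate_dataset(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def default_scenario():
    """The full-size default scenario: 875 counties / 38 states."""
    cfg = GeneratorConfig(seed=20211202)
    frame, truth = generate_dataset(cfg)
    return cfg, frame, truth


def make_hlm_records(
    n_counties: int,
    n_states: int,
    beta=(0.0, -0.2, -0.1, 0.0),
    sigma_state: float = 0.1,
    sigma_resid: float = 0.37,
    intercept: float = 1.37,
    seed: int = 0,
) -> pd.DataFrame:
    """County table whose PRR follows an exact random-intercept law.

    nHW non-adherence is constant, BAA non-adherence is the constant times
    ``y = intercept + z'beta + u_state + eps`` (z = standardized domain
    scores), so the county PRR equals y exactly and the HLM truth is known.
    """
    rng = np.random.default_rng(seed)
    state_idx = np.repeat(np.arange(n_states), -(-n_counties // n_states))[
        :n_counties
    ]
    scores = rng.standard_normal((n_counties, 4))
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    u = rng.normal(0.0, sigma_state, size=n_states)[state_idx]
    eps = rng.normal(0.0, sigma_resid, size=n_counties)
    y = intercept + z @ np.asarray(beta) + u + eps
    nhw = np.full(n_counties, 25.5)
    regions = np.array(["Midwest", "Northeast", "South", "West"])
    return pd.DataFrame(
        {
            "fips": [f"{i + 1001:05d}" for i in range(n_counties)],
            "state_id": [f"S{s:02d}" for s in state_idx],
            "region": regions[state_idx % 4],
            "baa_nonadh_pct": nhw * y,
            "nhw_nonadh_pct": nhw,
            "hb_score": scores[:, 0],
            "cc_score": scores[:, 1],
            "se_score": scores[:, 2],
            "pe_score": scores[:, 3],
            "pct_baa": rng.uniform(5, 40, n_counties),
            "pct_over65": rng.uniform(10, 25, n_counties),
            "pct_female": rng.uniform(48, 53, n_counties),
            "pct_rural": rng.uniform(0, 90, n_counties),
            "baa_hd_rate": np.full(n_counties, 200.0),
            "baa_st_rate": np.full(n_counties, 50.0),
            "nhw_hd_rate": np.full(n_counties, 150.0),
            "nhw_st_rate": np.full(n_counties, 40.0),
        }
    )
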