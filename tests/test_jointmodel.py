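"""Shared-component factor model: standardization, posterior summaries,
determinism, parameter recovery and simulation-based calibration of the
sampler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ahmdisparity.jointmodel import (
    JointModelSpec,
    MCMCSettings,
    PosteriorDraws,
    PriorSettings,
    SharedComponentFactorModel,
    _build_model_data,
    county_factor_report,
    interaction_effects,
    sample_posterior,
    standardize_covariates,
    summarize,
)
from ahmdisparity.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="module")
def fitted(small_scenario):
    """One moderately sized fit shared by the recovery/summary tests."""
    _, frame, truth = small_scenario
    model = SharedComponentFactorModel(
        chains=2, draws=500, warmup=500, random_state=5
    ).fit(frame)
    return frame, truth, model


def test_standardize_symmetric_triple_and_idempotence():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    z, stats_ = standardize_covariates(frame, ["a"])
    np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])
    assert stats_["a"] == (2.0, 1.0)
    z2, _ = standardize_covariates(z, ["a"])
    np.testing.assert_allclose(z2["a"], z["a"], atol=1e-12)


@given(
    st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40).filter(
        lambda v: np.std(v, ddof=1) > 1e-6
    )
)
@settings(max_examples=50, deadline=None)
def test_standardize_always_gives_mean_zero_sd_one(values):
    frame = pd.DataFrame({"x": values})
    z, _ = standardize_covariates(frame, ["x"])
    assert abs(z["x"].mean()) < 1e-10
    assert z["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_standardize_zero_variance_names_column():
    frame = pd.DataFrame({"pe_score": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="pe_score"):
        standardize_covariates(frame, ["pe_score"])


def test_summary_of_hand_countable_draws():
    draws = PosteriorDraws(
        scalars={"x": np.array([[-1.0, 1.0, 2.0, 3.0]])},
        factor_mean=np.zeros((1, 2)),
        factor_p_gt0=np.zeros((1, 2)),
        diff_mean=np.zeros((1, 2)),
        diff_p_gt0=np.zeros((1, 2)),
        fips=np.array(["01001"]),
        spec=JointModelSpec(),
        n_draws_total=4,
    )
    summary = summarize(draws)
    row = summary.param("x")
    assert row["mean"] == pytest.approx(1.25)
    assert row["p_gt0"] == pytest.approx(0.75)
    assert row["ci_low"] <= row["ci_high"]


def test_symmetric_draws_give_half_probability():
    rng = np.random.default_rng(0)
    sym = rng.standard_normal((2, 2000))
    draws = PosteriorDraws(
        scalars={"x": sym},
        factor_mean=np.zeros((1, 2)),
        factor_p_gt0=np.zeros((1, 2)),
        diff_mean=None,
        diff_p_gt0=None,
        fips=np.array(["01001"]),
        spec=JointModelSpec(),
        n_draws_total=4000,
    )
    row = summarize(draws).param("x")
    assert row["p_gt0"] == pytest.approx(0.5, abs=0.03)
    assert row["ci_low"] == pytest.approx(-row["ci_high"], abs=0.15)


def test_same_seed_gives_identical_draws():
    cfg = GeneratorConfig(n_states=4, n_counties=40, seed=2)
    frame, _ = generate_dataset(cfg)
    spec = JointModelSpec(mcmc=MCMCSettings(chains=2, draws=50, warmup=50, seed=9))
    a = sample_posterior(spec, frame)
    b = sample_posterior(spec, frame)
    for name in a.scalars:
        np.testing.assert_array_equal(a.scalars[name], b.scalars[name])
    np.testing.assert_array_equal(a.factor_mean, b.factor_mean)


def test_p_gt0_equals_counted_fraction_of_draws(fitted):
    _, _, model = fitted
    table = model.summary_.set_index("name")
    for name, arr in model.draws_.items():
        count = 0
        for chain in arr:
            for value in chain:
                if value > 0:
                    count += 1
        assert table.loc[name, "p_gt0"] == count / arr.size


def test_parameter_recovery_within_posterior_uncertainty(fitted):
    frame, truth, model = fitted
    mt = truth.config.mortality_truth
    table = model.summary_.set_index("name")
    for out in ("baa_hd", "baa_st", "nhw_hd", "nhw_st"):
        row = table.loc[f"{out}:nonadh"]
        assert abs(row["mean"] - mt.beta[out]["nonadh"]) < 4 * row["sd"]
        row_a = table.loc[f"{out}:intercept"]
        assert abs(row_a["mean"] - mt.alpha[out]) < 4 * row_a["sd"]
    rho_row = table.loc["rho"]
    assert rho_row["ci_low"] <= mt.rho <= rho_row["ci_high"]


def test_county_factor_estimates_track_realized_latents(fitted):
    frame, truth, model = fitted
    report = county_factor_report(model.posterior_)
    assert set(report.columns) == {"fips", "race", "factor_mean", "p_above_zero"}
    for race in ("baa", "nhw"):
        est = report[report["race"] == race].set_index("fips")["factor_mean"]
        real = truth.county_factors.set_index("fips")[f"f_{race}"]
        corr = np.corrcoef(est.loc[real.index], real)[0, 1]
        assert corr > 0.7
        # prior symmetry: factor means center on zero across counties
        assert abs(est.mean()) < 0.05
    # strongly positive realized factors are confidently flagged
    big = truth.county_factors.loc[
        truth.county_factors["f_baa"] > 2 * 0.3, "fips"
    ]
    baa = report[report["race"] == "baa"].set_index("fips")
    assert (baa.loc[big, "p_above_zero"] > 0.9).all()


def test_county_differences_reflect_race_gap(fitted):
    frame, truth, model = fitted
    diff = model.county_differences_
    hd = diff[diff["disease"] == "hd"]
    observed_gap = np.log(frame["baa_hd_rate"]) - np.log(frame["nhw_hd_rate"])
    corr = np.corrcoef(hd["diff_mean"], observed_gap)[0, 1]
    assert corr > 0.9


def test_constrained_loadings_reported_as_constant(fitted):
    _, _, model = fitted
    table = model.summary_.set_index("name")
    for name in ("lambda:baa_hd", "lambda:nhw_hd", "kappa:baa_hd"):
        assert table.loc[name, "mean"] == 1.0
        assert bool(table.loc[name, "constrained"])
        assert name not in model.draws_
    assert "lambda:baa_st" in model.draws_


def test_nonpositive_rate_errors_name_the_county(small_scenario):
    _, frame, _ = small_scenario
    bad = frame.copy()
    bad.loc[bad.index[2], "nhw_st_rate"] = 0.0
    with pytest.raises(ValueError, match=bad["fips"].iloc[2]):
        SharedComponentFactorModel(chains=1, draws=10, warmup=10).fit(bad)


def test_interaction_table_requires_interaction_fit(fitted):
    _, _, model = fitted
    with pytest.raises(ValueError, match="interaction"):
        interaction_effects(model.summary_obj_, model.spec())


def test_single_county_states_warn(small_scenario):
    _, frame, _ = small_scenario
    lonely = frame.copy()
    lonely.loc[lonely.index[-1], "state_id"] = "S99"
    with pytest.warns(UserWarning, match="single county"):
        _build_model_data(JointModelSpec(), lonely)


def test_simulation_based_calibration_of_sampler(small_scenario):
    """Data drawn from the model's own priors and refit must produce
    uniformly distributed posterior ranks of the generating values
    (chi-squared not rejected at 0.01) — a whole-sampler correctness check."""
    _, frame_full, _ = small_scenario
    frame = frame_full.iloc[:40].copy()
    priors = PriorSettings(coef_sd=0.5, sigma_scale=0.25)
    spec = JointModelSpec(priors=priors)
    data, _ = _build_model_data(spec, frame)
    n, O = data.y.shape
    tracked = ["baa_hd:nonadh", "rho", "sigma_f:baa", "sigma:nhw_st", "kappa:nhw_hd"]
    n_rep, n_draws = 50, 250
    ranks = {name: [] for name in tracked}
    rng = np.random.default_rng(2024)
    for rep in range(n_rep):
        truth = {}
        b = [rng.normal(0, priors.coef_sd, size=x.shape[1]) for x in data.X]
        lam_st = rng.normal(0, priors.coef_sd, size=2)
        kappa = np.concatenate([[1.0], rng.normal(0, priors.coef_sd, size=3)])
        sigma = np.abs(rng.normal(0, priors.sigma_scale, size=4)) + 1e-3
        sigma_f = np.abs(rng.normal(0, priors.sigma_scale, size=2)) + 1e-3
        rho = rng.uniform(-1, 1)
        sigma_g = abs(rng.normal(0, priors.sigma_scale)) + 1e-3
        cov = np.array(
            [
                [sigma_f[0] ** 2, rho * sigma_f[0] * sigma_f[1]],
                [rho * sigma_f[0] * sigma_f[1], sigma_f[1] ** 2],
            ]
        )
        f = rng.multivariate_normal(np.zeros(2), cov, size=n)
        g = rng.normal(0, sigma_g, size=data.n_states)
        lam = np.array([1.0, lam_st[0], 1.0, lam_st[1]])
        race = np.array([0, 0, 1, 1])
        y = np.empty((n, O))
        for o in range(O):
            y[:, o] = (
                data.X[o] @ b[o]
                + lam[o] * f[:, race[o]]
                + kappa[o] * g[data.state_idx]
                + rng.normal(0, sigma[o], size=n)
            )
        truth["baa_hd:nonadh"] = b[0][data.names[0].index("nonadh")]
        truth["rho"] = rho
        truth["sigma_f:baa"] = sigma_f[0]
        truth["sigma:nhw_st"] = sigma[3]
        truth["kappa:nhw_hd"] = kappa[2]
        rep_frame = frame.copy()
        for o, out in enumerate(("baa_hd", "baa_st", "nhw_hd", "nhw_st")):
            rep_frame[f"{out}_rate"] = np.exp(y[:, o])
        rep_spec = JointModelSpec(
            priors=priors,
            mcmc=MCMCSettings(chains=1, draws=n_draws, warmup=200, seed=rep),
        )
        draws = sample_posterior(rep_spec, rep_frame)
        for name in tracked:
            ranks[name].append(int(np.sum(draws.scalars[name] < truth[name])))
    n_bins = 5
    for name in tracked:
        binned = np.bincount(
            np.minimum(
                np.array(ranks[name]) * n_bins // (n_draws + 1), n_bins - 1
            ),
            minlength=n_bins,
        )
        _, pvalue = stats.chisquare(binned)
        assert pvalue > 0.01, f"SBC rank non-uniformity for {name}: {binned}"
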