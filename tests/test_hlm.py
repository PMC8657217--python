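"""Random-intercept HLM: recovery against known truth, closed-form toys,
the M1-M4 sequence and the variance-component pseudo-R^2."""

import numpy as np
import pytest
from conftest import make_hlm_records

from ahmdisparity.hlm import (
    fit_null,
    fit_random_intercept,
    model_sequence,
    pseudo_r2,
    RandomInterceptModel,
)


def test_fixed_effects_recovered_when_state_variance_is_zero():
    frame = make_hlm_records(
        1000, 20, beta=(0.0, -0.2, -0.1, 0.0), sigma_state=0.0,
        sigma_resid=0.3, seed=5,
    )
    X = np.column_stack(
        [
            (frame[c] - frame[c].mean()) / frame[c].std(ddof=1)
            for c in ("hb_score", "cc_score", "se_score", "pe_score")
        ]
    )
    y = frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]
    fit = fit_random_intercept(
        y, X, frame["state_id"], names=["hb", "cc", "se", "pe"]
    )
    assert fit.sigma2_state < 0.005
    for name, truth in zip(["hb", "cc", "se", "pe"], [0.0, -0.2, -0.1, 0.0]):
        assert abs(fit.coef(name) - truth) < 3 * fit.se(name) + 1e-9


def test_exact_linear_outcome_gives_exact_coefficients_zero_variance():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 2))
    y = 1.5 + X @ np.array([2.0, -1.0])
    groups = np.repeat(["a", "b", "c"], 20)
    fit = fit_random_intercept(y, X, groups)
    assert fit.coef("intercept") == pytest.approx(1.5, abs=1e-8)
    assert fit.coef("x0") == pytest.approx(2.0, abs=1e-8)
    assert fit.coef("x1") == pytest.approx(-1.0, abs=1e-8)
    assert fit.sigma2_state == 0.0 and fit.sigma2_resid == 0.0


def test_balanced_two_state_intercept_equals_grand_mean():
    """Six-row balanced toy: the ML fixed intercept of the null model is
    the grand mean (states weighted equally by balance)."""
    y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
    groups = np.array(["A", "A", "A", "B", "B", "B"])
    fit = fit_null(y, groups)
    assert fit.coef("intercept") == pytest.approx(y.mean(), abs=1e-6)
    assert fit.n_states == 2


def test_sklearn_estimator_interface():
    frame = make_hlm_records(200, 8, seed=6)
    X = frame[["cc_score", "se_score"]].to_numpy()
    y = (frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]).to_numpy()
    est = RandomInterceptModel().fit(X, y, groups=frame["state_id"])
    assert est.coef_.shape == (2,)
    assert est.sigma2_group_ >= 0 and est.sigma2_resid_ > 0
    pred = est.predict(X)
    assert pred.shape == y.shape
    assert est.get_params() == {"reml": False}


def test_rank_deficient_design_names_collinear_column():
    rng = np.random.default_rng(1)
    x0 = rng.standard_normal(50)
    X = np.column_stack([x0, 2.0 * x0])
    y = rng.standard_normal(50)
    groups = np.repeat(["a", "b"], 25)
    with pytest.raises(ValueError, match="x1"):
        fit_random_intercept(y, X, groups)


def test_single_state_falls_back_to_ols_with_warning():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 1))
    y = 1.0 + 0.5 * X[:, 0] + rng.normal(0, 0.1, 40)
    with pytest.warns(UserWarning, match="OLS"):
        fit = fit_random_intercept(y, X, np.repeat("only", 40))
    assert fit.method == "ols"
    assert fit.sigma2_state == 0.0


def test_pseudo_r2_endpoints_and_mismatch():
    frame = make_hlm_records(300, 10, seed=3)
    y = frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]
    null = fit_null(y, frame["state_id"])
    assert pseudo_r2(null, null).value == pytest.approx(0.0)
    null_short = fit_null(y[:100], frame["state_id"][:100])
    with pytest.raises(ValueError, match="different data"):
        pseudo_r2(null, null_short)


def test_pseudo_r2_matches_analytic_variance_share():
    """Scenario built so standardized covariates explain 25% of the total
    PRR variance: pseudo-R^2 lands within 0.03 of 0.25 at n = 5000."""
    beta = (0.0, -0.2, -0.1, 0.0)  # sum beta^2 = 0.05
    frame = make_hlm_records(
        5000, 38, beta=beta, sigma_state=0.1, sigma_resid=np.sqrt(0.14),
        seed=12, intercept=3.0,
    )
    table, fits = model_sequence(frame)
    share = 0.05 / (0.05 + 0.01 + 0.14)
    assert table.attrs["pseudo_r2"]["M3"] == pytest.approx(share, abs=0.03)


def test_pseudo_r2_near_zero_when_outcome_independent_of_covariates():
    frame = make_hlm_records(
        2000, 20, beta=(0, 0, 0, 0), sigma_state=0.0, sigma_resid=0.3, seed=4
    )
    table, _ = model_sequence(frame)
    assert abs(table.attrs["pseudo_r2"]["M3"]) < 0.02


def test_model_sequence_recovers_generating_coefficients():
    frame = make_hlm_records(
        2000, 38, beta=(0.0, -0.2, -0.1, 0.0), sigma_state=0.1,
        sigma_resid=0.3, seed=9, intercept=3.0,
    )
    table, fits = model_sequence(frame)
    m4 = fits["M4"]
    for domain, truth in zip(
        ("hb_score", "cc_score", "se_score", "pe_score"),
        (0.0, -0.2, -0.1, 0.0),
    ):
        assert abs(m4.coef(domain) - truth) < 3 * m4.se(domain)
    # roster checks
    assert set(fits["M1:hb_score"].fixed_effects) == {"intercept", "hb_score"}
    assert set(fits["M2:hb_score"].fixed_effects) == {
        "intercept", "hb_score", "pct_over65",
    }
    assert len(fits["M4"].fixed_effects) == 9
    # star convention: strong truth effects are flagged
    row_cc = table.set_index("domain").loc["cc_score"]
    assert row_cc["m4_star"] in ("*", "**")
    assert set(table.columns) == {
        "domain",
        *(f"m{i}_{k}" for i in range(1, 5) for k in ("beta", "star")),
    }


def test_standardization_rescales_coefficients_but_not_fit_quality():
    frame = make_hlm_records(800, 10, seed=13)
    y = (frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]).to_numpy()
    X = frame[["cc_score", "se_score"]].to_numpy()
    groups = frame["state_id"].to_numpy()
    raw = fit_random_intercept(y, X, groups, names=["cc", "se"])
    sds = X.std(axis=0, ddof=1)
    std = fit_random_intercept(
        y, (X - X.mean(axis=0)) / sds, groups, names=["cc", "se"]
    )
    for name, sd in zip(["cc", "se"], sds):
        assert std.coef(name) == pytest.approx(raw.coef(name) * sd, rel=1e-4)
        assert std.pvalue(name) == pytest.approx(raw.pvalue(name), abs=1e-6)
    assert std.loglik == pytest.approx(raw.loglik, abs=1e-4)
    null = fit_null(y, groups)
    assert pseudo_r2(null, std).value == pytest.approx(
        pseudo_r2(null, raw).value, abs=1e-6
    )


def test_pseudo_r2_invariant_to_affine_transform_of_outcome():
    frame = make_hlm_records(600, 12, seed=14)
    y = (frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]).to_numpy()
    X = frame[["cc_score"]].to_numpy()
    groups = frame["state_id"].to_numpy()
    r2 = pseudo_r2(
        fit_null(y, groups), fit_random_intercept(y, X, groups)
    ).value
    y2 = 3.0 * y - 7.0
    r2_affine = pseudo_r2(
        fit_null(y2, groups), fit_random_intercept(y2, X, groups)
    ).value
    assert r2_affine == pytest.approx(r2, abs=1e-4)


def test_hlm_matches_ols_when_no_state_effect():
    import statsmodels.api as sm

    frame = make_hlm_records(5000, 25, sigma_state=0.0, seed=15)
    y = (frame["baa_nonadh_pct"] / frame["nhw_nonadh_pct"]).to_numpy()
    X = frame[["cc_score", "se_score"]].to_numpy()
    fit = fit_random_intercept(y, X, frame["state_id"], names=["cc", "se"])
    ols = sm.OLS(y, sm.add_constant(X)).fit()
    assert abs(fit.coef("cc") - ols.params[1]) < 0.01
    assert abs(fit.coef("se") - ols.params[2]) < 0.01
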