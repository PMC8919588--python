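"""GLM suite vs statsmodels oracles; stepwise marginality; Tukey contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from petrelmig.glm import (
    GLMError,
    anova_drop,
    build_design,
    emmeans_tukey,
    fit_glm,
    removable_terms,
    stepwise_backward,
)


def emd_like_table(n=400, seed=0, b0=1862.0, b_same=-1287.0, b_diff=2.15, interact=0.0):
    rng = np.random.default_rng(seed)
    same = rng.integers(0, 2, n)
    diff = rng.uniform(0, 180, n)
    mu = b0 + b_same * same + b_diff * diff + interact * same * diff
    mu = np.maximum(mu, 50.0)
    shape = 8.0
    y = rng.gamma(shape, mu / shape)
    return pd.DataFrame({"emd_km": y, "same_individual": same, "departure_diff_days": diff})


SM_FAMILIES = {
    ("gamma", "identity"): sm.families.Gamma(sm.families.links.Identity()),
    ("gamma", "log"): sm.families.Gamma(sm.families.links.Log()),
    ("binomial", "log"): sm.families.Binomial(sm.families.links.Log()),
    ("gaussian", "identity"): sm.families.Gaussian(),
}


@pytest.mark.parametrize("family, link", list(SM_FAMILIES))
def test_coefficients_match_statsmodels(family, link):
    rng = np.random.default_rng(1)
    n = 300
    x1 = rng.uniform(0, 1, n)
    x2 = rng.integers(0, 2, n)
    eta = 0.5 + 0.8 * x1 - 0.6 * x2
    if family == "gamma":
        mu = eta if link == "identity" else np.exp(eta - 1.0)
        y = rng.gamma(10.0, np.maximum(mu, 0.05) / 10.0)
    elif family == "binomial":
        mu = np.exp(-0.2 - 0.8 * x1 - 0.4 * x2)
        y = rng.binomial(1, np.clip(mu, 0.01, 0.99)).astype(float)
        y = np.clip(mu + rng.normal(0, 0.05, n), 1e-3, 1 - 1e-3)  # BA-like proportions
    else:
        y = eta + rng.normal(0, 0.3, n)
    tbl = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    fit = fit_glm(tbl, "y", ["x1", "x2"], family=family, link=link)
    X = sm.add_constant(tbl[["x1", "x2"]].to_numpy())
    sm_fit = sm.GLM(y, X, family=SM_FAMILIES[(family, link)]).fit(
        start_params=fit.params, scale="X2" if family != "binomial" else None
    )
    np.testing.assert_allclose(fit.params, sm_fit.params, rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(fit.bse, sm_fit.bse, rtol=1e-4)
    assert fit.deviance == pytest.approx(sm_fit.deviance, rel=1e-6)


def test_gaussian_exact_fit_zero_deviance():
    tbl = pd.DataFrame({"y": [1.0, 3.0, 5.0, 7.0], "x": [0.0, 1.0, 2.0, 3.0]})
    fit = fit_glm(tbl, "y", ["x"], family="gaussian", link="identity")
    assert fit.deviance == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.params, [1.0, 2.0], atol=1e-10)


def test_similarity_style_coefficients_recovered_within_3se():
    tbl = emd_like_table(n=600, seed=2)
    fit = fit_glm(tbl, "emd_km", ["same_individual", "departure_diff_days"],
                  family="gamma", link="identity")
    truth = {"same_individual": -1287.0, "departure_diff_days": 2.15, "(Intercept)": 1862.0}
    for name, true_val in truth.items():
        k = fit.columns.index(name)
        assert abs(fit.params[k] - true_val) < 3 * fit.bse[k]


def test_gamma_identity_requires_positive_response():
    tbl = pd.DataFrame({"y": [1.0, -2.0, 3.0], "x": [0.0, 1.0, 2.0]})
    with pytest.raises(GLMError, match="positive"):
        fit_glm(tbl, "y", ["x"], family="gamma", link="identity")


def test_categorical_design_and_interaction_columns():
    tbl = pd.DataFrame(
        {"y": np.arange(6, dtype=float), "g": list("ababab"), "x": np.linspace(0, 1, 6)}
    )
    d = build_design(tbl, ["g", "x", "g:x"])
    assert d.columns == ["(Intercept)", "g[b]", "x", "g[b]:x"]
    np.testing.assert_allclose(d.X[:, 1] * d.X[:, 2], d.X[:, 3])


def test_removable_respects_marginality():
    terms = ["same_individual", "departure_diff_days", "same_individual:departure_diff_days"]
    assert removable_terms(terms) == ["same_individual:departure_diff_days"]
    assert set(removable_terms(["a", "b"])) == {"a", "b"}


def test_stepwise_drops_null_interaction_keeps_mains():
    tbl = emd_like_table(n=800, seed=3, interact=0.0)
    full = fit_glm(
        tbl, "emd_km",
        ["same_individual", "departure_diff_days", "same_individual:departure_diff_days"],
        family="gamma", link="identity",
    )
    reduced, log = stepwise_backward(full, alpha=0.05)
    assert "same_individual:departure_diff_days" not in reduced.terms
    assert "same_individual" in reduced.terms
    assert "departure_diff_days" in reduced.terms
    assert log and log[0]["dropped"] == "same_individual:departure_diff_days"


def test_stepwise_keeps_all_when_significant():
    tbl = emd_like_table(n=800, seed=4, interact=6.0)
    full = fit_glm(
        tbl, "emd_km",
        ["same_individual", "departure_diff_days", "same_individual:departure_diff_days"],
        family="gamma", link="identity",
    )
    reduced, log = stepwise_backward(full, alpha=0.05)
    assert reduced.terms == full.terms and not log


def test_anova_drop_agrees_with_f_test_direction():
    tbl = emd_like_table(n=500, seed=5)
    fit = fit_glm(tbl, "emd_km", ["same_individual", "departure_diff_days"],
                  family="gamma", link="identity")
    assert anova_drop(fit, "same_individual") < 1e-6


def stage_table(n_per=40, seed=0, effects=None):
    rng = np.random.default_rng(seed)
    levels = ["whole"] + [f"s{k}" for k in range(1, 7)]
    effects = effects or {lv: 500.0 + 60.0 * i for i, lv in enumerate(levels)}
    rows = []
    for lv in levels:
        mu = effects[lv]
        y = rng.gamma(6.0, mu / 6.0, n_per)
        for v in y:
            rows.append({"emd_km": v, "stage_label": lv,
                         "departure_diff_days": rng.uniform(0, 100)})
    return pd.DataFrame(rows)


def test_emmeans_seven_levels_gives_21_contrasts_adjusted_ge_raw():
    tbl = stage_table()
    fit = fit_glm(tbl, "emd_km", ["stage_label", "departure_diff_days"],
                  family="gamma", link="identity")
    con = emmeans_tukey(fit, "stage_label", covariate_values={"departure_diff_days": 50.0})
    assert len(con) == 21
    assert (con["p_adjusted"] >= con["p_raw"] - 1e-12).all()
    assert con["p_adjusted"].between(0, 1).all()


def test_emmeans_two_level_factor_unadjusted():
    tbl = emd_like_table(n=300, seed=6).assign(
        grp=lambda d: np.where(d.same_individual == 1, "w", "b")
    )
    fit = fit_glm(tbl, "emd_km", ["grp", "departure_diff_days"], family="gamma", link="identity")
    con = emmeans_tukey(fit, "grp")
    assert len(con) == 1
    assert con.loc[0, "p_adjusted"] == pytest.approx(con.loc[0, "p_raw"], abs=1e-12)
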