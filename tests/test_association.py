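"""Association analyses: OLS oracles, invariances, and the random-intercept
AR(1) mixed model (validated against nlme::lme on a frozen fixture)."""

import numpy as np
import pandas as pd
import pytest

from phenostates.association import (
    bonferroni_adjust,
    fit_comorbidity_model,
    fit_lmm_ar1,
    regress_transitions,
)
from phenostates.synthetic_cohort import (
    ComorbidityLink,
    default_config,
    simulate_comorbidity,
    simulate_dataset,
)


class TestBonferroni:
    def test_five_models(self):
        assert bonferroni_adjust(0.05, 5) == 0.01

    def test_single_test_identity(self):
        assert bonferroni_adjust(0.037, 1) == 0.037

    def test_two_tests(self):
        assert bonferroni_adjust(0.05, 2) == 0.025

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.05, 0)


def make_dyn(rng, n, effect=0.0, female=None):
    """Subject transition matrices with a female shift on the (0,1) cell."""
    if female is None:
        female = rng.binomial(1, 0.5, size=n)
    base = np.array([[0.85, 0.08, 0.07], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    gammas = np.empty((n, 3, 3))
    for i in range(n):
        logits = np.log(base[:, 1:] / base[:, :1]) + rng.normal(0, 0.3, size=(3, 2))
        logits[0, 0] += effect * female[i]
        ex = np.exp(np.concatenate([np.zeros((3, 1)), logits], axis=1))
        gammas[i] = ex / ex.sum(axis=1, keepdims=True)
    ids = [f"S{i}" for i in range(n)]
    cov = pd.DataFrame({"subject_id": ids, "female": female,
                        "age": rng.normal(12, 2.3, n).round(1),
                        "ethnoracial_minority": rng.binomial(1, 0.3, n)})
    return (ids, gammas), cov


def test_ols_matches_closed_form_normal_equations():
    rng = np.random.default_rng(50)
    dyn, cov = make_dyn(rng, 16)
    table = regress_transitions(dyn, cov)
    X = np.column_stack([np.ones(16), cov[["female", "age", "ethnoracial_minority"]]])
    for (i, j) in [(0, 1), (2, 2)]:
        y = dyn[1][:, i, j]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rows = table[(table.from_state == i) & (table.to_state == j)]
        got = rows.set_index("predictor")["b"]
        assert got["female"] == pytest.approx(beta[1], rel=1e-10)
        assert got["age"] == pytest.approx(beta[2], rel=1e-10)
        assert got["ethnoracial_minority"] == pytest.approx(beta[3], rel=1e-10)


def test_ols_invariant_to_subject_order_and_age_rescaling():
    rng = np.random.default_rng(51)
    dyn, cov = make_dyn(rng, 20)
    base = regress_transitions(dyn, cov)
    # subject order
    perm = rng.permutation(20)
    shuffled = ([dyn[0][i] for i in perm], dyn[1][perm])
    again = regress_transitions(shuffled, cov)
    pd.testing.assert_frame_equal(
        base.sort_values(["from_state", "to_state", "predictor"]).reset_index(drop=True),
        again.sort_values(["from_state", "to_state", "predictor"]).reset_index(drop=True),
    )
    # affine rescaling of age: months instead of years
    cov2 = cov.assign(age=cov["age"] * 12)
    scaled = regress_transitions(dyn, cov2)
    b0 = base[base.predictor == "age"].reset_index()
    b1 = scaled[scaled.predictor == "age"].reset_index()
    assert np.allclose(b1["b"], b0["b"] / 12, rtol=1e-10)
    assert np.allclose(b1["beta_std"], b0["beta_std"], rtol=1e-8)
    assert np.allclose(b1["p"], b0["p"], rtol=1e-8)


def test_constant_outcome_warns_and_zeroes():
    rng = np.random.default_rng(52)
    dyn, cov = make_dyn(rng, 12)
    gammas = dyn[1].copy()
    gammas[:, 0, :] = [0.8, 0.1, 0.1]
    with pytest.warns(UserWarning, match="constant outcome"):
        table = regress_transitions((dyn[0], gammas), cov)
    rows = table[(table.from_state == 0) & (table.to_state == 0)]
    assert (rows["b"] == 0).all() and (rows["p"] == 1).all()


def test_collinear_predictors_rejected():
    rng = np.random.default_rng(53)
    dyn, cov = make_dyn(rng, 12)
    cov = cov.assign(ethnoracial_minority=cov["female"])  # exact collinearity
    with pytest.raises(ValueError, match="collinear"):
        regress_transitions(dyn, cov)


def test_injected_female_effect_detected():
    rng = np.random.default_rng(54)
    dyn, cov = make_dyn(rng, 120, effect=0.3)
    table = regress_transitions(dyn, cov)
    row = table[(table.from_state == 0) & (table.to_state == 1)
                & (table.predictor == "female")].iloc[0]
    assert row["b"] > 0
    assert row["p"] < 0.05


# ---------------------------------------------------------------------------
# mixed model with AR(1) residuals


def lmm_fixture():
    """Synthetic panel frozen against an external mixed-model fit."""
    rng = np.random.default_rng(42)
    n, T = 25, 30
    rows = []
    for i in range(n):
        b = rng.normal(0, 0.7)
        x1 = rng.binomial(1, 0.5)
        x2 = rng.normal(12, 2)
        e = np.empty(T)
        e[0] = rng.normal(0, 0.8)
        for t in range(1, T):
            e[t] = 0.4 * e[t - 1] + rng.normal(0, 0.8 * np.sqrt(1 - 0.16))
        xt = rng.binomial(1, 0.3, T)
        y = 2.0 + 1.5 * xt + 0.5 * x1 - 0.05 * x2 + b + e
        for t in range(T):
            rows.append((f"S{i}", t + 1, y[t], xt[t], x1, x2))
    return pd.DataFrame(rows, columns=["subject_id", "week", "y", "xt", "x1", "x2"])


def test_lmm_ar1_matches_external_reference():
    """Estimates frozen from nlme::lme(..., correlation=corAR1, method='ML')
    on the identical fixture."""
    res = fit_lmm_ar1(lmm_fixture(), "y", ["xt", "x1", "x2"])
    assert res.converged
    expected = {"intercept": 1.08968194, "xt": 1.60240860,
                "x1": 0.77403796, "x2": 0.01239355}
    for name, val in expected.items():
        assert res.params[name] == pytest.approx(val, abs=2e-4)
    assert res.rho == pytest.approx(0.477552, abs=2e-3)
    assert res.tau2 == pytest.approx(0.3782574, rel=2e-3)
    assert res.sigma2 == pytest.approx(0.7100198, rel=2e-3)
    assert res.loglik == pytest.approx(-866.2658, abs=2e-3)


def test_lmm_rho_null_when_no_autocorrelation():
    rng = np.random.default_rng(55)
    rows = []
    for i in range(30):
        b = rng.normal(0, 0.5)
        for t in range(40):
            rows.append((f"S{i}", t + 1, 1.0 + b + rng.normal(0, 1.0)))
    df = pd.DataFrame(rows, columns=["subject_id", "week", "y"])
    res = fit_lmm_ar1(df, "y", [])
    assert abs(res.rho) < 0.08  # ~2 SE of a lag-1 ACF at n=1200


def test_freeing_rho_never_lowers_loglik():
    df = lmm_fixture()
    free = fit_lmm_ar1(df, "y", ["xt", "x1", "x2"])
    fixed = fit_lmm_ar1(df, "y", ["xt", "x1", "x2"], fix_rho=0.0)
    assert free.loglik >= fixed.loglik - 1e-6


# ---------------------------------------------------------------------------
# comorbidity models end-to-end on generator truth


def truth_states_frame(truth):
    labels = np.array(["low", "elevated", "cognitive_physical"])
    n, T = truth.latent_paths.shape
    return pd.DataFrame({
        "subject_id": np.repeat(truth.covariates["subject_id"].to_numpy(), T),
        "week": np.tile(np.arange(1, T + 1), n),
        "state_label": labels[truth.latent_paths.ravel()],
    })


def test_comorbidity_coefficient_recovery():
    """An injected elevated-state effect of +1.5 is recovered within ±0.3
    averaged across replicates."""
    est = []
    for rep in range(8):
        cfg = default_config(n_subjects=30, n_weeks=60, seed=600 + rep)
        cfg.comorbidity_link["ODD"] = ComorbidityLink(
            intercept=2.5, coef_elevated=1.5, coef_cogphys=0.0,
            subject_intercept_sd=0.4, ar1_rho=0.4, noise_sd=0.5)
        _, cov, truth = simulate_dataset(cfg)
        com = simulate_comorbidity(truth, cfg)
        result = fit_comorbidity_model(
            com, truth_states_frame(truth),
            (list(truth.covariates["subject_id"]), truth.subject_transition),
            cov, disorders=["ODD"],
            gamma_state_labels=("low", "elevated", "cognitive_physical"))
        est.append(result.tables["ODD"].loc["elevated", "b"])
    assert np.mean(est) == pytest.approx(1.5, abs=0.3)


def test_comorbidity_null_links_near_zero():
    cfg = default_config(n_subjects=30, n_weeks=60, seed=700)
    for link in cfg.comorbidity_link.values():
        link.coef_elevated = 0.0
        link.coef_cogphys = 0.0
    _, cov, truth = simulate_dataset(cfg)
    com = simulate_comorbidity(truth, cfg)
    result = fit_comorbidity_model(
        com, truth_states_frame(truth),
        (list(truth.covariates["subject_id"]), truth.subject_transition),
        cov, gamma_state_labels=("low", "elevated", "cognitive_physical"))
    assert result.adjusted_alpha == 0.01
    within = [
        abs(tab.loc[state, "b"]) < 2.5 * tab.loc[state, "se"]
        for tab in result.tables.values()
        for state in ("elevated", "cognitive_physical")
    ]
    assert np.mean(within) >= 0.8


def test_comorbidity_ar1_estimated_near_zero_for_independent_noise():
    cfg = default_config(n_subjects=25, n_weeks=50, seed=701)
    for link in cfg.comorbidity_link.values():
        link.ar1_rho = 0.0
        link.noise_sd = 0.8
    _, cov, truth = simulate_dataset(cfg)
    com = simulate_comorbidity(truth, cfg)
    result = fit_comorbidity_model(
        com, truth_states_frame(truth),
        (list(truth.covariates["subject_id"]), truth.subject_transition),
        cov, disorders=["ADHD"],
        gamma_state_labels=("low", "elevated", "cognitive_physical"))
    assert abs(result.fits["ADHD"].rho) < 0.1
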