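"""The mixed-model fitter: likelihood, Wald, LRT, predictions, ladder."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gengrad import (ModelSpec, default_config, fit_lmm, information_criteria,
                     lrt, model_ladder, predict_subjects, simulate_dataset,
                     simulate_worked_example, wald_tests)
from gengrad.lmm import _columns


def _dense_neg2ll(data, spec, beta, psi, sigma2):
    """Independent oracle: sum of dense multivariate-normal log-densities."""
    total = 0.0
    for _, sub in data.groupby("subject"):
        d = sub["d"].to_numpy(float)
        u = sub["u"].to_numpy(float)
        X = _columns(spec.fixed_terms, d, u)
        Z = _columns(spec.random_terms, d, u)
        V = Z @ psi @ Z.T + sigma2 * np.eye(len(d))
        total += stats.multivariate_normal.logpdf(sub["y"], mean=X @ beta,
                                                  cov=V)
    return -2.0 * total


# --- specs ------------------------------------------------------------------

def test_spec_formula_parsing_and_hierarchy():
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d")
    assert spec.fixed_terms == ("1", "d", "u", "d:u")
    assert spec.random_terms == ("1", "d")
    with pytest.raises(ValueError, match="lower-order"):
        ModelSpec.from_formula("1+d2", "1")  # d2 without d
    with pytest.raises(ValueError, match="lower-order"):
        ModelSpec.from_formula("1+d+u+d2:u", "1")
    with pytest.raises(ValueError):
        ModelSpec.from_formula("1+d", "1+d2")  # random d2 without d
    assert ModelSpec.from_formula("1+d", "1").is_nested_in(
        ModelSpec.from_formula("1+d+u+d:u", "1+d"))


# --- likelihood -------------------------------------------------------------

def test_deviance_matches_dense_mvn_oracle(small_dataset):
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML")
    fit = fit_lmm(small_dataset, spec)
    oracle = _dense_neg2ll(small_dataset, spec, fit.beta, fit.psi, fit.sigma2)
    assert fit.deviance == pytest.approx(oracle, rel=1e-8)


def test_deviance_oracle_tiny_fixture():
    # 2 subjects x 3 observations; checks the profiled machinery end to end
    data = pd.DataFrame({"subject": [0, 0, 0, 1, 1, 1],
                         "d": [0.0, 1, 2, 0, 1, 2],
                         "u": [2.0] * 3 + [7.0] * 3,
                         "y": [1.0, 2.0, 2.5, 4.0, 3.0, 5.0]})
    spec = ModelSpec.from_formula("1+d", "1", "ML")
    fit = fit_lmm(data, spec)
    oracle = _dense_neg2ll(data, spec, fit.beta, fit.psi, fit.sigma2)
    assert fit.deviance == pytest.approx(oracle, rel=1e-8)


def test_empty_random_part_reduces_to_ols(small_dataset):
    spec = ModelSpec.from_formula("1+d+u", "", "ML")
    fit = fit_lmm(small_dataset, spec)
    X = _columns(spec.fixed_terms, small_dataset["d"].to_numpy(float),
                 small_dataset["u"].to_numpy(float))
    y = small_dataset["y"].to_numpy(float)
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.beta, beta_ols, atol=1e-10)
    resid = y - X @ beta_ols
    s2 = resid @ resid / len(y)
    ll = -0.5 * len(y) * (1 + math.log(2 * math.pi * s2))
    assert fit.loglik == pytest.approx(ll, rel=1e-10)


def test_ml_fit_matches_statsmodels(small_dataset):
    smf = pytest.importorskip("statsmodels.formula.api")
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML")
    fit = fit_lmm(small_dataset, spec)
    df = small_dataset.assign(du=small_dataset.d * small_dataset.u)
    m = smf.mixedlm("y ~ d + u + du", df, groups=df["subject"], re_formula="~d")
    ref = m.fit(reml=False, method="lbfgs", maxiter=500)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
    assert np.allclose(fit.beta, ref.fe_params.values, atol=1e-4)
    assert np.allclose(fit.se, ref.bse_fe.values, atol=1e-4)


def test_reml_fit_matches_statsmodels(small_dataset):
    smf = pytest.importorskip("statsmodels.formula.api")
    spec = ModelSpec.from_formula("1+d", "1+d", "REML")
    fit = fit_lmm(small_dataset, spec)
    m = smf.mixedlm("y ~ d", small_dataset, groups=small_dataset["subject"],
                    re_formula="~d")
    ref = m.fit(reml=True, method="lbfgs", maxiter=500)
    assert np.allclose(fit.beta, ref.fe_params.values, atol=1e-4)
    assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)


def test_parameter_recovery_from_reference_generator():
    """n = 2000 subjects: fixed effects within 3 SE, variances within 5%."""
    cfg = default_config(n_subjects=2000, gamma11=0.10, seed=4)
    data = simulate_dataset(cfg, np.random.default_rng(4))
    fit = fit_lmm(data, ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML"))
    truth = {"1": cfg.gamma00, "d": cfg.gamma10, "u": cfg.gamma01,
             "d:u": cfg.gamma11}
    for term, val in truth.items():
        i = fit.fixed_names.index(term)
        assert abs(fit.beta[i] - val) < 3 * fit.se[i], term
    assert fit.psi[0, 0] == pytest.approx(cfg.tau00, rel=0.05)
    assert fit.psi[1, 1] == pytest.approx(cfg.tau11, rel=0.05)
    assert fit.sigma2 == pytest.approx(cfg.sigma2_eps, rel=0.05)


def test_shift_invariance_of_likelihood(small_dataset):
    """Translating d changes the intercept but not deviance, sigma2 or
    the d:u Wald p (likelihood reparameterization invariance)."""
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML")
    fit = fit_lmm(small_dataset, spec)
    shifted = small_dataset.assign(d=small_dataset["d"] - 4.5)
    fit2 = fit_lmm(shifted, spec)
    assert fit2.deviance == pytest.approx(fit.deviance, abs=1e-5)
    assert fit2.sigma2 == pytest.approx(fit.sigma2, rel=1e-4)
    assert fit2.coef_p("d:u") == pytest.approx(fit.coef_p("d:u"), abs=1e-5)
    assert fit2.coef("1") != pytest.approx(fit.coef("1"))


# --- Wald -------------------------------------------------------------------

def test_wald_se_matches_dense_information_matrix(small_dataset):
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML")
    fit = fit_lmm(small_dataset, spec)
    info = np.zeros((4, 4))
    for _, sub in small_dataset.groupby("subject"):
        d = sub["d"].to_numpy(float)
        u = sub["u"].to_numpy(float)
        X = _columns(spec.fixed_terms, d, u)
        Z = _columns(spec.random_terms, d, u)
        V = Z @ fit.psi @ Z.T + fit.sigma2 * np.eye(len(d))
        info += X.T @ np.linalg.solve(V, X)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    assert np.allclose(fit.se, se, rtol=1e-8)


def test_wald_zero_coefficient_gives_p_one():
    from gengrad.lmm import LmmFit
    fit = LmmFit(spec=ModelSpec.from_formula("1+d", "1"),
                 fixed_names=("1", "d"), beta=np.array([1.0, 0.0]),
                 se=np.array([0.1, 0.1]), z=np.array([10.0, 0.0]),
                 p=2 * stats.norm.sf([10.0, 0.0]), psi=np.array([[1.0]]),
                 sigma2=1.0, loglik=0.0, deviance=0.0, n_obs=10, n_clusters=2,
                 n_params=4, converged=True, subjects=np.array([0, 1]))
    assert wald_tests(fit)["p"].iloc[1] == pytest.approx(1.0)


def test_wald_null_pvalues_uniform():
    """Under gamma11 = 0 at large n the d:u Wald p-value is Uniform(0,1)."""
    cfg = default_config(n_subjects=150, gamma11=0.0)
    rng = np.random.default_rng(31)
    spec = ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML")
    ps = []
    for _ in range(400):
        data = simulate_dataset(cfg, rng)
        ps.append(fit_lmm(data, spec).coef_p("d:u"))
    stat = stats.kstest(ps, "uniform")
    assert stat.pvalue > 1e-3


# --- LRT --------------------------------------------------------------------

def test_lrt_identical_models(small_dataset):
    spec = ModelSpec.from_formula("1+d", "1+d", "ML")
    a, b = fit_lmm(small_dataset, spec), fit_lmm(small_dataset, spec)
    res = lrt(a, b)
    assert res.df == 0 and res.p_value == 1.0
    assert res.delta_deviance < 1e-4


def test_lrt_random_slope_df_two(small_dataset):
    f1 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "ML"))
    f2 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1+d", "ML"))
    res = lrt(f1, f2)
    assert res.df == 2  # slope variance + intercept-slope covariance
    assert res.delta_deviance >= 0


def test_lrt_refuses_reml_and_non_nested(small_dataset):
    r1 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "REML"))
    r2 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1+d", "REML"))
    with pytest.raises(ValueError, match="ML"):
        lrt(r1, r2)
    a = fit_lmm(small_dataset, ModelSpec.from_formula("1+d+u", "1", "ML"))
    b = fit_lmm(small_dataset, ModelSpec.from_formula("1+d+d2", "1", "ML"))
    with pytest.raises(ValueError, match="nested"):
        lrt(a, b)


def test_lrt_boundary_conservative():
    """Adding a random slope when the generator has none: the deviance gain
    is stochastically below chi2_2, so the naive test under-rejects."""
    from gengrad import SimulationConfig
    cfg = SimulationConfig(n_subjects=25, n_stimuli=5, gamma00=3.0,
                           gamma10=-0.3, tau00=1.0, tau11=0.0, tau01=0.0,
                           sigma2_eps=1.0, seed=0)
    rng = np.random.default_rng(55)
    small = ModelSpec.from_formula("1+d", "1", "ML")
    big = ModelSpec.from_formula("1+d", "1+d", "ML")
    crit = stats.chi2.ppf(0.95, 2)
    rej = 0
    reps = 300
    for _ in range(reps):
        data = simulate_dataset(cfg, rng)
        delta = fit_lmm(data, small).deviance - fit_lmm(data, big).deviance
        rej += max(delta, 0.0) > crit
    rate = rej / reps
    assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


# --- information criteria ---------------------------------------------------

def test_information_criteria_bookkeeping(small_dataset):
    f1 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "ML"))
    assert f1.n_params == 4  # 2 fixed + intercept variance + residual
    aic, bic = information_criteria(f1)
    assert aic == pytest.approx(f1.deviance + 8)
    assert bic == pytest.approx(f1.deviance + 4 * math.log(f1.n_obs))
    f2 = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1+d", "ML"))
    assert f2.n_params == 6  # 2 fixed + 3 covariance entries + residual
    assert f2.aic == pytest.approx(f2.deviance + 12)
    reml = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "REML"))
    with pytest.raises(ValueError):
        information_criteria(reml)


# --- predictions ------------------------------------------------------------

def test_predictions_with_zero_psi_are_population_line(small_dataset):
    fit = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "ML"))
    fit.psi = np.zeros((1, 1))
    pred = predict_subjects(fit, small_dataset)
    d = small_dataset["d"].to_numpy()
    pop = fit.beta[0] + fit.beta[1] * d
    assert np.allclose(pred["y_hat"], pop)


def test_random_intercept_blup_shrinkage_closed_form(small_dataset):
    fit = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "ML"))
    pred = predict_subjects(fit, small_dataset)
    tau2, s2 = fit.psi[0, 0], fit.sigma2
    d = small_dataset["d"].to_numpy()
    fixed = fit.beta[0] + fit.beta[1] * d
    for s, sub in small_dataset.groupby("subject"):
        idx = sub.index
        ni = len(idx)
        shrink = tau2 / (tau2 + s2 / ni)
        b_closed = shrink * (sub["y"] - fixed[idx]).mean()
        b_mine = pred.loc[idx, "y_hat"].iloc[0] - fixed[idx[0]]
        assert b_mine == pytest.approx(b_closed, abs=1e-8)


def test_mean_prediction_equals_fixed_curve_on_balanced_data(small_dataset):
    fit = fit_lmm(small_dataset, ModelSpec.from_formula("1+d+u+d:u", "1+d", "ML"))
    pred = predict_subjects(fit, small_dataset)
    merged = small_dataset.assign(y_hat=pred["y_hat"].to_numpy())
    X = _columns(fit.spec.fixed_terms, merged["d"].to_numpy(float),
                 merged["u"].to_numpy(float))
    fixed = X @ fit.beta
    by_d_pred = merged.groupby("d")["y_hat"].mean()
    by_d_fixed = merged.assign(f=fixed).groupby("d")["f"].mean()
    assert np.allclose(by_d_pred, by_d_fixed, atol=1e-8)


def test_unseen_subject_flagged_population_only(small_dataset):
    fit = fit_lmm(small_dataset, ModelSpec.from_formula("1+d", "1", "ML"))
    new = small_dataset.copy()
    new["subject"] = new["subject"] + 1000
    pred = predict_subjects(fit, new)
    assert pred["population_only"].all()


# --- the model ladder -------------------------------------------------------

def test_nesting_monotonicity_of_deviance(medium_dataset):
    ladder = model_ladder(medium_dataset)
    fits = ladder.fits
    for a, b in [(1, 2), (2, 3), (2, 4), (4, 5), (4, 6), (7, 6)]:
        assert fits[a].deviance >= fits[b].deviance - 1e-4, (a, b)


def test_ladder_df_counting(medium_dataset):
    ladder = model_ladder(medium_dataset)
    by_label = {lab: t for lab, _, _, t in ladder.comparisons}
    assert by_label["random slope (2 vs 1)"].df == 2
    assert by_label["random quadratic (5 vs 4)"].df == 3
    assert by_label["quadratic fixed effect (4 vs 2)"].df == 1
    assert by_label["drop d2:u (7 vs 6)"].df == 1


def test_ladder_detects_quadratic_and_rejects_random_quadratic():
    """On emulated worked-example data (quadratic fixed gradient, linear
    random slopes) the ladder keeps d2 fixed and drops the random d2."""
    data = simulate_worked_example(n_subjects=300,
                                   rng=np.random.default_rng(4), clip=False)
    ladder = model_ladder(data)
    by_label = {lab: t for lab, _, _, t in ladder.comparisons}
    assert by_label["quadratic fixed effect (4 vs 2)"].p_value < 0.05
    assert by_label["random quadratic (5 vs 4)"].p_value > 0.05


def test_ladder_flat_data_nothing_significant():
    rng = np.random.default_rng(6)
    n, k = 30, 10
    data = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                         "d": np.tile(np.arange(k, dtype=float), n),
                         "u": np.repeat(rng.uniform(0, 10, n), k),
                         "y": rng.normal(size=n * k)})
    ladder = model_ladder(data)
    for lab, _, _, t in ladder.comparisons:
        if lab != "drop d2:u (7 vs 6)":
            assert t.p_value > 0.05, lab
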