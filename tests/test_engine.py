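"""SEM engine: implied moments, FIML likelihood, estimation, fit statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcsm import (
    BiSpec,
    CouplingSpec,
    DataError,
    UniSpec,
    compile_spec,
    fiml_loglik,
    fit,
    fit_statistics,
    fit_univariate,
    implied_moments,
    simulate,
)
from lcsm.engine import FittedModel, baseline_fiml, extract_matrix, saturated_fiml

from conftest import (
    BI_EXAMPLE,
    EXAMPLE_THETA,
    UNI_CBP,
    X_VARS,
    Y_VARS,
)


def _zero_theta(model, **overrides):
    theta = {l: 0.0 for l in model.params.labels}
    theta.update(overrides)
    return theta


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------

def test_constant_change_means_are_linear():
    model = compile_spec(UniSpec(alpha_constant=True), 5)
    mu, sigma = implied_moments(model, _zero_theta(model, gamma_lx1=10, alpha_g2=-1))
    assert np.allclose(mu, [10, 9, 8, 7, 6], atol=1e-12)
    assert np.allclose(sigma, 0, atol=1e-12)


def test_proportional_change_means_are_geometric():
    model = compile_spec(UniSpec(beta=True), 5)
    mu, _ = implied_moments(model, _zero_theta(model, gamma_lx1=10, beta_x=-0.2))
    expected = 10 * (1 - 0.2) ** np.arange(5)
    assert np.allclose(mu, expected, atol=1e-12)
    assert np.allclose(mu, [10, 8, 6.4, 5.12, 4.096], atol=1e-12)


def test_implied_moments_match_coefficient_propagation_oracle():
    """Independent oracle: write x1..x3 as explicit linear maps of the
    exogenous vector (lx1, g2, u1, u2, u3) and propagate mean/covariance."""
    g, sl, su, a, sg, sgl, b, p = 12.0, 1.5, 0.4, -0.6, 0.5, 0.2, -0.15, 0.25
    model = compile_spec(UNI_CBP, 3)
    theta = dict(gamma_lx1=g, sigma2_lx1=sl, sigma2_ux=su, alpha_g2=a,
                 sigma2_g2=sg, sigma_g2lx1=sgl, beta_x=b, phi_x=p)
    mu, sigma = implied_moments(model, theta)

    mean_z = np.array([g, a, 0, 0, 0])
    cov_z = np.zeros((5, 5))
    cov_z[0, 0], cov_z[1, 1] = sl, sg
    cov_z[0, 1] = cov_z[1, 0] = sgl
    cov_z[2:, 2:] = su * np.eye(3)
    lx1 = np.array([1.0, 0, 0, 0, 0])
    dx2 = b * lx1 + np.array([0, 1.0, 0, 0, 0])
    lx2 = lx1 + dx2
    dx3 = b * lx2 + p * dx2 + np.array([0, 1.0, 0, 0, 0])
    lx3 = lx2 + dx3
    u = np.eye(5)[2:]
    C = np.vstack([lx1 + u[0], lx2 + u[1], lx3 + u[2]])
    assert np.allclose(mu, C @ mean_z, atol=1e-12)
    assert np.allclose(sigma, C @ cov_z @ C.T, atol=1e-12)


# ---------------------------------------------------------------------------
# FIML log-likelihood
# ---------------------------------------------------------------------------

def _brute_force_fiml(mu, sigma, Y):
    """Case-wise oracle: one MVN log-density per row's observed subset."""
    total = 0.0
    for row in Y:
        obs = ~np.isnan(row)
        if not obs.any():
            continue
        total += stats.multivariate_normal.logpdf(
            row[obs], mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
        )
    return total


def test_single_standard_normal_cell():
    model = compile_spec(UniSpec(), 2)
    data = pd.DataFrame({"x1": [0.0], "x2": [np.nan]})
    theta = _zero_theta(model, sigma2_lx1=0.5, sigma2_ux=0.5)  # var(x1) = 1
    ll = fiml_loglik(model, theta, data)
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_complete_data_reduces_to_plain_ml():
    model = compile_spec(UNI_CBP, 5)
    data = simulate(UNI_CBP, 5, 50, dict(gamma_lx1=10, sigma2_lx1=1, sigma2_ux=.5,
                                         alpha_g2=-.4, sigma2_g2=.3,
                                         sigma_g2lx1=.1, beta_x=-.1, phi_x=.1),
                    seed=3)
    theta = dict(gamma_lx1=10, sigma2_lx1=1, sigma2_ux=.5, alpha_g2=-.4,
                 sigma2_g2=.3, sigma_g2lx1=.1, beta_x=-.1, phi_x=.1)
    mu, sigma = implied_moments(model, theta)
    Y = extract_matrix(data, model.obs_names)
    expected = stats.multivariate_normal.logpdf(Y, mean=mu, cov=sigma).sum()
    assert fiml_loglik(model, theta, data) == pytest.approx(expected, rel=1e-12)


def test_pattern_grouping_equals_case_wise_brute_force():
    model = compile_spec(BI_EXAMPLE, 5)
    rng = np.random.default_rng(42)
    for trial in range(5):
        Y = rng.normal(size=(20, 10)) + np.array([29, 28, 27, 26, 25,
                                                  15, 14, 13, 12, 11], dtype=float)
        Y[rng.random((20, 10)) < 0.3] = np.nan
        data = pd.DataFrame(Y, columns=model.obs_names)
        mu, sigma = implied_moments(model, EXAMPLE_THETA)
        grouped = fiml_loglik(model, EXAMPLE_THETA, data)
        brute = _brute_force_fiml(mu, sigma, Y)
        assert grouped == pytest.approx(brute, rel=1e-10, abs=1e-10)


def test_loglik_invariant_to_row_order_and_empty_rows(example_data):
    model = compile_spec(UNI_CBP, 5, var_x=X_VARS)
    sub = example_data[["id"] + X_VARS].head(50)
    ll = fiml_loglik(model, EXAMPLE_THETA_X := {k: EXAMPLE_THETA[k] for k in
                     model.params.labels}, sub)
    shuffled = sub.sample(frac=1.0, random_state=9)
    assert fiml_loglik(model, EXAMPLE_THETA_X, shuffled) == pytest.approx(ll, rel=1e-12)
    empty = pd.DataFrame([[999] + [np.nan] * 5], columns=["id"] + X_VARS)
    padded = pd.concat([sub, empty, empty], ignore_index=True)
    assert fiml_loglik(model, EXAMPLE_THETA_X, padded) == pytest.approx(ll, rel=1e-12)


def test_non_positive_definite_theta_gives_minus_inf():
    model = compile_spec(UniSpec(), 3)
    data = pd.DataFrame({"x1": [1.0, 2.0], "x2": [1.0, 2.0], "x3": [1.0, 2.0]})
    ll = fiml_loglik(model, _zero_theta(model, sigma2_lx1=-1.0, sigma2_ux=-1.0), data)
    assert ll == -np.inf


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def test_constant_change_recovery_large_n():
    truth = dict(gamma_lx1=10, sigma2_lx1=1, sigma2_ux=.5, alpha_g2=-.4,
                 sigma2_g2=.3, sigma_g2lx1=.1)
    spec = UniSpec(alpha_constant=True)
    data = simulate(spec, 5, 10_000, truth, seed=11)
    fitted = fit_univariate(data, X_VARS, spec, compute_fit=False)
    assert fitted.converged
    # alpha_g2 within 3 Monte-Carlo standard errors of truth
    mc_se = np.sqrt(truth["sigma2_g2"] / 10_000)
    assert abs(fitted.estimates["alpha_g2"] - truth["alpha_g2"]) < 3 * mc_se + 0.01


def test_refit_from_solution_is_stationary(example_data, example_fit):
    refit = fit_univariate(example_data, X_VARS, UNI_CBP,
                           start=example_fit.estimates,
                           compute_se=False, compute_fit=False)
    assert refit.loglik == pytest.approx(example_fit.loglik, abs=1e-6)
    assert refit.diagnostics["n_iterations"] <= 2


def test_nested_model_likelihood_ordering(example_data):
    small = fit_univariate(example_data, X_VARS, UniSpec(alpha_constant=True),
                           compute_se=False, compute_fit=False)
    start = {l: small.estimates.get(l, 0.0)
             for l in compile_spec(UNI_CBP, 5, var_x=X_VARS).params.labels}
    big = fit_univariate(example_data, X_VARS, UNI_CBP, start=start,
                         compute_se=False, compute_fit=False)
    assert big.loglik >= small.loglik - 1e-6


def test_listwise_ml_drops_incomplete_rows(example_data):
    fitted = fit_univariate(example_data, X_VARS, UniSpec(alpha_constant=True),
                            estimator="listwise_ml", compute_se=False,
                            compute_fit=False)
    complete = example_data[X_VARS].notna().all(axis=1).sum()
    assert fitted.n_used == complete


def test_too_few_rows_is_a_data_error():
    model = compile_spec(UniSpec(), 3)
    data = pd.DataFrame({"x1": [1.0], "x2": [2.0], "x3": [1.5]})
    with pytest.raises(DataError):
        fit(model, data)


def test_standard_errors_shrink_with_sqrt_n():
    truth = dict(gamma_lx1=10, sigma2_lx1=1, sigma2_ux=.5, alpha_g2=-.4,
                 sigma2_g2=.3, sigma_g2lx1=.1)
    spec = UniSpec(alpha_constant=True)
    ses = {}
    for n in (500, 2000, 8000):
        data = simulate(spec, 5, n, truth, seed=100 + n)
        fitted = fit_univariate(data, X_VARS, spec, compute_fit=False)
        ses[n] = fitted.standard_errors["alpha_g2"]
    assert ses[500] / ses[2000] == pytest.approx(2.0, rel=0.25)
    assert ses[2000] / ses[8000] == pytest.approx(2.0, rel=0.25)


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

def test_degrees_of_freedom_from_moment_count(example_fit):
    # 5 means + 15 covariance entries = 20 moments, minus 8 free parameters
    assert example_fit.npar == 8
    assert example_fit.fit.df == 12


def test_information_criterion_identity(example_fit):
    fs = example_fit.fit
    assert fs.bic - fs.aic == pytest.approx(fs.npar * (np.log(fs.n) - 2), abs=1e-9)


def test_saturated_candidate_has_perfect_fit(example_data):
    """A model whose likelihood equals the saturated one: chisq 0, cfi 1, rmsea 0."""
    model = compile_spec(UNI_CBP, 5, var_x=X_VARS)
    Y = extract_matrix(example_data, X_VARS)
    _, _, ll_s, ok = saturated_fiml(Y)
    assert ok
    base = fit_univariate(example_data, X_VARS, UNI_CBP, compute_se=False,
                          compute_fit=False)
    pretend = FittedModel(model=model, estimates=base.estimates,
                          standard_errors=None, loglik=ll_s,
                          n_used=base.n_used, converged=True)
    fs = fit_statistics(pretend, example_data)
    assert fs.chisq == pytest.approx(0.0, abs=1e-6)
    assert fs.cfi == 1.0
    assert fs.rmsea == pytest.approx(0.0, abs=1e-6)


def test_saturated_loglik_bounds_model_loglik(example_fit, example_data):
    fs = example_fit.fit
    assert fs.loglik_saturated >= example_fit.loglik - 1e-6
    assert fs.chisq >= 0.0
    assert 0.0 <= fs.cfi <= 1.0 and fs.rmsea >= 0.0 and fs.srmr >= 0.0


def test_baseline_is_per_column_closed_form(example_data):
    Y = extract_matrix(example_data, X_VARS)
    ll, npar = baseline_fiml(Y)
    expected = 0.0
    for j in range(5):
        col = Y[:, j]
        col = col[~np.isnan(col)]
        expected += stats.norm.logpdf(col, col.mean(), col.std()).sum()
    assert npar == 10
    assert ll == pytest.approx(expected, rel=1e-12)
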