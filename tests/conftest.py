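"""Shared fixtures: the worked-example bivariate generating values.

The example emulates a five-session intervention (n = 500) with a process
variable X and an outcome variable Y, change in X predicting subsequent
change in Y (lagged change-to-change coupling), and MCAR missingness of 15%
on X cells and 10% on Y cells.
"""

import pytest

from lcsm import BiSpec, CouplingSpec, UniSpec, fit_univariate, simulate

EXAMPLE_X_PARAMS = {
    "gamma_lx1": 29, "sigma2_lx1": 0.5, "sigma2_ux": 0.2, "alpha_g2": -0.3,
    "sigma2_g2": 0.6, "sigma_g2lx1": 0.2, "beta_x": -0.1, "phi_x": 0.1,
}
EXAMPLE_Y_PARAMS = {
    "gamma_ly1": 15, "sigma2_ly1": 0.2, "sigma2_uy": 0.2, "alpha_j2": -0.4,
    "sigma2_j2": 0.1, "sigma_j2ly1": 0.02, "beta_y": -0.2, "phi_y": 0.1,
}
EXAMPLE_COUPLING_PARAMS = {
    "sigma_su": 0.01, "sigma_ly1lx1": 0.2, "sigma_g2ly1": 0.1,
    "sigma_j2lx1": 0.1, "sigma_j2g2": 0.01, "xi_lag_yx": 0.5,
}
EXAMPLE_THETA = {**EXAMPLE_X_PARAMS, **EXAMPLE_Y_PARAMS, **EXAMPLE_COUPLING_PARAMS}

UNI_CBP = UniSpec(alpha_constant=True, beta=True, phi=True)
BI_EXAMPLE = BiSpec(model_x=UNI_CBP, model_y=UNI_CBP,
                    coupling=CouplingSpec(xi_lag_yx=True))

X_VARS = [f"x{t}" for t in range(1, 6)]
Y_VARS = [f"y{t}" for t in range(1, 6)]


@pytest.fixture(scope="session")
def example_data():
    """Bivariate dataset simulated under the example generating values."""
    return simulate(BI_EXAMPLE, T=5, n=500, theta=EXAMPLE_THETA,
                    na_x_pct=0.15, na_y_pct=0.10, seed=1234)


@pytest.fixture(scope="session")
def example_fit(example_data):
    """FIML fit of the univariate x-model to the example dataset."""
    fitted = fit_univariate(example_data, X_VARS, UNI_CBP)
    assert fitted.converged
    return fitted
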