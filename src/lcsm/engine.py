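"""Self-contained SEM estimation engine for latent change score models.

Model-implied moments follow standard RAM algebra: with directed paths ``A``,
symmetric covariances ``S``, means ``m`` and observed-variable filter ``F``,

    mu    = F (I - A)^-1 m
    Sigma = F (I - A)^-1 S (I - A)^-T F^T

Estimation is full-information maximum likelihood (FIML): each individual
contributes the multivariate-normal log-density of their observed subset, so
cases with incomplete rows are retained (valid under MCAR/MAR).  Rows are
grouped by missingness pattern for efficiency; the grouped value is
numerically identical to case-wise evaluation.

Fit statistics compare the fitted model against a saturated model
(unstructured mean and covariance, estimated by EM under missingness) and an
independence baseline (free means and variances, zero covariances, which under
FIML has a closed-form per-column solution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from scipy import stats

from .spec import (
    BiSpec,
    SpecificationError,
    StructuralModel,
    spec_from_dict,
    spec_to_dict,
)

_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e12  # objective value when the implied covariance is not PD


class DataError(ValueError):
    """Input data unusable for the requested model."""


class StructuralCycleError(RuntimeError):
    """(I - A) is singular; the directed paths contain an ill-posed cycle."""


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------

def implied_moments(model: StructuralModel, theta) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance of the observed variables."""
    A, S, m = model.materialize(theta)
    eye = np.eye(model.nvar)
    try:
        B = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as exc:
        raise StructuralCycleError("(I - A) is singular") from exc
    mu = B @ m
    sigma = B @ S @ B.T
    o = model.obs_idx
    return mu[o], sigma[np.ix_(o, o)]


# ---------------------------------------------------------------------------
# Data preparation and pattern-grouped Gaussian log-likelihood
# ---------------------------------------------------------------------------

def extract_matrix(data: pd.DataFrame, obs_names: Sequence[str]) -> np.ndarray:
    missing_cols = [c for c in obs_names if c not in data.columns]
    if missing_cols:
        raise DataError(
            f"data lacks column(s) {missing_cols}; available: {list(data.columns)}"
        )
    return data.loc[:, list(obs_names)].to_numpy(dtype=float)


@dataclass
class _Patterns:
    """Rows grouped by missingness pattern (all-missing rows dropped)."""

    groups: list[tuple[np.ndarray, np.ndarray]]  # (observed col idx, values)
    n_used: int
    n_dropped: int


def group_patterns(Y: np.ndarray) -> _Patterns:
    obs = ~np.isnan(Y)
    keep = obs.any(axis=1)
    n_dropped = int((~keep).sum())
    Y = Y[keep]
    obs = obs[keep]
    groups = []
    if len(Y):
        # lexicographic pattern key
        keys = obs @ (1 << np.arange(obs.shape[1], dtype=np.int64))
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        starts = np.flatnonzero(np.r_[True, np.diff(keys_sorted) != 0])
        bounds = np.r_[starts, len(keys_sorted)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows = order[a:b]
            cols = np.flatnonzero(obs[rows[0]])
            groups.append((cols, Y[np.ix_(rows, cols)]))
    return _Patterns(groups=groups, n_used=len(Y), n_dropped=n_dropped)


def _gaussian_loglik(mu: np.ndarray, sigma: np.ndarray, patterns: _Patterns) -> float | None:
    """Sum of MVN log-densities over pattern groups; None if sigma is not PD."""
    total = 0.0
    for cols, vals in patterns.groups:
        sub = sigma[np.ix_(cols, cols)]
        try:
            chol = sla.cho_factor(sub, lower=True, check_finite=False)
        except (sla.LinAlgError, ValueError):
            return None
        dev = vals - mu[cols]
        sol = sla.cho_solve(chol, dev.T, check_finite=False)
        quad = np.einsum("ij,ji->i", dev, sol)
        logdet = 2.0 * np.log(np.diag(chol[0])).sum()
        k = len(cols)
        total += -0.5 * (len(vals) * (k * _LOG2PI + logdet) + quad.sum())
    return float(total)


def fiml_loglik(model: StructuralModel, theta, data: pd.DataFrame) -> float:
    """FIML log-likelihood of ``theta``; -inf if the implied covariance is not PD."""
    Y = extract_matrix(data, model.obs_names)
    patterns = group_patterns(Y)
    mu, sigma = implied_moments(model, theta)
    ll = _gaussian_loglik(mu, sigma, patterns)
    return -np.inf if ll is None else ll


# ---------------------------------------------------------------------------
# Saturated and baseline reference models
# ---------------------------------------------------------------------------

def saturated_fiml(
    Y: np.ndarray, tol: float = 1e-10, max_iter: int = 20000
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """FIML solution of the unstructured (mu, Sigma) model.

    Complete data has the closed-form sample-moment solution; under
    missingness the solution is found by EM for the multivariate normal,
    iterated until the relative change in the observed-data log-likelihood
    falls below ``tol``.
    """
    patterns = group_patterns(Y)
    Yk = Y[~np.isnan(Y).all(axis=1)]
    n, p = Yk.shape
    if not np.isnan(Yk).any():
        mu = Yk.mean(axis=0)
        dev = Yk - mu
        sigma = dev.T @ dev / n
        ll = _gaussian_loglik(mu, sigma, patterns)
        return mu, sigma, float(ll), True

    mu = np.nanmean(Yk, axis=0)
    masked = np.ma.masked_invalid(Yk)
    sigma = np.ma.cov(masked, rowvar=False, bias=True).filled(0.0)
    sigma = 0.5 * (sigma + sigma.T)
    w, V = np.linalg.eigh(sigma)
    floor = max(1e-6 * w.max(), 1e-8)
    sigma = (V * np.clip(w, floor, None)) @ V.T

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        esum = np.zeros(p)
        ess = np.zeros((p, p))
        for cols, vals in patterns.groups:
            rows = len(vals)
            mis = np.setdiff1d(np.arange(p), cols)
            X = np.empty((rows, p))
            X[:, cols] = vals
            if len(mis):
                soo = sigma[np.ix_(cols, cols)]
                som = sigma[np.ix_(cols, mis)]
                K = np.linalg.solve(soo, som)
                X[:, mis] = mu[mis] + (vals - mu[cols]) @ K
                cond = sigma[np.ix_(mis, mis)] - som.T @ K
            esum += X.sum(axis=0)
            ess += X.T @ X
            if len(mis):
                ess[np.ix_(mis, mis)] += rows * cond
        mu = esum / n
        sigma = ess / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _gaussian_loglik(mu, sigma, patterns)
        if ll is None:
            break
        if abs(ll - prev_ll) < tol * (abs(ll) + 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sigma, float(prev_ll), converged


def baseline_fiml(Y: np.ndarray) -> tuple[float, int]:
    """Independence-model FIML log-likelihood and its parameter count.

    With zero covariances the likelihood factorises over columns, so the MLE
    is the per-column mean and ML variance over the observed cells.
    """
    Yk = Y[~np.isnan(Y).all(axis=1)]
    p = Yk.shape[1]
    ll = 0.0
    for j in range(p):
        col = Yk[:, j]
        col = col[~np.isnan(col)]
        if len(col) < 2:
            raise DataError(f"column {j} has fewer than 2 observed values")
        mu = col.mean()
        var = col.var()
        if var <= 0:
            raise DataError(f"column {j} has zero variance")
        ll += stats.norm.logpdf(col, mu, np.sqrt(var)).sum()
    return float(ll), 2 * p


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

@dataclass
class FitStatistics:
    chisq: float
    df: int
    npar: int
    aic: float
    bic: float
    cfi: float | None
    rmsea: float | None
    srmr: float | None
    pvalue: float | None
    loglik: float
    loglik_saturated: float | None
    loglik_baseline: float | None
    n: int
    indices_available: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FittedModel:
    model: StructuralModel
    estimates: dict[str, float]
    standard_errors: dict[str, float] | None
    loglik: float
    n_used: int
    converged: bool
    fit: FitStatistics | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def npar(self) -> int:
        return len(self.estimates)

    def to_dict(self) -> dict:
        return {
            "type": "lcsm_fitted_model",
            "spec": spec_to_dict(self.model.spec),
            "T": self.model.T,
            "observed": list(self.model.obs_names),
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "loglik": self.loglik,
            "n_used": self.n_used,
            "converged": self.converged,
            "fit": self.fit.to_dict() if self.fit is not None else None,
            "diagnostics": {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in self.diagnostics.items()
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def fit_statistics(fitted: FittedModel, data: pd.DataFrame) -> FitStatistics:
    """Likelihood-ratio chi-square against the saturated model plus fit indices.

    ``df`` counts the observed first- and second-order moments (p means and
    p(p+1)/2 covariance entries over all observed variables jointly) minus the
    number of free parameters.  ``n`` is the number of rows with at least one
    observed value.
    """
    model = fitted.model
    Y = extract_matrix(data, model.obs_names)
    if fitted.diagnostics.get("estimator") == "listwise_ml":
        Y = Y[~np.isnan(Y).any(axis=1)]
    p = len(model.obs_names)
    npar = fitted.npar
    moments = p * (p + 3) // 2
    df = moments - npar
    n = fitted.n_used
    ll = fitted.loglik
    aic = -2.0 * ll + 2.0 * npar
    bic = -2.0 * ll + npar * np.log(n)
    base = dict(npar=npar, aic=aic, bic=bic, loglik=ll, n=n, df=df)
    try:
        mu_s, sigma_s, ll_s, sat_ok = saturated_fiml(Y)
        if not sat_ok:
            raise RuntimeError("saturated model EM did not converge")
        ll_b, _ = baseline_fiml(Y)
    except (RuntimeError, DataError, np.linalg.LinAlgError):
        return FitStatistics(
            chisq=np.nan, cfi=None, rmsea=None, srmr=None, pvalue=None,
            loglik_saturated=None, loglik_baseline=None,
            indices_available=False, **base,
        )
    chisq = max(2.0 * (ll_s - ll), 0.0)
    chisq_b = max(2.0 * (ll_s - ll_b), 0.0)
    df_b = moments - 2 * p
    denom = max(chisq_b - df_b, chisq - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - max(chisq - df, 0.0) / denom
    rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * n))) if df > 0 else 0.0
    mu_m, sigma_m = implied_moments(model, fitted.estimates)
    sd = np.sqrt(np.diag(sigma_s))
    cov_resid = (sigma_s - sigma_m) / np.outer(sd, sd)
    tril = np.tril_indices(p)
    mean_resid = (mu_s - mu_m) / sd
    resid = np.concatenate([cov_resid[tril], mean_resid])
    srmr = float(np.sqrt(np.mean(resid**2)))
    pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else None
    return FitStatistics(
        chisq=float(chisq), cfi=float(cfi), rmsea=rmsea, srmr=srmr,
        pvalue=pvalue, loglik_saturated=float(ll_s), loglik_baseline=float(ll_b),
        **base,
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def default_start(model: StructuralModel, Y: np.ndarray) -> np.ndarray:
    """Data-driven start values.

    Initial true-score mean from the first occasion's observed mean; initial
    true-score and unique variances each at half the first occasion's
    variance; change-factor means at the mean successive difference (and half
    its variance for the factor variance); regressions and covariances at 0.
    """
    starts: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        for c, meta in model.constructs.items():
            cols = [model.obs_names.index(v) for v in meta["obs"]]
            block = Y[:, cols]
            first = block[:, 0]
            mu1 = float(np.nanmean(first))
            v1 = float(np.nanvar(first))
            diffs = np.diff(block, axis=1)
            md = float(np.nanmean(diffs))
            vd = float(np.nanvar(diffs))
            if not np.isfinite(md):
                md = 0.0
            if not np.isfinite(vd) or vd <= 0:
                vd = 1.0
            lp = "l" + c
            starts[f"gamma_{lp}1"] = mu1
            starts[f"sigma2_{lp}1"] = max(0.5 * v1, 1e-3)
            starts[f"sigma2_u{c}"] = max(0.5 * v1, 1e-3)
            for fname in meta["factors"]:
                starts[f"alpha_{fname}"] = md
                starts[f"sigma2_{fname}"] = max(0.5 * vd, 1e-3)
    return np.array([starts.get(l, 0.0) for l in model.params.labels])


def _num_hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian (observed information of the objective)."""
    k = len(x)
    h = 1e-4 * (np.abs(x) + 1e-2)
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit(
    model: StructuralModel,
    data: pd.DataFrame,
    estimator: str = "fiml",
    start: Mapping[str, float] | Sequence[float] | None = None,
    compute_se: bool = True,
    compute_fit: bool = True,
    max_iter: int = 500,
) -> FittedModel:
    """Estimate a compiled LCSM by quasi-Newton maximisation of the likelihood.

    ``estimator="fiml"`` keeps rows with incomplete data; ``"listwise_ml"``
    drops them first.  Non-convergence is reported through the ``converged``
    flag (with diagnostics), not an exception.
    """
    if estimator not in ("fiml", "listwise_ml"):
        raise ValueError(f"unknown estimator {estimator!r}")
    Y = extract_matrix(data, model.obs_names)
    if estimator == "listwise_ml":
        Y = Y[~np.isnan(Y).any(axis=1)]
    patterns = group_patterns(Y)
    if patterns.n_used < 2:
        raise DataError(f"only {patterns.n_used} usable row(s); need at least 2")
    if patterns.n_used < len(model.params):
        raise DataError(
            f"{patterns.n_used} usable rows cannot identify {len(model.params)} parameters"
        )

    def nll(vec: np.ndarray) -> float:
        try:
            mu, sigma = implied_moments(model, vec)
        except StructuralCycleError:
            return _PENALTY
        ll = _gaussian_loglik(mu, sigma, patterns)
        return _PENALTY if ll is None else -ll

    x0 = model.theta_vector(start) if start is not None else default_start(model, Y)
    options = dict(maxiter=max_iter, maxfun=200000, ftol=1e-11, gtol=1e-6, eps=1e-6)
    res = optimize.minimize(nll, x0, method="L-BFGS-B", options=options)
    # one polish restart: L-BFGS-B occasionally stops early on its internal
    # curvature estimate; re-starting resets the memory
    res2 = optimize.minimize(nll, res.x, method="L-BFGS-B", options=options)
    best = res2 if res2.fun <= res.fun else res
    xhat = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    converged = bool((res.success or res2.success) and best.fun < _PENALTY / 2)
    estimates = dict(zip(model.params.labels, xhat.tolist()))
    diagnostics = {
        "estimator": estimator,
        "n_iterations": int(res.nit),
        "n_iterations_polish": int(res2.nit),
        "n_function_evals": int(res.nfev + res2.nfev),
        "optimizer_message": str(best.message),
        "n_rows_dropped": patterns.n_dropped,
    }
    standard_errors = None
    if compute_se and converged:
        try:
            H = _num_hessian(nll, xhat)
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                standard_errors = dict(
                    zip(model.params.labels, np.sqrt(diag).tolist())
                )
            else:
                diagnostics["se_failure"] = "information matrix not positive definite"
        except np.linalg.LinAlgError:
            diagnostics["se_failure"] = "information matrix singular"
    fitted = FittedModel(
        model=model,
        estimates=estimates,
        standard_errors=standard_errors,
        loglik=loglik,
        n_used=patterns.n_used,
        converged=converged,
        diagnostics=diagnostics,
    )
    if compute_fit and converged:
        fitted.fit = fit_statistics(fitted, data)
    return fitted


# ---------------------------------------------------------------------------
# Convenience wrappers over compile + fit
# ---------------------------------------------------------------------------

def fit_univariate(data, var, spec, estimator="fiml", **kwargs) -> FittedModel:
    from .spec import compile_spec

    model = compile_spec(spec, len(var), var_x=var)
    return fit(model, data, estimator=estimator, **kwargs)


def fit_bivariate(data, var_x, var_y, spec: BiSpec, estimator="fiml", **kwargs) -> FittedModel:
    from .spec import compile_spec

    if len(var_x) != len(var_y):
        raise SpecificationError("var_x and var_y must have equal length")
    model = compile_spec(spec, len(var_x), var_x=var_x, var_y=var_y)
    return fit(model, data, estimator=estimator, **kwargs)


def fitted_from_dict(d: Mapping) -> FittedModel:
    """Rebuild a FittedModel (for results extraction) from its JSON form."""
    from .spec import compile_spec

    spec = spec_from_dict(d["spec"])
    T = int(d["T"])
    obs = list(d["observed"])
    if hasattr(spec, "coupling"):
        model = compile_spec(spec, T, var_x=obs[:T], var_y=obs[T:])
    else:
        model = compile_spec(spec, T, var_x=obs)
    fit_block = d.get("fit")
    return FittedModel(
        model=model,
        estimates={k: float(v) for k, v in d["estimates"].items()},
        standard_errors=(
            {k: float(v) for k, v in d["standard_errors"].items()}
            if d.get("standard_errors")
            else None
        ),
        loglik=float(d["loglik"]),
        n_used=int(d["n_used"]),
        converged=bool(d["converged"]),
        fit=FitStatistics(**fit_block) if fit_block else None,
        diagnostics=dict(d.get("diagnostics", {})),
    )
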