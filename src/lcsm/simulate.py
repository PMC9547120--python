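"""Simulate wide-format longitudinal data from LCSM parameter values.

Generation is structural: the exogenous components (initial true scores,
change factors and per-occasion unique scores) are drawn from the
multivariate normal defined by the parameter values, and the change-score
recursions then build true, change and observed scores.  In RAM form the
recursion is exactly ``v = (I - A)^-1 (m + e)`` with ``e ~ N(0, S)``, so the
simulated observed vectors follow the model-implied distribution by
construction, while the latent scores remain available for diagnostics.

Missingness is injected cell-wise, missing completely at random, with a
separate probability per construct.  The same seed always reproduces the same
dataset; reproducing another implementation's draws bit-for-bit (e.g. a
dataset generated elsewhere with its own seed) is not possible, because RNG
streams differ across platforms and libraries.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spec import BiSpec, SpecificationError, StructuralModel, UniSpec, compile_spec


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = S for a positive *semi*-definite S."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(S)
        scale = max(abs(w).max(), 1.0)
        if w.min() < -1e-8 * scale:
            raise SpecificationError(
                "exogenous covariance matrix implied by theta is not positive "
                f"semi-definite (min eigenvalue {w.min():.3g})"
            )
        return V * np.sqrt(np.clip(w, 0.0, None))


def expand_theta(model: StructuralModel, theta: Mapping[str, float]) -> dict[str, float]:
    """Complete a partial parameter mapping: unspecified labels default to 0.

    Unknown labels are rejected with the full list of valid ones, mirroring
    list()-style partial specification of generating values.
    """
    extra = [k for k in theta if k not in model.params]
    if extra:
        raise SpecificationError(
            f"theta has label(s) {extra} not in the model's parameter table "
            f"{model.params.labels}"
        )
    full = {l: 0.0 for l in model.params.labels}
    full.update({k: float(v) for k, v in theta.items()})
    return full


def simulate(
    spec: UniSpec | BiSpec,
    T: int,
    n: int,
    theta: Mapping[str, float],
    na_x_pct: float = 0.0,
    na_y_pct: float = 0.0,
    seed: int | None = None,
    var_x: Sequence[str] | None = None,
    var_y: Sequence[str] | None = None,
    return_latents: bool = False,
):
    """Draw ``n`` individuals from the LCSM defined by ``spec`` and ``theta``.

    Returns a wide DataFrame with columns ``id, x1..xT[, y1..yT]``; with
    ``return_latents=True`` also a companion frame of latent true/change
    scores and change factors (before missingness, for diagnostics).
    """
    for name, pct in (("na_x_pct", na_x_pct), ("na_y_pct", na_y_pct)):
        if not 0.0 <= pct < 1.0:
            raise SpecificationError(f"{name}={pct} must lie in [0, 1)")
    model = compile_spec(spec, T, var_x=var_x, var_y=var_y)
    vec = model.theta_vector(expand_theta(model, theta))
    A, S, m = model.materialize(vec)
    rng = np.random.default_rng(seed)
    L = _psd_factor(S)
    e = rng.standard_normal((n, model.nvar)) @ L.T
    v = np.linalg.solve(np.eye(model.nvar) - A, (m + e).T).T
    obs = v[:, model.obs_idx].copy()

    pct_by_construct = {"x": na_x_pct, "y": na_y_pct}
    for c, meta in model.constructs.items():
        pct = pct_by_construct[c]
        if pct > 0:
            cols = [model.obs_names.index(name) for name in meta["obs"]]
            mask = rng.random((n, len(cols))) < pct
            block = obs[:, cols]
            block[mask] = np.nan
            obs[:, cols] = block

    data = pd.DataFrame(obs, columns=model.obs_names)
    data.insert(0, "id", np.arange(1, n + 1))
    if not return_latents:
        return data
    latent_names = [name for name in model.names if name not in model.obs_names]
    latent_idx = [model.names.index(name) for name in latent_names]
    latents = pd.DataFrame(v[:, latent_idx], columns=latent_names)
    latents.insert(0, "id", np.arange(1, n + 1))
    return data, latents


def inject_missingness(
    data: pd.DataFrame,
    pct: float | Mapping[str, float],
    seed: int | None = None,
    id_col: str = "id",
) -> pd.DataFrame:
    """Mask cells MCAR, cell-wise independently; the id column is never masked.

    ``pct`` is either one proportion for all non-id columns or a mapping from
    column prefix to proportion (a prefix matches columns ``<prefix><digits>``).
    """
    rng = np.random.default_rng(seed)
    out = data.copy()
    value_cols = [c for c in data.columns if c != id_col]
    if isinstance(pct, Mapping):
        plan = []
        for prefix, p in pct.items():
            cols = [c for c in value_cols if re.fullmatch(re.escape(prefix) + r"\d+", c)]
            plan.append((cols, float(p)))
    else:
        plan = [(value_cols, float(pct))]
    for cols, p in plan:
        if not 0.0 <= p < 1.0:
            raise SpecificationError(f"missingness proportion {p} must lie in [0, 1)")
        if p == 0.0 or not cols:
            continue
        mask = rng.random((len(out), len(cols))) < p
        block = out.loc[:, cols].to_numpy(dtype=float)
        block[mask] = np.nan
        out.loc[:, cols] = block
    return out
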