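"""Declarative model specification for latent change score models (LCSMs).

A univariate LCSM decomposes an observed repeated measure ``x[t]`` into a
latent true score ``lx[t]`` plus an occasion-specific unique score.  Adjacent
true scores are linked through latent change scores ``dx[t] = lx[t] - lx[t-1]``,
and the change scores themselves can be driven by

* a constant change factor ``g2`` (unit loadings on every change score, a
  latent "slope" with mean ``alpha_g2`` and variance ``sigma2_g2``),
* proportional change ``beta_x`` (regression of ``dx[t]`` on ``lx[t-1]``),
* an autoregression of change scores ``phi_x`` (``dx[t]`` on ``dx[t-1]``).

A bivariate LCSM pairs two such models and adds coupling regressions between
the constructs: ``delta`` couplings use the other construct's true scores as
sources, ``xi`` couplings its change scores, either concurrently (``con``) or
with a one-occasion lag (``lag``).

This module turns those declarative options into (a) the exact set of free
parameters and (b) a RAM-style structural model (directed paths ``A``,
symmetric covariances ``S``, means ``m``, and an observed-variable filter)
with a label -> cells map encoding equality constraints over time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class SpecificationError(ValueError):
    """Inconsistent or incomplete model options."""


class Role(str, Enum):
    MEAN = "mean"
    VARIANCE = "variance"
    COVARIANCE = "covariance"
    REGRESSION = "regression"


_GREEK = {
    "gamma": "γ",
    "alpha": "α",
    "beta": "β",
    "phi": "ϕ",
    "delta": "δ",
    "xi": "ξ",
    "sigma": "σ",
    "sigma2": "σ²",
}


def label_symbol(label: str) -> str:
    """Greek rendering of a parameter label, e.g. ``sigma2_lx1`` -> ``σ²_lx1``."""
    head, _, rest = label.partition("_")
    if head in _GREEK:
        return f"{_GREEK[head]}_{rest}"
    # coupling regressions keep their full subscript: delta_con_xy -> δ_con_xy
    return label


def label_role(label: str) -> Role:
    if label.startswith("sigma2_"):
        return Role.VARIANCE
    if label.startswith("sigma_"):
        return Role.COVARIANCE
    if label.startswith(("gamma_", "alpha_")):
        return Role.MEAN
    return Role.REGRESSION


@dataclass(frozen=True)
class Parameter:
    label: str
    symbol: str
    role: Role


class ParameterTable:
    """Ordered collection of the free parameters implied by a specification."""

    def __init__(self, labels: Sequence[str]):
        if len(set(labels)) != len(labels):
            raise SpecificationError(f"duplicate parameter labels: {list(labels)}")
        self.parameters = [Parameter(l, label_symbol(l), label_role(l)) for l in labels]
        self._index = {p.label: i for i, p in enumerate(self.parameters)}

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.parameters]

    def index(self, label: str) -> int:
        return self._index[label]

    def __len__(self) -> int:
        return len(self.parameters)

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self.parameters)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.parameters],
                "symbol": [p.symbol for p in self.parameters],
                "role": [p.role.value for p in self.parameters],
            }
        )


# ---------------------------------------------------------------------------
# Declarative specifications
# ---------------------------------------------------------------------------

_CHANGE_FACTOR_FLAGS = ("alpha_constant", "alpha_piecewise", "alpha_linear")

COUPLING_FLAGS = (
    "delta_con_xy",
    "delta_con_yx",
    "delta_lag_xy",
    "delta_lag_yx",
    "xi_con_xy",
    "xi_con_yx",
    "xi_lag_xy",
    "xi_lag_yx",
)


@dataclass(frozen=True)
class UniSpec:
    """Options for one construct's change process (one flag per model option)."""

    alpha_constant: bool = False
    alpha_piecewise: bool = False
    alpha_piecewise_num: int | None = None
    alpha_linear: bool = False
    beta: bool = False
    phi: bool = False

    def validate(self, T: int) -> None:
        if T < 2:
            raise SpecificationError("an LCSM needs at least 2 repeated measures")
        active = [f for f in _CHANGE_FACTOR_FLAGS if getattr(self, f)]
        if len(active) > 1:
            raise SpecificationError(
                "conflicting change-factor options: " + ", ".join(active)
            )
        if self.alpha_piecewise:
            k = self.alpha_piecewise_num
            if k is None:
                raise SpecificationError(
                    "alpha_piecewise requires alpha_piecewise_num (the change point)"
                )
            if not 2 <= k <= T - 1:
                raise SpecificationError(
                    f"alpha_piecewise_num={k} must lie in [2, T-1] = [2, {T - 1}]"
                )
        if self.phi and T < 3:
            raise SpecificationError(
                "phi needs two successive change scores, i.e. T >= 3"
            )

    def change_factors(self, T: int, letter: str) -> list[tuple[str, dict[int, float]]]:
        """Change factors as ``(name, {t: loading on d<c>[t]})``.

        ``letter`` is ``"g"`` for construct x and ``"j"`` for construct y.
        """
        if self.alpha_constant:
            return [(f"{letter}2", {t: 1.0 for t in range(2, T + 1)})]
        if self.alpha_linear:
            return [(f"{letter}2", {t: float(t - 1) for t in range(2, T + 1)})]
        if self.alpha_piecewise:
            k = self.alpha_piecewise_num
            return [
                (f"{letter}2", {t: 1.0 for t in range(2, k + 1)}),
                (f"{letter}3", {t: 1.0 for t in range(k + 1, T + 1)}),
            ]
        return []


@dataclass(frozen=True)
class CouplingSpec:
    """Between-construct coupling options of a bivariate LCSM."""

    delta_con_xy: bool = False
    delta_con_yx: bool = False
    delta_lag_xy: bool = False
    delta_lag_yx: bool = False
    xi_con_xy: bool = False
    xi_con_yx: bool = False
    xi_lag_xy: bool = False
    xi_lag_yx: bool = False
    coupling_piecewise: bool = False
    coupling_piecewise_num: int | None = None

    def active(self) -> list[str]:
        return [f for f in COUPLING_FLAGS if getattr(self, f)]

    def validate(self, T: int) -> None:
        if self.coupling_piecewise:
            k = self.coupling_piecewise_num
            if k is None:
                raise SpecificationError(
                    "coupling_piecewise requires coupling_piecewise_num"
                )
            if not 2 <= k <= T - 1:
                raise SpecificationError(
                    f"coupling_piecewise_num={k} must lie in [2, T-1] = [2, {T - 1}]"
                )
        if (self.xi_lag_xy or self.xi_lag_yx) and T < 3:
            raise SpecificationError(
                "lagged change-to-change coupling needs T >= 3"
            )

    def terms(self, T: int) -> list[tuple[str, str, list[tuple[int, str]]]]:
        """Active coupling paths as ``(label, target_construct, [(t, source_var)])``.

        The flag name encodes direction as <target><source>: ``xi_lag_yx``
        regresses ``dy[t]`` on ``dx[t-1]``.  Lagged ``xi`` couplings start at
        t = 3 (they need the source change score to exist); all others at t = 2.
        """
        out: list[tuple[str, str, list[tuple[int, str]]]] = []
        for flag in self.active():
            kind, timing, direction = flag.split("_")
            tgt, src = direction[0], direction[1]
            src_prefix = ("l" if kind == "delta" else "d") + src
            t_start = 3 if (kind == "xi" and timing == "lag") else 2
            pairs = []
            for t in range(t_start, T + 1):
                s_t = t if timing == "con" else t - 1
                pairs.append((t, f"{src_prefix}{s_t}"))
            if self.coupling_piecewise:
                k = self.coupling_piecewise_num
                phase1 = [(t, s) for t, s in pairs if t <= k]
                phase2 = [(t, s) for t, s in pairs if t > k]
                if phase1:
                    out.append((flag + "1", tgt, phase1))
                if phase2:
                    out.append((flag + "2", tgt, phase2))
            else:
                out.append((flag, tgt, pairs))
        return out


@dataclass(frozen=True)
class BiSpec:
    """Bivariate LCSM: two univariate change processes plus their coupling."""

    model_x: UniSpec
    model_y: UniSpec
    coupling: CouplingSpec = field(default_factory=CouplingSpec)

    def validate(self, T: int) -> None:
        self.model_x.validate(T)
        self.model_y.validate(T)
        self.coupling.validate(T)


# ---------------------------------------------------------------------------
# Serialisation of specs (config files, fitted-model JSON)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: UniSpec | BiSpec) -> dict:
    def uni(u: UniSpec) -> dict:
        d = {f.name: getattr(u, f.name) for f in fields(u)}
        return {k: v for k, v in d.items() if v not in (False, None)}

    if isinstance(spec, BiSpec):
        c = {f.name: getattr(spec.coupling, f.name) for f in fields(spec.coupling)}
        return {
            "model_x": uni(spec.model_x),
            "model_y": uni(spec.model_y),
            "coupling": {k: v for k, v in c.items() if v not in (False, None)},
        }
    return uni(spec)


def spec_from_dict(d: Mapping) -> UniSpec | BiSpec:
    def uni(m: Mapping) -> UniSpec:
        valid = {f.name for f in fields(UniSpec)}
        bad = set(m) - valid
        if bad:
            raise SpecificationError(
                f"unknown model option(s) {sorted(bad)}; valid options: {sorted(valid)}"
            )
        return UniSpec(**m)

    if "model_x" in d or "model_y" in d or "coupling" in d:
        coupling = d.get("coupling", {})
        valid = {f.name for f in fields(CouplingSpec)}
        bad = set(coupling) - valid
        if bad:
            raise SpecificationError(
                f"unknown coupling option(s) {sorted(bad)}; valid: {sorted(valid)}"
            )
        return BiSpec(
            model_x=uni(d.get("model_x", {})),
            model_y=uni(d.get("model_y", {})),
            coupling=CouplingSpec(**coupling),
        )
    return uni(d)


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

def _uni_labels(u: UniSpec, T: int, construct: str) -> list[str]:
    """Free-parameter labels of one construct, in catalogue order."""
    lp = "l" + construct
    letter = "g" if construct == "x" else "j"
    factors = [name for name, _ in u.change_factors(T, letter)]
    labels = [f"gamma_{lp}1", f"sigma2_{lp}1", f"sigma2_u{construct}"]
    labels += [f"alpha_{f}" for f in factors]
    labels += [f"sigma2_{f}" for f in factors]
    labels += [f"sigma_{f}{lp}1" for f in factors]
    if len(factors) == 2:
        labels.append(f"sigma_{factors[0]}{factors[1]}")
    if u.beta:
        labels.append(f"beta_{construct}")
    if u.phi:
        labels.append(f"phi_{construct}")
    return labels


def _coupling_cov_labels(fx: list[str], fy: list[str]) -> list[str]:
    """Cross-construct covariance labels for whichever change factors exist."""
    labels = ["sigma_su", "sigma_ly1lx1"]
    if "g2" in fx:
        labels.append("sigma_g2ly1")
    if "g3" in fx:
        labels.append("sigma_g3ly1")
    if "j2" in fy:
        labels.append("sigma_j2lx1")
    if "j3" in fy:
        labels.append("sigma_j3lx1")
    if "g2" in fx and "j2" in fy:
        labels.append("sigma_j2g2")
    if "g3" in fx and "j2" in fy:
        labels.append("sigma_j2g3")
    if "g2" in fx and "j3" in fy:
        labels.append("sigma_j3g2")
    return labels


def build_parameter_table(spec: UniSpec | BiSpec, T: int) -> ParameterTable:
    """The exact set of free parameters implied by the active options.

    Labels are ordered as in the parameter catalogue: construct x block,
    construct y block, then coupling covariances and coupling regressions.
    """
    spec.validate(T)
    if isinstance(spec, UniSpec):
        return ParameterTable(_uni_labels(spec, T, "x"))
    fx = [n for n, _ in spec.model_x.change_factors(T, "g")]
    fy = [n for n, _ in spec.model_y.change_factors(T, "j")]
    labels = _uni_labels(spec.model_x, T, "x")
    labels += _uni_labels(spec.model_y, T, "y")
    labels += _coupling_cov_labels(fx, fy)
    labels += [label for label, _, _ in spec.coupling.terms(T)]
    return ParameterTable(labels)


# ---------------------------------------------------------------------------
# Structural model (RAM matrices)
# ---------------------------------------------------------------------------

@dataclass
class StructuralModel:
    """RAM representation of a compiled LCSM.

    ``A`` holds directed paths (fixed values; free cells are indexed through
    ``label_map``), ``S`` symmetric covariances, ``m`` means/intercepts.  The
    observed-variable filter is implicit in ``obs_names``/``obs_idx``.  Cells
    sharing a label are constrained equal.
    """

    names: list[str]
    obs_names: list[str]
    A: np.ndarray
    S: np.ndarray
    m: np.ndarray
    params: ParameterTable
    label_map: dict[str, list[tuple[str, int, int]]]
    constructs: dict[str, dict]
    spec: UniSpec | BiSpec
    T: int

    def __post_init__(self) -> None:
        self.obs_idx = np.array([self.names.index(v) for v in self.obs_names])
        self._index = {n: i for i, n in enumerate(self.names)}
        # flat index arrays for fast materialisation
        a_i, a_j, a_k, s_i, s_j, s_k, m_i, m_k = [], [], [], [], [], [], [], []
        for label, cells in self.label_map.items():
            k = self.params.index(label)
            for mat, i, j in cells:
                if mat == "A":
                    a_i.append(i); a_j.append(j); a_k.append(k)
                elif mat == "S":
                    s_i.append(i); s_j.append(j); s_k.append(k)
                else:
                    m_i.append(i); m_k.append(k)
        self._a_idx = (np.array(a_i, dtype=int), np.array(a_j, dtype=int), np.array(a_k, dtype=int))
        self._s_idx = (np.array(s_i, dtype=int), np.array(s_j, dtype=int), np.array(s_k, dtype=int))
        self._m_idx = (np.array(m_i, dtype=int), np.array(m_k, dtype=int))

    @property
    def nvar(self) -> int:
        return len(self.names)

    def theta_vector(self, theta: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Coerce a label->value mapping (or ordered sequence) to a vector."""
        if isinstance(theta, Mapping):
            missing = [l for l in self.params.labels if l not in theta]
            extra = [l for l in theta if l not in self.params]
            if missing or extra:
                raise SpecificationError(
                    f"theta does not match the parameter table; missing={missing}, extra={extra}"
                )
            return np.array([float(theta[l]) for l in self.params.labels])
        vec = np.asarray(theta, dtype=float)
        if vec.shape != (len(self.params),):
            raise SpecificationError(
                f"theta has length {vec.shape}, expected {len(self.params)}"
            )
        return vec

    def materialize(self, theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fill the free cells of (A, S, m) with the values in ``theta``."""
        vec = self.theta_vector(theta)
        A = self.A.copy()
        S = self.S.copy()
        m = self.m.copy()
        ai, aj, ak = self._a_idx
        A[ai, aj] = vec[ak]
        si, sj, sk = self._s_idx
        S[si, sj] = vec[sk]
        S[sj, si] = vec[sk]
        mi, mk = self._m_idx
        m[mi] = vec[mk]
        return A, S, m


def _default_names(prefix: str, T: int) -> list[str]:
    return [f"{prefix}{t}" for t in range(1, T + 1)]


def compile_spec(
    spec: UniSpec | BiSpec,
    T: int,
    var_x: Sequence[str] | None = None,
    var_y: Sequence[str] | None = None,
) -> StructuralModel:
    """Compile declarative options into RAM matrices with labelled free cells.

    Observed variables default to ``x1..xT`` (and ``y1..yT``); latent names are
    always canonical (``lx``/``dx``/``g2`` and ``ly``/``dy``/``j2`` prefixes)
    regardless of the observed column names.
    """
    spec.validate(T)
    bivariate = isinstance(spec, BiSpec)
    var_x = list(var_x) if var_x is not None else _default_names("x", T)
    if len(var_x) != T or len(set(var_x)) != T:
        raise SpecificationError(f"need {T} distinct x variable names, got {var_x}")
    constructs: dict[str, dict] = {}
    uni_by_c = {"x": spec.model_x if bivariate else spec}
    if bivariate:
        var_y = list(var_y) if var_y is not None else _default_names("y", T)
        if len(var_y) != T or len(set(var_y)) != T:
            raise SpecificationError(f"need {T} distinct y variable names, got {var_y}")
        if set(var_x) & set(var_y):
            raise SpecificationError("x and y variable names overlap")
        uni_by_c["y"] = spec.model_y

    obs_names: list[str] = []
    latent_names: list[str] = []
    for c, uni in uni_by_c.items():
        obs = var_x if c == "x" else var_y
        letter = "g" if c == "x" else "j"
        factors = uni.change_factors(T, letter)
        constructs[c] = {
            "obs": list(obs),
            "true": [f"l{c}{t}" for t in range(1, T + 1)],
            "change": [f"d{c}{t}" for t in range(2, T + 1)],
            "factors": dict(factors),
        }
        obs_names += list(obs)
        latent_names += constructs[c]["true"] + constructs[c]["change"] + list(
            constructs[c]["factors"]
        )

    names = obs_names + latent_names
    idx = {n: i for i, n in enumerate(names)}
    d = len(names)
    A = np.zeros((d, d))
    S = np.zeros((d, d))
    m = np.zeros(d)
    label_cells: dict[str, list[tuple[str, int, int]]] = defaultdict(list)

    for c, uni in uni_by_c.items():
        meta = constructs[c]
        lp = "l" + c
        for t in range(1, T + 1):
            A[idx[meta["obs"][t - 1]], idx[f"{lp}{t}"]] = 1.0  # x[t] <- lx[t]
            label_cells[f"sigma2_u{c}"].append(("S", idx[meta["obs"][t - 1]], idx[meta["obs"][t - 1]]))
        for t in range(2, T + 1):
            A[idx[f"{lp}{t}"], idx[f"{lp}{t - 1}"]] = 1.0  # true-score autoregression
            A[idx[f"{lp}{t}"], idx[f"d{c}{t}"]] = 1.0  # change-score definition
        label_cells[f"gamma_{lp}1"].append(("m", idx[f"{lp}1"], -1))
        label_cells[f"sigma2_{lp}1"].append(("S", idx[f"{lp}1"], idx[f"{lp}1"]))
        for fname, loadings in meta["factors"].items():
            for t, lam in loadings.items():
                A[idx[f"d{c}{t}"], idx[fname]] = lam
            label_cells[f"alpha_{fname}"].append(("m", idx[fname], -1))
            label_cells[f"sigma2_{fname}"].append(("S", idx[fname], idx[fname]))
            label_cells[f"sigma_{fname}{lp}1"].append(("S", idx[fname], idx[f"{lp}1"]))
        fnames = list(meta["factors"])
        if len(fnames) == 2:
            label_cells[f"sigma_{fnames[0]}{fnames[1]}"].append(
                ("S", idx[fnames[0]], idx[fnames[1]])
            )
        if uni.beta:
            for t in range(2, T + 1):
                label_cells[f"beta_{c}"].append(("A", idx[f"d{c}{t}"], idx[f"{lp}{t - 1}"]))
        if uni.phi:
            for t in range(3, T + 1):
                label_cells[f"phi_{c}"].append(("A", idx[f"d{c}{t}"], idx[f"d{c}{t - 1}"]))

    if bivariate:
        for t in range(1, T + 1):
            label_cells["sigma_su"].append(
                ("S", idx[constructs["x"]["obs"][t - 1]], idx[constructs["y"]["obs"][t - 1]])
            )
        label_cells["sigma_ly1lx1"].append(("S", idx["ly1"], idx["lx1"]))
        fx = list(constructs["x"]["factors"])
        fy = list(constructs["y"]["factors"])
        for f in fx:
            label_cells[f"sigma_{f}ly1"].append(("S", idx[f], idx["ly1"]))
        for f in fy:
            label_cells[f"sigma_{f}lx1"].append(("S", idx[f], idx["lx1"]))
        if "g2" in fx and "j2" in fy:
            label_cells["sigma_j2g2"].append(("S", idx["j2"], idx["g2"]))
        if "g3" in fx and "j2" in fy:
            label_cells["sigma_j2g3"].append(("S", idx["j2"], idx["g3"]))
        if "g2" in fx and "j3" in fy:
            label_cells["sigma_j3g2"].append(("S", idx["j3"], idx["g2"]))
        for label, tgt, pairs in spec.coupling.terms(T):
            for t, src in pairs:
                label_cells[label].append(("A", idx[f"d{tgt}{t}"], idx[src]))

    params = build_parameter_table(spec, T)
    if set(label_cells) != set(params.labels):
        raise AssertionError(
            "internal inconsistency between parameter table and compiled cells: "
            f"{set(label_cells) ^ set(params.labels)}"
        )
    return StructuralModel(
        names=names,
        obs_names=obs_names,
        A=A,
        S=S,
        m=m,
        params=params,
        label_map={l: label_cells[l] for l in params.labels},
        constructs=constructs,
        spec=spec,
        T=T,
    )
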