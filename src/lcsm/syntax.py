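"""Render a compiled structural model as human-readable lavaan-dialect syntax.

The renderer emits one statement per line with section comments, using the
usual operators: ``=~`` (loading), ``~`` (regression / intercept with ``1`` on
the right-hand side), ``~~`` (covariance).  Equality constraints over time are
expressed by repeating the same premultiplied label, so the set of distinct
labels in the text equals the model's parameter table.  Output is
deterministic: the same model always renders byte-identically.
"""

from __future__ import annotations

import re

from .spec import StructuralModel


def _num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _find_label(model: StructuralModel, mat: str, i: int, j: int) -> str | None:
    for label, cells in model.label_map.items():
        if (mat, i, j) in cells or (mat == "S" and ("S", j, i) in cells):
            return label
    return None


def render_syntax(model: StructuralModel) -> str:
    """Emit lavaan-dialect model syntax for a compiled LCSM (LF line endings)."""
    idx = {n: k for k, n in enumerate(model.names)}
    lines: list[str] = []

    def mean_line(var: str) -> str:
        cells = [("m", idx[var], -1)]
        for label, cc in model.label_map.items():
            if cells[0] in cc:
                return f"{var} ~ {label} * 1"
        return f"{var} ~ {_num(model.m[idx[var]])} * 1"

    def var_line(var: str) -> str:
        label = _find_label(model, "S", idx[var], idx[var])
        if label is not None:
            return f"{var} ~~ {label} * {var}"
        return f"{var} ~~ {_num(model.S[idx[var], idx[var]])} * {var}"

    for c, meta in model.constructs.items():
        obs, true, change = meta["obs"], meta["true"], meta["change"]
        lines.append(f"# Construct {c}: latent true scores")
        for o, l in zip(obs, true):
            lines.append(f"{l} =~ 1 * {o}")
        lines.append(f"# Construct {c}: mean of latent true scores")
        lines += [mean_line(l) for l in true]
        lines.append(f"# Construct {c}: variance of latent true scores")
        lines += [var_line(l) for l in true]
        lines.append(f"# Construct {c}: intercepts of observed scores")
        lines += [f"{o} ~ 0 * 1" for o in obs]
        lines.append(f"# Construct {c}: variance of observed scores")
        lines += [var_line(o) for o in obs]
        lines.append(f"# Construct {c}: autoregressions of latent true scores")
        lines += [f"{b} ~ 1 * {a}" for a, b in zip(true[:-1], true[1:])]
        lines.append(f"# Construct {c}: latent change scores")
        lines += [f"{d} =~ 1 * {l}" for d, l in zip(change, true[1:])]
        lines.append(f"# Construct {c}: latent change score means")
        lines += [f"{d} ~ 0 * 1" for d in change]
        lines.append(f"# Construct {c}: latent change score variances")
        lines += [f"{d} ~~ 0 * {d}" for d in change]
        for fname, loadings in meta["factors"].items():
            lines.append(f"# Construct {c}: change factor {fname}")
            terms = " + ".join(
                f"{_num(lam)} * d{c}{t}" for t, lam in sorted(loadings.items())
            )
            lines.append(f"{fname} =~ {terms}")
            lines.append(mean_line(fname))
            lines.append(var_line(fname))
            lines.append(f"{fname} ~~ sigma_{fname}l{c}1 * l{c}1")
        fnames = list(meta["factors"])
        if len(fnames) == 2:
            lines.append(f"# Construct {c}: covariance of change factors")
            lines.append(f"{fnames[0]} ~~ sigma_{fnames[0]}{fnames[1]} * {fnames[1]}")
        spec_c = model.spec if not hasattr(model.spec, "model_x") else getattr(
            model.spec, f"model_{c}"
        )
        if spec_c.beta:
            lines.append(f"# Construct {c}: proportional change")
            lines += [
                f"d{c}{t} ~ beta_{c} * l{c}{t - 1}" for t in range(2, model.T + 1)
            ]
        if spec_c.phi:
            lines.append(f"# Construct {c}: autoregression of change scores")
            lines += [
                f"d{c}{t} ~ phi_{c} * d{c}{t - 1}" for t in range(3, model.T + 1)
            ]

    if hasattr(model.spec, "coupling"):
        lines.append("# Coupling: residual covariances")
        for ox, oy in zip(model.constructs["x"]["obs"], model.constructs["y"]["obs"]):
            lines.append(f"{ox} ~~ sigma_su * {oy}")
        lines.append("# Coupling: covariances of intercepts and change factors")
        lines.append("ly1 ~~ sigma_ly1lx1 * lx1")
        for label in model.params.labels:
            if label in ("sigma_su", "sigma_ly1lx1"):
                continue
            if label.startswith("sigma_") and label in (
                "sigma_g2ly1", "sigma_g3ly1", "sigma_j2lx1", "sigma_j3lx1",
                "sigma_j2g2", "sigma_j2g3", "sigma_j3g2",
            ):
                (_, i, j) = model.label_map[label][0]
                lines.append(f"{model.names[i]} ~~ {label} * {model.names[j]}")
        coupling_terms = model.spec.coupling.terms(model.T)
        if coupling_terms:
            lines.append("# Coupling: change-to-change and change-on-true regressions")
            for label, tgt, pairs in coupling_terms:
                for t, src in pairs:
                    lines.append(f"d{tgt}{t} ~ {label} * {src}")

    return "\n".join(lines) + "\n"


_LABEL_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\s*\*")


def syntax_labels(text: str) -> set[str]:
    """Distinct free-parameter labels appearing in rendered syntax."""
    return set(_LABEL_RE.findall(text))
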