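"""Trajectory plots and simplified path diagrams.

The tested artifact is the data behind each figure: ``plot_trajectories``
returns the long-format table it draws, and ``plot_lcsm`` returns a
``DiagramLayout`` whose edge set is exactly the directed-path pattern of the
model's ``A`` matrix plus the off-diagonal free pattern of ``S`` (restricted
to shown nodes).  Rendering is a thin matplotlib layer over those objects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spec import StructuralModel

_LAYER_ORDER = {"observed": 0, "true": 1, "change": 2, "factor": 3}


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _variable_groups(variables) -> dict[str, list[str]]:
    if isinstance(variables, Mapping):
        return {str(k): list(v) for k, v in variables.items()}
    variables = list(variables)
    prefix = variables[0].rstrip("0123456789") or "x"
    return {prefix: variables}


def plot_trajectories(
    data: pd.DataFrame,
    variables,
    id_col: str = "id",
    random_sample_frac: float = 1.0,
    seed: int | None = None,
    connect_missing: bool = False,
):
    """Per-individual trajectory plot, one panel per construct.

    ``variables`` is a list of columns (one construct) or a mapping
    ``{construct: [columns]}``.  A seed-deterministic random fraction of ids
    can be drawn; missing occasions break each line unless
    ``connect_missing`` is set.  Returns ``(figure, long_table)`` where the
    long table has columns ``(id, time, construct, value)`` with missing
    cells dropped.
    """
    groups = _variable_groups(variables)
    if not groups or not any(groups.values()):
        raise ValueError("at least one variable is required")
    for cols in groups.values():
        absent = [c for c in cols if c not in data.columns]
        if absent:
            raise ValueError(f"variable(s) {absent} not in data")
    if not 0.0 < random_sample_frac <= 1.0:
        raise ValueError("random_sample_frac must lie in (0, 1]")
    ids = data[id_col].unique()
    if random_sample_frac < 1.0:
        k = int(round(random_sample_frac * len(ids)))
        if k == 0:
            raise ValueError("random sample is empty")
        rng = np.random.default_rng(seed)
        ids = np.sort(rng.choice(ids, size=k, replace=False))
    subset = data[data[id_col].isin(ids)]

    long_parts = []
    for construct, cols in groups.items():
        part = subset.melt(
            id_vars=[id_col], value_vars=cols, var_name="variable", value_name="value"
        )
        part["time"] = part["variable"].map({c: t for t, c in enumerate(cols, start=1)})
        part["construct"] = construct
        long_parts.append(part[[id_col, "time", "construct", "value"]])
    long_table = pd.concat(long_parts, ignore_index=True).dropna(subset=["value"])
    long_table = long_table.rename(columns={id_col: "id"})

    fig, axes = plt.subplots(
        1, len(groups), figsize=(4.5 * len(groups), 3.5), squeeze=False, sharex=True
    )
    for ax, (construct, cols) in zip(axes[0], groups.items()):
        times = np.arange(1, len(cols) + 1)
        for _, row in subset.iterrows():
            values = row[cols].to_numpy(dtype=float)
            if connect_missing:
                ok = ~np.isnan(values)
                ax.plot(times[ok], values[ok], color="steelblue", alpha=0.4, lw=0.8)
            else:
                ax.plot(times, values, color="steelblue", alpha=0.4, lw=0.8)
        ax.set_title(construct)
        ax.set_xlabel("time")
        ax.set_xticks(times)
    axes[0][0].set_ylabel("score")
    fig.tight_layout()
    return fig, long_table


# ---------------------------------------------------------------------------
# Path diagrams
# ---------------------------------------------------------------------------

@dataclass
class DiagramNode:
    name: str
    shape: str  # "square" | "circle"
    layer: str  # "observed" | "true" | "change" | "factor"
    x: float
    y: float


@dataclass
class DiagramEdge:
    source: str
    target: str
    kind: str  # "directed" | "bidirectional"
    label: str | None


@dataclass
class DiagramLayout:
    nodes: list[DiagramNode] = field(default_factory=list)
    edges: list[DiagramEdge] = field(default_factory=list)

    def node(self, name: str) -> DiagramNode:
        return next(nd for nd in self.nodes if nd.name == name)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(
            {"nodes": [asdict(n) for n in self.nodes], "edges": [asdict(e) for e in self.edges]},
            indent=indent,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _classify(model: StructuralModel, name: str) -> tuple[str, str] | None:
    for c, meta in model.constructs.items():
        if name in meta["obs"]:
            return c, "observed"
        if name in meta["true"]:
            return c, "true"
        if name in meta["change"]:
            return c, "change"
        if name in meta["factors"]:
            return c, "factor"
    return None


def build_layout(model: StructuralModel, show_residuals: bool = False) -> DiagramLayout:
    """Layered left-to-right layout: time on x, model layer on y.

    For bivariate models the y construct is mirrored below the x construct so
    the two change-factor layers face each other.  Residual (unique score)
    nodes are hidden by default.
    """
    layout = DiagramLayout()
    sign = {"x": 1.0, "y": -1.0}
    for c, meta in model.constructs.items():
        s = sign.get(c, 1.0)  # construct y mirrored below construct x
        for t, name in enumerate(meta["obs"], start=1):
            layout.nodes.append(DiagramNode(name, "square", "observed", t, s * 1.0))
        for t, name in enumerate(meta["true"], start=1):
            layout.nodes.append(DiagramNode(name, "circle", "true", t, s * 2.0))
        for t, name in enumerate(meta["change"], start=2):
            layout.nodes.append(DiagramNode(name, "circle", "change", t - 0.5, s * 3.0))
        for k, (fname, loadings) in enumerate(meta["factors"].items()):
            xs = [t for t in loadings]
            layout.nodes.append(
                DiagramNode(fname, "circle", "factor", float(np.mean(xs)) + k, s * 4.0)
            )
        if show_residuals:
            for t, name in enumerate(meta["obs"], start=1):
                layout.nodes.append(
                    DiagramNode(f"u_{name}", "circle", "observed", t + 0.3, s * 0.3)
                )
                layout.edges.append(DiagramEdge(f"u_{name}", name, "directed", None))
    shown = {nd.name for nd in layout.nodes}

    label_of = {}
    for label, cells in model.label_map.items():
        for cell in cells:
            label_of[cell] = label
    d = model.nvar
    for i in range(d):
        for j in range(d):
            tgt, src = model.names[i], model.names[j]
            if tgt not in shown or src not in shown:
                continue
            label = label_of.get(("A", i, j))
            if model.A[i, j] != 0.0 or label is not None:
                text = label if label is not None else (
                    None if model.A[i, j] == 1.0 else f"{model.A[i, j]:g}"
                )
                layout.edges.append(DiagramEdge(src, tgt, "directed", text))
    for i in range(d):
        for j in range(i):
            label = label_of.get(("S", i, j)) or label_of.get(("S", j, i))
            a, b = model.names[i], model.names[j]
            if label is not None and a in shown and b in shown:
                layout.edges.append(DiagramEdge(b, a, "bidirectional", label))
    return layout


def render_layout(layout: DiagramLayout):
    fig, ax = plt.subplots(figsize=(10, 6))
    pos = {nd.name: (nd.x, nd.y) for nd in layout.nodes}
    for nd in layout.nodes:
        marker = "s" if nd.shape == "square" else "o"
        ax.scatter(*pos[nd.name], s=900, marker=marker, facecolor="white",
                   edgecolor="black", zorder=3)
        ax.annotate(nd.name, pos[nd.name], ha="center", va="center", fontsize=7, zorder=4)
    for ed in layout.edges:
        (x0, y0), (x1, y1) = pos[ed.source], pos[ed.target]
        style = "<->" if ed.kind == "bidirectional" else "->"
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(arrowstyle=style, color="gray", lw=0.8,
                            shrinkA=16, shrinkB=16),
        )
        if ed.label:
            ax.annotate(ed.label, ((x0 + x1) / 2, (y0 + y1) / 2),
                        fontsize=6, color="firebrick", ha="center")
    ax.set_axis_off()
    fig.tight_layout()
    return fig


def plot_lcsm(model: StructuralModel, show_residuals: bool = False):
    """Simplified path diagram; returns ``(layout, figure)``."""
    layout = build_layout(model, show_residuals=show_residuals)
    fig = render_layout(layout)
    return layout, fig
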