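"""Tabular extraction of fit statistics and parameter estimates.

Both extractors return pandas DataFrames that serialise losslessly to CSV or
JSON.  The human-facing printer rounds to 3 significant digits and can format
p-values journal-style (``< .001``, otherwise three decimals without the
leading zero).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .engine import FittedModel, fitted_from_dict

_FIT_COLUMNS = ["model", "chisq", "npar", "aic", "bic", "cfi", "rmsea", "srmr"]
_FIT_DETAILS = ["df", "pvalue", "loglik", "n"]


def _as_fitted(obj) -> FittedModel:
    if isinstance(obj, FittedModel):
        return obj
    if isinstance(obj, Mapping):
        return fitted_from_dict(obj)
    raise TypeError(f"expected FittedModel or its JSON dict, got {type(obj)!r}")


def format_p(p: float) -> str:
    """``< .001`` below 0.001, else three decimals without the leading zero."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "< .001"
    text = f"{p:.3f}"
    return text[1:] if text.startswith("0") else text


def extract_fit(*models, details: bool = False) -> pd.DataFrame:
    """One row of fit statistics per fitted model, ordered as passed."""
    rows = []
    for k, obj in enumerate(models, start=1):
        fitted = _as_fitted(obj)
        fs = fitted.fit
        row = {
            "model": str(k),
            "chisq": fs.chisq if fs else np.nan,
            "npar": fitted.npar,
            "aic": fs.aic if fs else np.nan,
            "bic": fs.bic if fs else np.nan,
            "cfi": (fs.cfi if fs and fs.cfi is not None else np.nan),
            "rmsea": (fs.rmsea if fs and fs.rmsea is not None else np.nan),
            "srmr": (fs.srmr if fs and fs.srmr is not None else np.nan),
        }
        if details:
            row.update(
                {
                    "df": fs.df if fs else np.nan,
                    "pvalue": (fs.pvalue if fs and fs.pvalue is not None else np.nan),
                    "loglik": fitted.loglik,
                    "n": fitted.n_used,
                }
            )
        rows.append(row)
    columns = _FIT_COLUMNS + (_FIT_DETAILS if details else [])
    return pd.DataFrame(rows, columns=columns)


def extract_param(model, printp: bool = False) -> pd.DataFrame:
    """One row per free parameter: estimate, SE, Wald z and two-sided p."""
    from scipy import stats

    fitted = _as_fitted(model)
    labels = fitted.model.params.labels
    est = np.array([fitted.estimates[l] for l in labels])
    if fitted.standard_errors is not None:
        se = np.array([fitted.standard_errors[l] for l in labels])
        stat = est / se
        pvals = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        se = np.full(len(labels), np.nan)
        stat = np.full(len(labels), np.nan)
        pvals = np.full(len(labels), np.nan)
    table = pd.DataFrame(
        {
            "label": labels,
            "estimate": est,
            "std.error": se,
            "statistic": stat,
            "p.value": [format_p(p) for p in pvals] if printp else pvals,
        }
    )
    return table


def _sig3(x) -> str:
    if isinstance(x, str) or x is None:
        return "" if x is None else x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if not np.isfinite(x):
        return ""
    return np.format_float_positional(
        float(x), precision=3, unique=False, fractional=False, trim="-"
    )


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering at 3 significant digits."""
    show = table.copy()
    for col in show.columns:
        show[col] = [_sig3(v) for v in show[col]]
    widths = {
        col: max(len(col), *(len(v) for v in show[col])) if len(show) else len(col)
        for col in show.columns
    }
    header = "  ".join(col.rjust(widths[col]) for col in show.columns)
    lines = [header]
    for _, row in show.iterrows():
        lines.append("  ".join(str(row[col]).rjust(widths[col]) for col in show.columns))
    return "\n".join(lines)
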