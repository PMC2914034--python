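"""Rendering of regression and descriptive tables.

Regression tables show one outcome across the three specifications with
``IRR(SE)`` cells and significance stars (* p<0.10, ** p<0.05, *** p<0.01,
two-sided normal test on the coefficient).  Every printed number is a
rounded field of a fit result; no arithmetic happens at the formatting
stage.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cohort import ModelSpec
from .count_models import FitResult

__all__ = ["stars", "format_cell", "regression_table", "render_table", "results_payload"]

_SPEC_LABEL = {
    ModelSpec.STATIC_BASE: "Static (base)",
    ModelSpec.STATIC_CRE: "Static (CRE)",
    ModelSpec.DYNAMIC: "Dynamic",
}


def stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def _sig4(x: float) -> str:
    if not np.isfinite(x):
        return "nan"
    return f"{x:.4g}"


def format_cell(irr: float, irr_se: float, p: float) -> str:
    """One table cell in the ``IRR***(SE)`` style."""
    return f"{_sig4(irr)}{stars(p)}({_sig4(irr_se)})"


def regression_table(results: dict[ModelSpec, FitResult]) -> pd.DataFrame:
    """Three-column IRR(SE) table for one outcome.

    Rows are the union of coefficient names in fit order; specifications
    missing a row (e.g. static fits lack the lag terms) show an empty cell.
    """
    order: list[str] = []
    for res in results.values():
        for name in res.params.index:
            if name not in order:
                order.append(name)
    footer = ["log-likelihood", "observations", "individuals"]
    any_warn = any(not res.converged for res in results.values())
    index = order + footer + (["WARNING"] if any_warn else [])
    table = pd.DataFrame(index=index)
    for spec, res in results.items():
        sf = res.summary_frame()
        col = {}
        for name in order:
            if name in sf.index:
                r = sf.loc[name]
                col[name] = format_cell(r["irr"], r["irr_se"], r["p"])
        col["log-likelihood"] = _sig4(res.loglik)
        col["observations"] = str(res.n_obs)
        col["individuals"] = str(res.n_persons)
        if not res.converged:
            col["WARNING"] = "did not converge"
        table[_SPEC_LABEL[ModelSpec(spec)]] = pd.Series(col)
    return table.fillna("")


def render_table(table: pd.DataFrame, fmt: str = "text", title: str = "") -> str:
    """Render a table as aligned text, TSV or Markdown."""
    if fmt == "tsv":
        body = table.to_csv(sep="\t")
    elif fmt == "md":
        body = table.to_markdown()
    elif fmt == "text":
        body = table.to_string()
    else:
        raise ValueError("fmt must be text, tsv or md")
    return (title + "\n" + body) if title else body


def results_payload(all_results: dict[str, dict[ModelSpec, FitResult]], meta: dict | None = None) -> str:
    """Deterministic machine-readable JSON for a full analysis run."""
    payload = {
        "meta": meta or {},
        "fits": {
            outcome: {ModelSpec(spec).value: res.to_dict() for spec, res in by_spec.items()}
            for outcome, by_spec in all_results.items()
        },
    }
    return json.dumps(payload, sort_keys=True, indent=1)
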