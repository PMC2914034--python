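"""Group descriptive tables and two-group comparison tests.

Summaries are stratified by the transition grouping (none / single /
multiple Medicaid transitions).  Baseline covariates are summarized one
value per person; round-varying covariates and utilization counts are
summarized per person-round, so utilization means are on the per-round
scale.  The comparison tests are a Welch (unequal-variance) two-sample
t-test for continuous variables and a pooled two-proportion z-test for
binary ones; both are two-sided and compare each transition group against
the no-transition group.  The original analyses of such tables rarely name
their tests, so agreement in kind should not be mistaken for agreement in
method.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import TransitionGroup, transition_profiles
from .panel_io import COUNT_COLUMNS, PanelDataset, STATIC_COLUMNS

__all__ = ["two_group_test", "summarize_by_group"]

#: Variables summarized per person (constant within person).
PERSON_LEVEL = list(STATIC_COLUMNS)
#: Variables summarized per person-round.
ROUND_LEVEL = ["employed", "healthy", "income"] + COUNT_COLUMNS

_BINARY = {"male", "married", "high_school", "white", "employed", "healthy"}


def two_group_test(values_a, values_b, kind: str = "continuous") -> float:
    """Two-sided p-value comparing two independent samples.

    ``kind="continuous"`` runs a Welch t-test; ``kind="binary"`` runs a
    pooled two-proportion z-test on 0/1 samples.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind == "continuous":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            return 1.0 if a.mean() != b.mean() else 1.0  # degenerate: no variance
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if kind == "binary":
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("binary test requires 0/1 samples")
        n1, n2 = len(a), len(b)
        p1, p2 = a.mean(), b.mean()
        pooled = (a.sum() + b.sum()) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        if se == 0:
            return 1.0
        z = (p1 - p2) / se
        return float(2 * special.ndtr(-abs(z)))
    raise ValueError("kind must be 'continuous' or 'binary'")


def _stat_disp(values: np.ndarray, binary: bool) -> tuple[float, float]:
    mean = float(values.mean())
    if len(values) < 2:
        warnings.warn("single observation in group: dispersion undefined")
        sd = float("nan")
    else:
        sd = float(values.std(ddof=1))
    if binary:
        return 100.0 * mean, sd
    return mean, sd


def summarize_by_group(dataset: PanelDataset, variables=None) -> pd.DataFrame:
    """Group means/percentages with dispersion and p-values vs the no-transition group.

    Returns one row per variable with columns ``none``, ``none_sd``,
    ``single``, ``single_sd``, ``p_single``, ``multiple``, ``multiple_sd``,
    ``p_multiple`` and a ``level`` marker (person vs person-round).  Binary
    variables are reported as percentages; their tests are two-proportion
    z-tests, all others Welch t-tests.
    """
    if variables is None:
        variables = PERSON_LEVEL + ROUND_LEVEL
    unknown = [v for v in variables if v not in PERSON_LEVEL + ROUND_LEVEL]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")

    profiles = transition_profiles(dataset)
    df = dataset.data.join(profiles[["group"]], on="person_id")
    person_df = df[df["round"] == 1].set_index("person_id")

    rows = []
    for var in variables:
        binary = var in _BINARY
        per_person = var in PERSON_LEVEL
        source = person_df if per_person else df
        groups = {
            g: source.loc[source["group"] == g, var].to_numpy(dtype=float)
            for g in TransitionGroup
        }
        row = {"variable": var, "level": "person" if per_person else "person-round"}
        for g, label in ((TransitionGroup.NONE, "none"), (TransitionGroup.SINGLE, "single"),
                         (TransitionGroup.MULTIPLE, "multiple")):
            vals = groups[g]
            if len(vals) == 0:
                row[label], row[f"{label}_sd"] = float("nan"), float("nan")
            else:
                row[label], row[f"{label}_sd"] = _stat_disp(vals, binary)
        kind = "binary" if binary else "continuous"
        for g, label in ((TransitionGroup.SINGLE, "p_single"), (TransitionGroup.MULTIPLE, "p_multiple")):
            try:
                row[label] = two_group_test(groups[g], groups[TransitionGroup.NONE], kind=kind)
            except ValueError:
                row[label] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["group_counts"] = {
        "none": int((profiles["group"] == TransitionGroup.NONE).sum()),
        "single": int((profiles["group"] == TransitionGroup.SINGLE).sum()),
        "multiple": int((profiles["group"] == TransitionGroup.MULTIPLE).sum()),
    }
    return out
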