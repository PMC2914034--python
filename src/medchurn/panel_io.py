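"""Long-format panel schema, CSV interchange and structural validation.

The canonical data layout is one row per person-round ("long" format), the
natural shape both for survey panels such as MEPS and for panel likelihood
evaluation.  A :class:`PanelDataset` wraps a validated, sorted
:class:`pandas.DataFrame` together with the common number of rounds ``T``.

Panels must be *complete*: every person contributes rounds ``1..T`` with no
gaps.  Incomplete persons are rejected by default (``on_incomplete="error"``)
so that sample shrinkage is always an explicit, logged choice, never a silent
side effect of parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed CSV header, in canonical column order.
SCHEMA_COLUMNS = [
    "person_id",
    "round",
    "medicaid",
    "employed",
    "healthy",
    "income",
    "er_visits",
    "outpatient_visits",
    "inpatient_discharges",
    "rx_fills",
    "age",
    "male",
    "married",
    "high_school",
    "white",
    "family_size",
    "chronic_count",
]

#: The four utilization count outcomes.
COUNT_COLUMNS = ["er_visits", "outpatient_visits", "inpatient_discharges", "rx_fills"]

#: 0/1 indicator columns.
BINARY_COLUMNS = ["medicaid", "employed", "healthy", "male", "married", "high_school", "white"]

#: Columns that must be constant within a person (baseline characteristics).
STATIC_COLUMNS = ["age", "male", "married", "high_school", "white", "family_size", "chronic_count"]

#: Columns allowed to vary across rounds within a person.
TIME_VARYING_COLUMNS = ["medicaid", "employed", "healthy", "income"] + COUNT_COLUMNS


class PanelSchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class PanelValidationError(ValueError):
    """The data violate a structural invariant of the panel."""


@dataclass(frozen=True)
class PanelDataset:
    """A validated complete panel: every person observed in rounds ``1..T``.

    Attributes
    ----------
    data:
        Long-format frame with the :data:`SCHEMA_COLUMNS`, sorted by
        ``(person_id, round)`` with a RangeIndex.
    n_rounds:
        The common number of rounds ``T`` shared by all persons.
    """

    data: pd.DataFrame
    n_rounds: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_rounds == 0 and len(self.data):
            object.__setattr__(self, "n_rounds", int(self.data["round"].max()))

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    @property
    def person_ids(self) -> np.ndarray:
        return self.data["person_id"].unique()

    def person(self, person_id) -> pd.DataFrame:
        """Rows of a single person, ordered by round."""
        sub = self.data[self.data["person_id"] == person_id]
        if sub.empty:
            raise KeyError(f"unknown person_id {person_id!r}")
        return sub

    def __eq__(self, other) -> bool:  # logical, not identity, equality
        if not isinstance(other, PanelDataset):
            return NotImplemented
        if self.n_rounds != other.n_rounds:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False, rtol=0, atol=1e-12)
        except AssertionError:
            return False
        return True


def _check_integral(series: pd.Series, name: str) -> None:
    vals = series.to_numpy(dtype=float)
    bad = ~np.isclose(vals, np.round(vals)) | ~np.isfinite(vals)
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise PanelValidationError(
            f"column {name!r} must be integral; offending value {vals[bad][0]!r} at data row {series.index[row]}"
        )


def validate_panel(df: pd.DataFrame) -> None:
    """Raise if ``df`` violates any schema or structural invariant.

    Checks, in order: presence of every schema column; integrality and
    non-negativity of counts; 0/1 coding of indicators; uniqueness of
    ``(person_id, round)``; the complete-panel rule (consecutive rounds
    ``1..T`` with a common ``T``); and constancy of baseline covariates
    within person.
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return
    if df[SCHEMA_COLUMNS].isna().any().any():
        col = df[SCHEMA_COLUMNS].isna().any().idxmax()
        raise PanelValidationError(f"column {col!r} contains missing values")

    for col in COUNT_COLUMNS + ["round", "family_size", "chronic_count"]:
        _check_integral(df[col], col)
    for col in COUNT_COLUMNS + ["chronic_count", "income"]:
        if (df[col].to_numpy(dtype=float) < 0).any():
            raise PanelValidationError(f"column {col!r} contains negative values")
    if (df["family_size"].to_numpy(dtype=float) < 1).any():
        raise PanelValidationError("family_size must be a positive integer")
    for col in BINARY_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise PanelValidationError(f"column {col!r} must be 0/1; found {bad!r}")
    if (df["round"].to_numpy(dtype=float) < 1).any():
        raise PanelValidationError("round indices must be >= 1")

    if df.duplicated(subset=["person_id", "round"]).any():
        dup = df[df.duplicated(subset=["person_id", "round"])].iloc[0]
        raise PanelValidationError(
            f"duplicate (person_id, round) pair: ({dup['person_id']!r}, {int(dup['round'])})"
        )

    rounds_by_person = df.groupby("person_id", sort=False)["round"]
    t_max = int(df["round"].max())
    sizes = rounds_by_person.size()
    mins = rounds_by_person.min()
    maxs = rounds_by_person.max()
    bad = sizes.index[(sizes != t_max) | (mins != 1) | (maxs != t_max)]
    if len(bad):
        raise PanelValidationError(
            f"incomplete panel: person(s) {list(bad[:5])} lack consecutive rounds 1..{t_max}"
        )

    nun = df.groupby("person_id", sort=False)[STATIC_COLUMNS].nunique()
    varying = nun.gt(1)
    if varying.any().any():
        col = varying.any().idxmax()
        pid = varying.index[varying[col]][0]
        raise PanelValidationError(
            f"baseline covariate {col!r} varies within person {pid!r}"
        )


def from_dataframe(df: pd.DataFrame, on_incomplete: str = "error") -> PanelDataset:
    """Validate a long-format frame and wrap it as a :class:`PanelDataset`.

    Parameters
    ----------
    on_incomplete:
        ``"error"`` (default) raises on persons whose round sequence is not
        ``1..T``; ``"drop"`` removes them before the final validation.
    """
    if on_incomplete not in ("error", "drop"):
        raise ValueError("on_incomplete must be 'error' or 'drop'")
    df = df.copy()
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[SCHEMA_COLUMNS]
    if len(df) and on_incomplete == "drop":
        t_max = int(pd.to_numeric(df["round"]).max())
        grp = df.groupby("person_id", sort=False)["round"]
        ok = (grp.transform("size") == t_max) & (grp.transform("min") == 1) & (grp.transform("max") == t_max)
        df = df[ok]
    df = df.sort_values(["person_id", "round"], kind="mergesort").reset_index(drop=True)
    validate_panel(df)
    for col in ["round"] + COUNT_COLUMNS + BINARY_COLUMNS + ["family_size", "chronic_count"]:
        df[col] = df[col].astype(np.int64)
    for col in ("income", "age"):
        df[col] = df[col].astype(float)
    t = int(df["round"].max()) if len(df) else 0
    return PanelDataset(data=df, n_rounds=t)


def read_panel(path, on_incomplete: str = "error") -> PanelDataset:
    """Read a comma-separated panel file and validate it.

    The file must carry the fixed header of :data:`SCHEMA_COLUMNS` (any
    column order, extra columns ignored), UTF-8 encoded, ``.`` decimal.
    """
    df = pd.read_csv(path)
    return from_dataframe(df, on_incomplete=on_incomplete)


def write_panel(dataset: PanelDataset, path) -> None:
    """Write a panel to CSV such that :func:`read_panel` round-trips it.

    Incomes are written with ``repr`` precision so the read-back dataset is
    logically identical to the in-memory one.
    """
    dataset.data[SCHEMA_COLUMNS].to_csv(path, index=False, float_format="%.17g")
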