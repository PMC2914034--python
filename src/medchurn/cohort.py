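"""Derived analysis variables and model frames.

This module turns a validated :class:`~medchurn.panel_io.PanelDataset` into
the regression inputs of the three model specifications:

* ``static_base`` — random-effects Poisson with baseline and round-varying
  covariates plus indicators for one and for multiple Medicaid transitions;
* ``static_cre`` — the correlated-random-effects (Mundlak) augmentation,
  adding within-person means of employment and health status so the
  individual effect may correlate with those histories;
* ``dynamic`` — the dynamic specification, adding ``h`` of the lagged
  outcome and ``h`` of the round-1 outcome (the Wooldridge initial-condition
  device) and restricting the sample to rounds ``2..T``.

A "transition" is any adjacent-round change of the Medicaid indicator;
persons are grouped as no-transition (continuously enrolled, since the
sample is enrolled in at least one round), single-transition, or
multiple-transition.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import PanelDataset, TIME_VARYING_COLUMNS


class TransitionGroup(enum.Enum):
    NONE = "none"
    SINGLE = "single"
    MULTIPLE = "multiple"


class ModelSpec(enum.Enum):
    """The three model specifications, in increasing order of structure."""

    STATIC_BASE = "static_base"
    STATIC_CRE = "static_cre"
    DYNAMIC = "dynamic"


_H_FORMS = {
    "identity": lambda y: np.asarray(y, dtype=float),
    "log1p": lambda y: np.log1p(np.asarray(y, dtype=float)),
}


@dataclass(frozen=True)
class TransitionProfile:
    person_id: object
    n_transitions: int
    group: TransitionGroup


@dataclass
class ModelFrame:
    """Design matrix and outcome for one specification of one outcome.

    Rows are grouped contiguously by person and ordered by round within
    person; ``person_index`` holds contiguous 0-based person codes and
    ``person_starts`` the row offsets where each person's block begins.
    """

    outcome: str
    spec: ModelSpec
    y: np.ndarray
    X: pd.DataFrame
    person_index: np.ndarray
    person_starts: np.ndarray
    rounds: np.ndarray
    person_ids: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_persons(self) -> int:
        return len(self.person_starts)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def count_transitions(enrollment) -> int:
    """Number of adjacent-round changes in a 0/1 enrollment sequence.

    Warns (does not fail) if the person was never enrolled, since the study
    sample is defined by Medicaid enrollment in at least one round.
    """
    seq = np.asarray(enrollment)
    if seq.ndim != 1 or len(seq) < 1:
        raise ValueError("enrollment must be a non-empty 1-d sequence")
    if not np.isin(seq, (0, 1)).all():
        raise ValueError(f"enrollment entries must be 0/1, got {seq!r}")
    if not seq.any():
        warnings.warn("enrollment sequence is all-zero; person is outside the Medicaid-ever sample")
    return int(np.count_nonzero(np.diff(seq.astype(np.int8))))


def classify_group(n_transitions: int) -> TransitionGroup:
    """Map a transition count to the none / single / multiple grouping."""
    n = int(n_transitions)
    if n < 0:
        raise ValueError("transition count cannot be negative")
    if n == 0:
        return TransitionGroup.NONE
    if n == 1:
        return TransitionGroup.SINGLE
    return TransitionGroup.MULTIPLE


def transition_profiles(dataset: PanelDataset) -> pd.DataFrame:
    """Per-person transition counts and groups.

    Returns a frame indexed by ``person_id`` with columns ``n_transitions``,
    ``group`` (:class:`TransitionGroup`), ``one_transition`` and
    ``multi_transition`` indicator columns.
    """
    df = dataset.data
    n = df.groupby("person_id", sort=False)["medicaid"].agg(
        lambda s: int(np.count_nonzero(np.diff(s.to_numpy())))
    )
    out = n.to_frame("n_transitions")
    out["group"] = out["n_transitions"].map(classify_group)
    out["one_transition"] = (out["n_transitions"] == 1).astype(int)
    out["multi_transition"] = (out["n_transitions"] > 1).astype(int)
    return out


def within_means(dataset: PanelDataset, variables=("employed", "healthy")) -> pd.DataFrame:
    """Within-person arithmetic means of round-varying variables over all rounds."""
    for v in variables:
        if v not in TIME_VARYING_COLUMNS:
            raise KeyError(f"{v!r} is not a round-varying variable")
    means = dataset.data.groupby("person_id", sort=False)[list(variables)].mean()
    return means.rename(columns={v: f"mean_{v}" for v in variables})


def normalize_income(dataset: PanelDataset) -> pd.Series:
    """Income per row divided by the grand mean over all person-rounds.

    The resulting ratio has grand mean exactly 1 by construction.
    """
    inc = dataset.data["income"].to_numpy(dtype=float)
    grand = inc.mean()
    if not grand > 0:
        raise ValueError("income normalization undefined: sample mean income is not positive")
    return pd.Series(inc / grand, index=dataset.data.index, name="income_ratio")


def lag_and_initial(panel: pd.DataFrame, outcome: str) -> tuple[np.ndarray, int]:
    """Lagged outcome (rounds 2..T) and the round-1 initial value of one person.

    ``panel`` is a single person's rows ordered by round.  Returns the lag
    vector aligned with rounds ``2..T`` and the scalar initial value.
    """
    if outcome not in panel.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    y = panel.sort_values("round")[outcome].to_numpy()
    if len(y) < 2:
        raise ValueError("dynamic specification requires at least 2 rounds")
    return y[:-1].copy(), int(y[0])


def build_model_frame(
    dataset: PanelDataset,
    outcome: str,
    spec: ModelSpec | str = ModelSpec.STATIC_BASE,
    h_form: str = "identity",
) -> ModelFrame:
    """Assemble the regressor matrix and outcome vector for one specification.

    Static frames use all ``N*T`` rows; the dynamic frame drops each
    person's first round (``N*(T-1)`` rows) and appends ``h(lagged outcome)``
    and ``h(initial outcome)`` columns.  Round fixed effects are dummies
    with the first modeled round as the reference category.
    """
    spec = ModelSpec(spec)
    if outcome not in dataset.data.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    if h_form not in _H_FORMS:
        raise ValueError(f"h_form must be one of {sorted(_H_FORMS)}")
    T = dataset.n_rounds
    if spec is ModelSpec.DYNAMIC and T < 2:
        raise ValueError("dynamic specification requires T >= 2")

    df = dataset.data.copy()
    profiles = transition_profiles(dataset)
    df = df.join(profiles[["one_transition", "multi_transition"]], on="person_id")
    df["income_ratio"] = normalize_income(dataset)
    means = within_means(dataset)
    df = df.join(means, on="person_id")

    grp = df.groupby("person_id", sort=False)[outcome]
    df["_lag"] = grp.shift(1)
    df["_initial"] = grp.transform("first")

    first_round = 1
    if spec is ModelSpec.DYNAMIC:
        df = df[df["round"] >= 2]
        first_round = 2

    cols = {}
    cols["const"] = np.ones(len(df))
    cols["one_transition"] = df["one_transition"].to_numpy(dtype=float)
    cols["multi_transition"] = df["multi_transition"].to_numpy(dtype=float)
    for c in ("age", "male", "married", "high_school", "white", "family_size",
              "employed", "healthy"):
        cols[c] = df[c].to_numpy(dtype=float)
    cols["income_ratio"] = df["income_ratio"].to_numpy(dtype=float)
    cols["chronic_count"] = df["chronic_count"].to_numpy(dtype=float)
    if spec in (ModelSpec.STATIC_CRE, ModelSpec.DYNAMIC):
        cols["mean_employed"] = df["mean_employed"].to_numpy(dtype=float)
        cols["mean_healthy"] = df["mean_healthy"].to_numpy(dtype=float)
    if spec is ModelSpec.DYNAMIC:
        h = _H_FORMS[h_form]
        cols[f"lag_{outcome}"] = h(df["_lag"].to_numpy(dtype=float))
        cols[f"initial_{outcome}"] = h(df["_initial"].to_numpy(dtype=float))
    for r in range(first_round + 1, T + 1):
        cols[f"round_{r}"] = (df["round"] == r).to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=df.index)
    person_codes, _ = pd.factorize(df["person_id"], sort=False)
    starts = np.flatnonzero(np.r_[True, np.diff(person_codes) != 0])
    return ModelFrame(
        outcome=outcome,
        spec=spec,
        y=df[outcome].to_numpy(dtype=np.int64),
        X=X,
        person_index=person_codes.astype(np.int64),
        person_starts=starts.astype(np.int64),
        rounds=df["round"].to_numpy(dtype=np.int64),
        person_ids=df["person_id"].unique(),
    )
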