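"""Synthetic MEPS-like panel generator with known ground truth.

Emulates the structure of a two-year Medicaid panel: ``N`` adults observed
for ``T`` rounds, a first-order Markov enrollment process producing the
observed mix of no-transition / single-transition / multiple-transition
persons, persistent binary employment and self-rated-health processes,
log-normal household income, and Poisson utilization counts whose log-mean
combines observed covariates, an individual effect correlated with the
person's employment and health histories, and (optionally) state dependence
on the previous round's count.

All randomness flows from a single seed through named substreams, so adding
an outcome or a covariate does not perturb the enrollment draws.

The generated individual effect has the form::

    c_i = exp(g_e * (mean_employed_i - pi_e) + g_h * (mean_healthy_i - pi_h)) * a_i

with ``a_i`` drawn from the configured mixing law (unit-mean gamma by
default).  Because the systematic part is linear in the within-person means,
the correlated-random-effects (Mundlak) specification is correctly specified
on these data while the base static specification omits a relevant,
transition-correlated regressor — the scenario the estimators are designed
to distinguish.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel_io import PanelDataset, SCHEMA_COLUMNS, from_dataframe

__all__ = [
    "EnrollmentChain",
    "CovariateLaws",
    "OutcomeTruth",
    "SimulationConfig",
    "TruthRecord",
    "default_config",
    "simulate_enrollment",
    "simulate_covariates",
    "simulate_outcomes",
    "generate_dataset",
]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class EnrollmentChain:
    """First-order Markov law for the Medicaid indicator.

    ``employed_exit_shift`` / ``employed_entry_shift`` move the log-odds of
    *staying* enrolled (down) and of *staying* unenrolled (up) for currently
    employed persons, tying insurance churn to employment the way eligibility
    rules tie Medicaid to income from work.  ``age_stability_shift`` raises
    both staying log-odds with standardized age, making older enrollees'
    coverage more stable (disability-based eligibility churns less than
    income-based eligibility).  Defaults are calibrated so that with the
    default covariate laws and T=6 the transition-group mix is close to
    53% none / 30% single / 17% multiple among persons enrolled in at least
    one round.
    """

    p_start_enrolled: float = 0.743
    p_stay_enrolled: float = 0.954
    p_stay_unenrolled: float = 0.532
    employed_exit_shift: float = 1.1
    employed_entry_shift: float = 1.1
    age_stability_shift: float = 0.5

    def __post_init__(self):
        for name in ("p_start_enrolled", "p_stay_enrolled", "p_stay_unenrolled"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class CovariateLaws:
    """Distributions of the baseline and round-varying covariates.

    Binary round-varying processes follow a stationary Markov chain
    parameterized by the marginal probability ``pi`` and a persistence
    ``r``: ``P(x_t = 1 | x_{t-1}) = r * x_{t-1} + (1 - r) * pi``
    (``r = 1`` freezes the chain, ``r = 0`` gives i.i.d. draws).  Income is
    log-normal with a person-level location effect, scaled so the population
    mean is 1 (the analysis uses income relative to the sample mean).
    """

    pi_employed: float = 0.31
    r_employed: float = 0.85
    pi_healthy: float = 0.68
    r_healthy: float = 0.85
    income_person_sd: float = 0.5
    income_round_sd: float = 0.3
    income_employed_boost: float = 0.35
    p_male: float = 0.305
    p_married: float = 0.33
    p_high_school: float = 0.48
    p_white: float = 0.67
    age_range: tuple = (18, 64)
    family_size_rate: float = 2.2
    chronic_rate: float = 0.17


@dataclass(frozen=True)
class OutcomeTruth:
    """Generating parameters for one count outcome.

    ``beta`` maps model-frame column names (e.g. ``employed``,
    ``multi_transition``, ``income_ratio``, ``round_3``) to true
    coefficients; unnamed columns have true coefficient 0.  ``gamma_employed``
    and ``gamma_healthy`` set the loading of the individual effect on the
    (centered) within-person means; ``rho`` is the state-dependence
    coefficient on ``h`` of the previous round's count; ``theta``/``sigma``
    parameterize the mixing law.
    """

    beta: dict = field(default_factory=dict)
    mixing_family: str = "gamma"
    theta: float = 1.5
    sigma: float = 0.7
    gamma_employed: float = 0.0
    gamma_healthy: float = 0.0
    rho: float = 0.0
    h_form: str = "identity"

    def __post_init__(self):
        if self.mixing_family not in ("gamma", "normal", "none"):
            raise ValueError("mixing_family must be gamma, normal or none")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.h_form not in ("identity", "log1p"):
            raise ValueError("h_form must be identity or log1p")


@dataclass(frozen=True)
class SimulationConfig:
    """Full truth for one synthetic panel."""

    n_persons: int = 1000
    n_rounds: int = 6
    seed: int = 0
    enrollment: EnrollmentChain = field(default_factory=EnrollmentChain)
    covariates: CovariateLaws = field(default_factory=CovariateLaws)
    outcomes: dict = field(default_factory=dict)  # name -> OutcomeTruth

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        if self.n_rounds < 2:
            raise ValueError("n_rounds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"]["age_range"] = list(self.covariates.age_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "enrollment" in d and isinstance(d["enrollment"], dict):
            d["enrollment"] = EnrollmentChain(**d["enrollment"])
        if "covariates" in d and isinstance(d["covariates"], dict):
            cov = dict(d["covariates"])
            if "age_range" in cov:
                cov["age_range"] = tuple(cov["age_range"])
            d["covariates"] = CovariateLaws(**cov)
        if "outcomes" in d:
            d["outcomes"] = {
                k: (OutcomeTruth(**v) if isinstance(v, dict) else v)
                for k, v in d["outcomes"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Generating parameters plus realized per-person effects (diagnostics only)."""

    config: SimulationConfig
    individual_effects: dict  # outcome -> ndarray of c_i
    group_shares: dict  # none/single/multiple fractions

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "individual_effects": {k: list(map(float, v)) for k, v in self.individual_effects.items()},
            "group_shares": {k: float(v) for k, v in self.group_shares.items()},
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# default truth: four outcomes with magnitudes in the range seen in adult
# Medicaid populations (per-round means of roughly 0.14 ER visits, 2.5
# office visits, 0.09 discharges and 6 prescription fills)

_DEFAULT_OUTCOMES = {
    "er_visits": OutcomeTruth(
        beta={
            "const": -0.78, "one_transition": 0.03, "multi_transition": 0.16,
            "age": -0.013, "male": -0.26, "married": -0.07, "high_school": -0.06,
            "white": -0.06, "family_size": -0.09, "employed": -0.20,
            "healthy": -0.55, "income_ratio": 0.01, "chronic_count": 0.21,
        },
        theta=1.5, gamma_employed=0.06, gamma_healthy=-0.40, rho=-0.02,
    ),
    "outpatient_visits": OutcomeTruth(
        beta={
            "const": 0.77, "one_transition": -0.14, "multi_transition": 0.10,
            "age": 0.005, "male": -0.33, "married": -0.05, "high_school": 0.25,
            "white": 0.14, "family_size": -0.025, "employed": -0.44,
            "healthy": -0.06, "income_ratio": 0.04, "chronic_count": 0.056,
        },
        theta=1.2, gamma_employed=-0.03, gamma_healthy=-0.88, rho=-0.001,
    ),
    "inpatient_discharges": OutcomeTruth(
        beta={
            "const": -1.95, "one_transition": 0.04, "multi_transition": 0.31,
            "age": -0.006, "male": -0.33, "married": 0.07, "high_school": 0.08,
            "white": 0.20, "family_size": -0.023, "employed": -0.76,
            "healthy": -0.55, "income_ratio": -0.02, "chronic_count": 0.25,
        },
        theta=1.5, gamma_employed=0.14, gamma_healthy=-0.43, rho=-0.04,
    ),
    "rx_fills": OutcomeTruth(
        beta={
            "const": 1.18, "one_transition": -0.35, "multi_transition": -0.21,
            "age": 0.023, "male": -0.19, "married": 0.07, "high_school": 0.19,
            "white": 0.05, "family_size": -0.059, "employed": -0.06,
            "healthy": -0.10, "income_ratio": -0.015, "chronic_count": 0.032,
        },
        theta=0.8, gamma_employed=-0.25, gamma_healthy=-1.09, rho=-0.003,
    ),
}


def default_config(n_persons: int = 1000, n_rounds: int = 6, seed: int = 0) -> SimulationConfig:
    """Packaged default: calibrated enrollment churn and four outcomes."""
    return SimulationConfig(
        n_persons=n_persons,
        n_rounds=n_rounds,
        seed=seed,
        outcomes=dict(_DEFAULT_OUTCOMES),
    )


# ---------------------------------------------------------------------------
# simulation primitives


def _streams(seed: int):
    ss = np.random.SeedSequence(seed)
    names = ("statics", "time_varying", "enrollment", "outcomes")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _markov_binary(rng, n, T, pi, r):
    out = np.empty((n, T), dtype=np.int64)
    out[:, 0] = rng.random(n) < pi
    for t in range(1, T):
        p = r * out[:, t - 1] + (1.0 - r) * pi
        out[:, t] = rng.random(n) < p
    return out


def simulate_covariates(config: SimulationConfig, rng_statics, rng_tv):
    """Baseline covariates (per person) and round-varying processes.

    Returns ``(statics, employed, healthy, income)`` where ``statics`` is a
    DataFrame with one row per person and the arrays are ``(N, T)``.
    """
    law = config.covariates
    n, T = config.n_persons, config.n_rounds
    statics = pd.DataFrame(
        {
            "age": rng_statics.integers(law.age_range[0], law.age_range[1] + 1, size=n).astype(float),
            "male": (rng_statics.random(n) < law.p_male).astype(np.int64),
            "married": (rng_statics.random(n) < law.p_married).astype(np.int64),
            "high_school": (rng_statics.random(n) < law.p_high_school).astype(np.int64),
            "white": (rng_statics.random(n) < law.p_white).astype(np.int64),
            "family_size": 1 + rng_statics.poisson(law.family_size_rate, size=n),
            "chronic_count": rng_statics.poisson(law.chronic_rate, size=n),
        }
    )
    employed = _markov_binary(rng_tv, n, T, law.pi_employed, law.r_employed)
    healthy = _markov_binary(rng_tv, n, T, law.pi_healthy, law.r_healthy)
    # location chosen so that E[income] = 1 before the employment boost
    mu = -0.5 * (law.income_person_sd**2 + law.income_round_sd**2)
    person_loc = mu + law.income_person_sd * rng_tv.standard_normal(n)
    noise = law.income_round_sd * rng_tv.standard_normal((n, T))
    income = np.exp(person_loc[:, None] + law.income_employed_boost * (employed - law.pi_employed) + noise)
    return statics, employed, healthy, income


def simulate_enrollment(config: SimulationConfig, rng, employed=None, age=None) -> np.ndarray:
    """Markov enrollment sequences, conditioned on being enrolled at least once.

    ``employed`` (``(N, T)`` binary) and ``age`` (``(N,)`` years) shift the
    transition log-odds per the chain's couplings; omit them for a
    homogeneous chain.  Persons whose drawn sequence is all-zero are
    redrawn, matching a sample defined by Medicaid enrollment in at least
    one round.
    """
    chain = config.enrollment
    law = config.covariates
    n, T = config.n_persons, config.n_rounds
    if employed is None:
        employed = np.zeros((n, T), dtype=np.int64)
    if age is None:
        z_age = np.zeros(n)
    else:
        mid = 0.5 * (law.age_range[0] + law.age_range[1])
        half = max(0.5 * (law.age_range[1] - law.age_range[0]), 1.0)
        z_age = (np.asarray(age, dtype=float) - mid) / half
    logit_stay_e = _logit(np.clip(chain.p_stay_enrolled, 1e-9, 1 - 1e-9))
    logit_stay_u = _logit(np.clip(chain.p_stay_unenrolled, 1e-9, 1 - 1e-9))
    out = np.empty((n, T), dtype=np.int64)
    active = np.arange(n)
    out[:, 0] = rng.random(n) < chain.p_start_enrolled
    for _ in range(1000):
        for t in range(1, T):
            emp = employed[active, t]
            za = z_age[active]
            p_stay_e = _expit(logit_stay_e - chain.employed_exit_shift * emp
                              + chain.age_stability_shift * za)
            p_stay_u = _expit(logit_stay_u + chain.employed_entry_shift * emp
                              + chain.age_stability_shift * za)
            prev = out[active, t - 1]
            p_enrolled = np.where(prev == 1, p_stay_e, 1.0 - p_stay_u)
            out[active, t] = rng.random(len(active)) < p_enrolled
        active = np.flatnonzero(~out.any(axis=1))
        if len(active) == 0:
            return out
        out[active, 0] = rng.random(len(active)) < chain.p_start_enrolled
    raise RuntimeError("failed to draw ever-enrolled sequences; check chain probabilities")


def _draw_effects(truth: OutcomeTruth, mean_emp, mean_health, pi_e, pi_h, rng):
    loc = truth.gamma_employed * (mean_emp - pi_e) + truth.gamma_healthy * (mean_health - pi_h)
    if truth.mixing_family == "gamma":
        a = rng.gamma(truth.theta, 1.0 / truth.theta, size=len(mean_emp))
    elif truth.mixing_family == "normal":
        a = np.exp(truth.sigma * rng.standard_normal(len(mean_emp)))
    else:
        a = np.ones(len(mean_emp))
    return np.exp(loc) * a


def simulate_outcomes(config: SimulationConfig, enrollment, statics, employed, healthy, income, rng):
    """Draw the count outcomes given enrollment and covariates.

    Round-1 counts come from the model without the lag term; later rounds
    are drawn recursively with log-mean ``x'beta + log c_i + rho * h(y_prev)``.
    Returns ``(counts, effects)``: ``counts[name]`` is ``(N, T)`` and
    ``effects[name]`` the realized ``c_i``.
    """
    n, T = config.n_persons, config.n_rounds
    law = config.covariates
    n_trans = np.abs(np.diff(enrollment, axis=1)).sum(axis=1)
    one_tr = (n_trans == 1).astype(float)
    multi_tr = (n_trans > 1).astype(float)
    mean_emp = employed.mean(axis=1)
    mean_health = healthy.mean(axis=1)

    static_cols = {
        "const": np.ones(n),
        "one_transition": one_tr,
        "multi_transition": multi_tr,
        "age": statics["age"].to_numpy(dtype=float),
        "male": statics["male"].to_numpy(dtype=float),
        "married": statics["married"].to_numpy(dtype=float),
        "high_school": statics["high_school"].to_numpy(dtype=float),
        "white": statics["white"].to_numpy(dtype=float),
        "family_size": statics["family_size"].to_numpy(dtype=float),
        "chronic_count": statics["chronic_count"].to_numpy(dtype=float),
        "mean_employed": mean_emp,
        "mean_healthy": mean_health,
    }

    counts: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    # sorted order makes draws independent of outcome insertion order
    for name in sorted(config.outcomes):
        truth = config.outcomes[name]
        hfun = (lambda v: np.log1p(v)) if truth.h_form == "log1p" else (lambda v: v)
        eta = np.zeros((n, T))
        for col, b in truth.beta.items():
            if b == 0.0:
                continue
            if col in static_cols:
                eta += b * static_cols[col][:, None]
            elif col == "employed":
                eta += b * employed
            elif col == "healthy":
                eta += b * healthy
            elif col == "income_ratio":
                eta += b * income
            elif col.startswith("round_"):
                r = int(col.split("_")[1])
                eta[:, r - 1] += b
            else:
                raise KeyError(f"unknown truth coefficient {col!r} for outcome {name!r}")
        c = _draw_effects(truth, mean_emp, mean_health, law.pi_employed, law.pi_healthy, rng)
        log_c = np.log(c)
        y = np.empty((n, T), dtype=np.int64)
        log_mu = eta[:, 0] + log_c
        if np.any(log_mu > 20):
            raise ValueError("divergent mean at round 1: reduce coefficient magnitudes")
        y[:, 0] = rng.poisson(np.exp(log_mu))
        for t in range(1, T):
            log_mu = eta[:, t] + log_c + truth.rho * hfun(y[:, t - 1].astype(float))
            if np.any(log_mu > 20):
                raise ValueError(f"divergent mean at round {t + 1}: reduce coefficients or rho")
            y[:, t] = rng.poisson(np.exp(log_mu))
        counts[name] = y
        effects[name] = c
    return counts, effects


def generate_dataset(config: SimulationConfig) -> tuple[PanelDataset, TruthRecord]:
    """Generate one complete synthetic panel plus its truth record."""
    rngs = _streams(config.seed)
    statics, employed, healthy, income = simulate_covariates(
        config, rngs["statics"], rngs["time_varying"]
    )
    enrollment = simulate_enrollment(
        config, rngs["enrollment"], employed=employed, age=statics["age"].to_numpy()
    )
    counts, effects = simulate_outcomes(
        config, enrollment, statics, employed, healthy, income, rngs["outcomes"]
    )
    n, T = config.n_persons, config.n_rounds
    pid = np.repeat([f"p{i:06d}" for i in range(n)], T)
    rows = {
        "person_id": pid,
        "round": np.tile(np.arange(1, T + 1), n),
        "medicaid": enrollment.ravel(),
        "employed": employed.ravel(),
        "healthy": healthy.ravel(),
        "income": income.ravel(),
    }
    zero = np.zeros(n * T, dtype=np.int64)
    for name in ("er_visits", "outpatient_visits", "inpatient_discharges", "rx_fills"):
        rows[name] = counts[name].ravel() if name in counts else zero
    for col in ("age", "male", "married", "high_school", "white", "family_size", "chronic_count"):
        rows[col] = np.repeat(statics[col].to_numpy(), T)
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    dataset = from_dataframe(df)
    n_trans = np.abs(np.diff(enrollment, axis=1)).sum(axis=1)
    shares = {
        "none": float(np.mean(n_trans == 0)),
        "single": float(np.mean(n_trans == 1)),
        "multiple": float(np.mean(n_trans > 1)),
    }
    record = TruthRecord(config=config, individual_effects=effects, group_shares=shares)
    return dataset, record
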