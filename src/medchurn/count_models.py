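"""Random-effects Poisson panel likelihoods and maximum-likelihood fitting.

Each count outcome ``y_it`` is Poisson with conditional mean
``exp(x_it' beta) * c_i`` where ``c_i`` is an unobserved individual effect.
Two mixing laws for ``c_i`` are implemented:

* **gamma** (default): ``c_i ~ Gamma(theta, theta)`` — multiplicative with
  mean 1 and variance ``1/theta``.  The marginal likelihood of a person's
  round sequence has a closed form (negative-binomial-type), obtained by
  integrating the gamma effect analytically.
* **normal**: ``log c_i = sigma * u_i`` with ``u_i ~ N(0, 1)``; the marginal
  likelihood is evaluated by Gauss–Hermite quadrature.

Fitting maximizes the sum of per-person marginal log-likelihoods over
``(beta, log theta)`` or ``(beta, log sigma)`` by quasi-Newton (BFGS) with
analytic gradients; standard errors come from the inverse observed
information (numerical Hessian of the analytic gradient).  Incidence rate
ratios are ``exp(beta)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .cohort import ModelFrame, ModelSpec, build_model_frame

__all__ = [
    "MixingSpec",
    "FitResult",
    "poisson_logpmf",
    "pooled_poisson_loglik",
    "loglik_person_gamma",
    "loglik_person_normal",
    "fit",
    "compare_specs",
]

_ETA_CAP = 40.0  # guards exp overflow during line search; inactive at any optimum


@dataclass(frozen=True)
class MixingSpec:
    """Distributional law of the individual effect.

    Parameters
    ----------
    family:
        ``"gamma"`` or ``"normal"``.
    parameter:
        Starting value for the mixing parameter (``theta`` for gamma,
        ``sigma`` for normal); ``None`` uses a method-of-moments start.
        With ``fixed=True`` the parameter is held at this value.
    quadrature_nodes:
        Number of Gauss–Hermite nodes (normal family only).
    fixed:
        Do not estimate the mixing parameter.  ``normal`` with
        ``parameter=0.0, fixed=True`` is the pooled Poisson model.
    """

    family: str = "gamma"
    parameter: float | None = None
    quadrature_nodes: int = 32
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "normal"):
            raise ValueError("mixing family must be 'gamma' or 'normal'")
        if self.quadrature_nodes < 1:
            raise ValueError("quadrature_nodes must be >= 1")
        if self.parameter is not None:
            if self.family == "gamma" and not self.parameter > 0:
                raise ValueError("gamma dispersion theta must be > 0")
            if self.family == "normal" and self.parameter < 0:
                raise ValueError("normal sigma must be >= 0")
        if self.fixed and self.parameter is None:
            raise ValueError("fixed mixing requires an explicit parameter value")


@dataclass
class FitResult:
    """Maximum-likelihood estimates for one specification of one outcome."""

    spec: ModelSpec
    outcome: str
    params: pd.Series
    se: pd.Series
    mixing_family: str
    mixing_estimate: float | None
    mixing_se: float | None
    loglik: float
    n_iter: int
    converged: bool
    n_persons: int
    n_obs: int
    message: str = ""

    @property
    def irr(self) -> pd.Series:
        return np.exp(self.params).rename("irr")

    @property
    def zvalues(self) -> pd.Series:
        return (self.params / self.se).rename("z")

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * special.ndtr(-np.abs(z)), index=self.params.index, name="p")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "irr": self.irr,
                "irr_se": self.irr * self.se,  # delta method
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.value,
            "outcome": self.outcome,
            "coef": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "irr": {k: float(v) for k, v in self.irr.items()},
            "mixing_family": self.mixing_family,
            "mixing_estimate": self.mixing_estimate,
            "mixing_se": self.mixing_se,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_persons": self.n_persons,
            "n_obs": self.n_obs,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def poisson_logpmf(y, rate):
    """Log Poisson pmf ``y log(rate) - rate - log(y!)``, stable for large y."""
    y = np.asarray(y, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("Poisson rate must be positive")
    return special.xlogy(y, rate) - rate - special.gammaln(y + 1.0)


def pooled_poisson_loglik(y, eta) -> float:
    """Poisson log-likelihood with log-mean ``eta``, no individual effect."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    lam = np.exp(eta)
    return float(np.sum(y * eta - lam - special.gammaln(y + 1.0)))


def loglik_person_gamma(y, rates, theta: float) -> float:
    """Closed-form marginal log-likelihood of one person under gamma mixing.

    Integrates ``prod_t Poisson(y_t; a * rate_t)`` against
    ``a ~ Gamma(theta, theta)`` (mean 1, variance ``1/theta``)::

        sum_t [y_t log rate_t - log y_t!]
        + lgamma(theta + S_y) - lgamma(theta)
        + theta log theta - (theta + S_y) log(theta + S_rate)

    with ``S_y = sum y_t`` and ``S_rate = sum rate_t``.
    """
    y = np.asarray(y, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if y.shape != rates.shape:
        raise ValueError("y and rates must have equal length")
    if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
        raise ValueError("rates must be finite and positive")
    if not theta > 0:
        raise ValueError("theta must be positive")
    s_y = y.sum()
    s_r = rates.sum()
    return float(
        np.sum(special.xlogy(y, rates) - special.gammaln(y + 1.0))
        + special.gammaln(theta + s_y)
        - special.gammaln(theta)
        + theta * np.log(theta)
        - (theta + s_y) * np.log(theta + s_r)
    )


def _agh_mode_scale(s_y, s_lam0, sigma):
    """Vectorized mode and curvature scale of the per-person integrand.

    Solves ``g'(u) = sigma*S_y - sigma*e^(sigma*u)*S_lam0 - u = 0`` by
    Newton iteration (``g`` is strictly concave in ``u``).
    """
    u = np.zeros_like(np.asarray(s_y, dtype=float))
    for _ in range(50):
        e = np.exp(sigma * u) * s_lam0
        g1 = sigma * s_y - sigma * e - u
        g2 = -(sigma**2) * e - 1.0
        step = g1 / g2
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    scale = 1.0 / np.sqrt((sigma**2) * np.exp(sigma * u) * s_lam0 + 1.0)
    return u, scale


def loglik_person_normal(y, eta, sigma: float, nodes: int = 32) -> float:
    """Adaptive Gauss–Hermite marginal log-likelihood under log-normal mixing.

    Approximates ``log ∫ prod_t Poisson(y_t; exp(eta_t + sigma*u)) phi(u) du``
    with ``nodes`` Hermite points recentered and rescaled at the posterior
    mode of ``u`` (adaptive quadrature, as used for GLMM likelihoods), so
    accuracy does not degrade when large counts shift the posterior away
    from the prior mode.  ``sigma = 0`` returns the pooled Poisson
    log-likelihood exactly; ``nodes = 1`` is the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have equal length")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    if sigma == 0:
        return pooled_poisson_loglik(y, eta)
    x, w = np.polynomial.hermite.hermgauss(nodes)
    mode, scale = _agh_mode_scale(y.sum(), np.exp(eta).sum(), sigma)
    u = mode + np.sqrt(2.0) * scale * x
    a = eta[:, None] + sigma * u[None, :]
    logjoint = np.sum(y[:, None] * a - np.exp(a), axis=0) - 0.5 * u**2
    logq = np.log(w) + x**2 + 0.5 * np.log(2.0) + np.log(scale) - 0.5 * np.log(2 * np.pi)
    const = -special.gammaln(y + 1.0).sum()
    return float(special.logsumexp(logjoint + logq) + const)


# ---------------------------------------------------------------------------
# vectorized objective / gradient over a whole frame


def _person_sums(v: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(v, starts)


def _gamma_negll_grad(params, X, y, starts, log_theta_fixed):
    """Negative total log-likelihood and gradient, gamma mixing.

    ``params`` is ``[beta, log_theta]`` (or just ``beta`` when the
    dispersion is held fixed at ``log_theta_fixed``).
    """
    k = X.shape[1]
    beta = params[:k]
    log_theta = params[k] if log_theta_fixed is None else log_theta_fixed
    theta = np.exp(log_theta)
    eta = X @ beta
    lam = np.exp(np.minimum(eta, _ETA_CAP))
    s_y = _person_sums(y, starts)
    s_l = _person_sums(lam, starts)
    ll = (
        np.sum(special.xlogy(y, np.maximum(lam, 1e-300)) - special.gammaln(y + 1.0))
        + np.sum(
            special.gammaln(theta + s_y)
            - special.gammaln(theta)
            + theta * log_theta
            - (theta + s_y) * np.log(theta + s_l)
        )
    )
    ratio = (theta + s_y) / (theta + s_l)
    w_row = y - np.repeat(ratio, np.diff(np.r_[starts, len(y)])) * lam
    grad_beta = X.T @ w_row
    if log_theta_fixed is None:
        d_theta = np.sum(
            special.digamma(theta + s_y)
            - special.digamma(theta)
            + log_theta
            + 1.0
            - np.log(theta + s_l)
            - ratio
        )
        grad = np.r_[grad_beta, theta * d_theta]
    else:
        grad = grad_beta
    return -ll, -grad


def _normal_negll_grad(params, X, y, starts, log_sigma_fixed, nodes):
    """Negative total log-likelihood and gradient, normal mixing on log scale."""
    k = X.shape[1]
    beta = params[:k]
    log_sigma = params[k] if log_sigma_fixed is None else log_sigma_fixed
    sigma = np.exp(log_sigma) if np.isfinite(log_sigma) else 0.0
    eta = X @ beta
    if sigma == 0.0:
        lam = np.exp(np.minimum(eta, _ETA_CAP))
        ll = np.sum(y * eta - lam - special.gammaln(y + 1.0))
        grad_beta = X.T @ (y - lam)
        grad = grad_beta if log_sigma_fixed is not None else np.r_[grad_beta, 0.0]
        return -ll, -grad
    x, w = np.polynomial.hermite.hermgauss(nodes)
    eta_c = np.minimum(eta, _ETA_CAP)
    s_y = _person_sums(y, starts)
    s_lam0 = _person_sums(np.exp(eta_c), starts)
    mode, scale = _agh_mode_scale(s_y, s_lam0, sigma)  # per person
    u = mode[:, None] + np.sqrt(2.0) * scale[:, None] * x[None, :]  # (persons, nodes)
    sizes = np.diff(np.r_[starts, len(y)])
    u_row = np.repeat(u, sizes, axis=0)  # (rows, nodes)
    a = np.minimum(eta[:, None] + sigma * u_row, _ETA_CAP)
    lam = np.exp(a)
    contrib = y[:, None] * a - lam  # (rows, nodes)
    logq = np.log(w)[None, :] + x[None, :] ** 2 + 0.5 * np.log(2.0) \
        + np.log(scale)[:, None] - 0.5 * np.log(2 * np.pi)
    joint = np.add.reduceat(contrib, starts, axis=0) - 0.5 * u**2 + logq
    const = -_person_sums(special.gammaln(y + 1.0), starts)
    ll_i = special.logsumexp(joint, axis=1) + const
    ll = float(ll_i.sum())
    post = np.exp(joint - special.logsumexp(joint, axis=1)[:, None])  # (persons, nodes)
    post_row = np.repeat(post, sizes, axis=0)
    resid = y[:, None] - lam
    w_row = np.sum(post_row * resid, axis=1)
    grad_beta = X.T @ w_row
    if log_sigma_fixed is None:
        d_sigma = float(np.sum(post_row * resid * u_row))
        grad = np.r_[grad_beta, sigma * d_sigma]
    else:
        grad = grad_beta
    return -ll, -grad


# ---------------------------------------------------------------------------
# starting values and fitting


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    _, r, piv = linalg.qr(arr / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps * 100
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def _pooled_poisson_start(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Newton (IRLS) fit of the pooled Poisson model for starting values."""
    k = X.shape[1]
    beta = np.zeros(k)
    const = np.where(np.all(X == 1.0, axis=0))[0]
    if len(const):
        beta[const[0]] = np.log(max(y.mean(), 1e-8))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.minimum(X @ beta, _ETA_CAP)
        lam = np.exp(eta)
        ll = np.sum(y * eta - lam)
        grad = X.T @ (y - lam)
        h = (X * lam[:, None]).T @ X
        try:
            step = np.linalg.solve(h + 1e-10 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        # step halving
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = np.minimum(X @ cand, _ETA_CAP)
            if np.sum(y * eta_c - np.exp(eta_c)) >= ll:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll - ll_old) < 1e-10 * (1 + abs(ll)):
            break
        ll_old = ll
    return beta


def _mom_dispersion(X, y, starts, beta) -> float:
    """Method-of-moments start for 1/theta from person-total overdispersion."""
    lam = np.exp(np.minimum(X @ beta, _ETA_CAP))
    s_y = _person_sums(y.astype(float), starts)
    s_l = _person_sums(lam, starts)
    num = np.sum((s_y - s_l) ** 2 - s_y)
    den = np.sum(s_l**2)
    v = num / den if den > 0 else 0.0
    v = float(np.clip(v, 1e-3, 50.0))
    return 1.0 / v  # theta


def _newton_polish(objective, x0: np.ndarray, gtol: float, max_steps: int = 15):
    """Newton refinement from the quasi-Newton solution.

    Uses the finite-difference Hessian of the analytic gradient; stops when
    the Newton decrement (the expected log-likelihood gain of one full
    step) falls below ``1e-8 * (1 + |f|)``.  Returns the refined point, its
    objective value, the Hessian there, and whether the decrement test was
    met.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = objective(x)
    hess = None
    converged = False
    for _ in range(max_steps):
        hess = _numerical_hessian(lambda p: objective(p)[1], x)
        try:
            step = np.linalg.solve(hess, -g)
        except np.linalg.LinAlgError:
            break
        decrement = float(-g @ step)
        if not np.isfinite(decrement) or decrement < 0:
            break
        if decrement < 1e-8 * (1.0 + abs(f)):
            converged = True
            break
        t = 1.0
        for _ in range(30):
            fc, gc = objective(x + t * step)
            if np.isfinite(fc) and fc <= f - 0.25 * t * decrement:
                x = x + t * step
                f, g = fc, gc
                break
            t *= 0.5
        else:
            break
    if hess is None:
        hess = _numerical_hessian(lambda p: objective(p)[1], x)
    if not converged:
        converged = bool(np.max(np.abs(g)) < gtol)
    return x, f, hess, converged


def _numerical_hessian(grad_fn, x0: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    n = len(x0)
    h = np.empty((n, n))
    for j in range(n):
        step = 1e-5 * max(1.0, abs(x0[j]))
        xp = x0.copy()
        xm = x0.copy()
        xp[j] += step
        xm[j] -= step
        gp = grad_fn(xp)
        gm = grad_fn(xm)
        h[:, j] = (gp - gm) / (2 * step)
    return 0.5 * (h + h.T)


def fit(
    frame: ModelFrame,
    mixing: MixingSpec = MixingSpec(),
    max_iter: int = 500,
    gtol: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood fit of one model frame.

    Deterministic given the frame and options: starting values come from a
    pooled Poisson Newton fit plus a method-of-moments dispersion estimate,
    and the optimizer (BFGS on the unconstrained ``(beta, log mixing)``
    parameterization) uses no randomness.  Non-convergence is reported via
    ``converged=False``, never silently.
    """
    X_df = frame.X
    _check_rank(X_df)
    X = np.ascontiguousarray(X_df.to_numpy(dtype=float))
    y = frame.y.astype(float)
    starts = frame.person_starts
    k = X.shape[1]

    beta0 = _pooled_poisson_start(X, y)
    if mixing.family == "gamma":
        theta0 = mixing.parameter if mixing.parameter is not None else _mom_dispersion(X, y, starts, beta0)
        log_m0 = np.log(theta0)
        if mixing.fixed:
            objective = lambda p: _gamma_negll_grad(p, X, y, starts, log_m0)
            x0 = beta0
        else:
            objective = lambda p: _gamma_negll_grad(p, X, y, starts, None)
            x0 = np.r_[beta0, log_m0]
    else:
        nodes = mixing.quadrature_nodes
        sigma0 = mixing.parameter if mixing.parameter is not None else None
        if sigma0 is None:
            theta0 = _mom_dispersion(X, y, starts, beta0)
            sigma0 = float(np.sqrt(np.log1p(1.0 / theta0)))  # variance match on log scale
        log_m0 = np.log(sigma0) if sigma0 > 0 else -np.inf
        if mixing.fixed:
            objective = lambda p: _normal_negll_grad(p, X, y, starts, log_m0, nodes)
            x0 = beta0
        else:
            if not np.isfinite(log_m0):
                log_m0 = np.log(0.1)
            objective = lambda p: _normal_negll_grad(p, X, y, starts, None, nodes)
            x0 = np.r_[beta0, log_m0]

    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    xhat, f_at, hess, converged = _newton_polish(objective, res.x, gtol)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(len(xhat), np.nan)
        converged = False

    params = pd.Series(xhat[:k], index=X_df.columns, name="coef")
    se = pd.Series(se_all[:k], index=X_df.columns, name="se")
    if mixing.fixed:
        mix_est = float(mixing.parameter)
        mix_se = None
    else:
        mix_est = float(np.exp(xhat[k]))
        mix_se = float(se_all[k] * mix_est)  # delta method from log scale
    return FitResult(
        spec=frame.spec,
        outcome=frame.outcome,
        params=params,
        se=se,
        mixing_family=mixing.family,
        mixing_estimate=mix_est,
        mixing_se=mix_se,
        loglik=float(-f_at),
        n_iter=int(res.nit),
        converged=converged,
        n_persons=frame.n_persons,
        n_obs=frame.n_obs,
        message=str(res.message),
    )


def compare_specs(
    dataset,
    outcome: str,
    mixing: MixingSpec = MixingSpec(),
    h_form: str = "identity",
    specs=(ModelSpec.STATIC_BASE, ModelSpec.STATIC_CRE, ModelSpec.DYNAMIC),
) -> dict[ModelSpec, FitResult]:
    """Fit the requested specifications of one outcome on one dataset.

    Returns an ordered mapping so a three-column regression table (static
    base, static CRE, dynamic) can be assembled directly.
    """
    results: dict[ModelSpec, FitResult] = {}
    for spec in specs:
        spec = ModelSpec(spec)
        frame = build_model_frame(dataset, outcome, spec, h_form=h_form)
        results[spec] = fit(frame, mixing=mixing)
    return results
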