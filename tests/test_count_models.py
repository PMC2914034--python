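"""Marginal likelihoods against independent oracles, and fitting behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from medchurn.cohort import ModelSpec, build_model_frame
from medchurn.count_models import (
    MixingSpec,
    fit,
    loglik_person_gamma,
    loglik_person_normal,
    poisson_logpmf,
    pooled_poisson_loglik,
)
from medchurn.synthetic_data import default_config, generate_dataset


def oracle_gamma(y, rates, theta):
    """Max-shifted adaptive quadrature of the gamma-mixed Poisson integrand."""
    y, rates = np.asarray(y, float), np.asarray(rates, float)

    def logjoint(a):
        return float(np.sum(stats.poisson.logpmf(y, a * rates))
                     + stats.gamma.logpdf(a, theta, scale=1.0 / theta))

    grid = np.geomspace(1e-8, 100, 2001)
    shift = max(logjoint(a) for a in grid)
    val, _ = integrate.quad(lambda a: np.exp(logjoint(a) - shift), 0, np.inf, limit=500)
    return shift + np.log(val)


def oracle_normal(y, eta, sigma):
    y, eta = np.asarray(y, float), np.asarray(eta, float)

    def logjoint(u):
        return float(np.sum(stats.poisson.logpmf(y, np.exp(eta + sigma * u)))
                     + stats.norm.logpdf(u))

    grid = np.linspace(-12, 12, 2001)
    shift = max(logjoint(u) for u in grid)
    val, _ = integrate.quad(lambda u: np.exp(logjoint(u) - shift), -13, 13, limit=500)
    return shift + np.log(val)


class TestPoissonLogpmf:
    def test_point_values(self):
        assert poisson_logpmf(0, 1.0) == pytest.approx(-1.0)
        assert poisson_logpmf(2, 3.0) == pytest.approx(2 * np.log(3) - 3 - np.log(2))

    def test_normalization(self):
        total = np.exp(poisson_logpmf(np.arange(201), 5.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_count_stability(self):
        val = poisson_logpmf(10_000, 10_000.0)
        # Stirling-regime mass ~ 1/sqrt(2*pi*lambda)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * 10_000), abs=1e-3)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_logpmf(1, 0.0)


class TestGammaMarginal:
    def test_single_zero_count_closed_form(self):
        # P(y=0) = (1 + lambda/theta)^(-theta)
        assert loglik_person_gamma([0], [2.0], 4.0) == pytest.approx(-4 * np.log(1.5))

    def test_large_theta_reduces_to_pooled(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 10, 5)
        eta = rng.uniform(-1, 1, 5)
        assert loglik_person_gamma(y, np.exp(eta), 1e8) == pytest.approx(
            pooled_poisson_loglik(y, eta), abs=1e-5
        )

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            T = rng.integers(1, 6)
            y = rng.integers(0, 15, T)
            rates = rng.uniform(0.2, 4.0, T)
            theta = rng.uniform(0.3, 6.0)
            assert loglik_person_gamma(y, rates, theta) == pytest.approx(
                oracle_gamma(y, rates, theta), abs=1e-8
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            loglik_person_gamma([1, 2], [1.0], 1.0)
        with pytest.raises(ValueError):
            loglik_person_gamma([1], [1.0], 0.0)
        with pytest.raises(ValueError):
            loglik_person_gamma([1], [np.inf], 1.0)


class TestNormalMarginal:
    def test_sigma_zero_is_pooled(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 8, 4)
        eta = rng.uniform(-1, 1, 4)
        assert loglik_person_normal(y, eta, 0.0) == pytest.approx(pooled_poisson_loglik(y, eta))

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 12, 5)
        eta = rng.uniform(-1, 1.5, 5)
        a = loglik_person_normal(y, eta, 0.8, nodes=64)
        b = loglik_person_normal(y, eta, 0.8, nodes=128)
        assert abs(a - b) < 1e-9

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            T = rng.integers(1, 6)
            y = rng.integers(0, 15, T)
            eta = rng.uniform(-1.5, 1.5, T)
            sigma = rng.uniform(0.05, 1.5)
            assert loglik_person_normal(y, eta, sigma, nodes=64) == pytest.approx(
                oracle_normal(y, eta, sigma), abs=1e-7
            )


@pytest.fixture(scope="module")
def dataset():
    ds, _ = generate_dataset(default_config(n_persons=400, seed=5))
    return ds


class TestFitting:

    def test_intercept_only_pooled_mle(self, dataset):
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        frame.X = frame.X[["const"]]
        res = fit(frame, MixingSpec(family="normal", parameter=0.0, fixed=True))
        assert res.params["const"] == pytest.approx(np.log(frame.y.mean()), abs=1e-6)
        assert res.mixing_estimate == 0.0

    def test_pooled_matches_statsmodels_glm(self, dataset):
        sm = pytest.importorskip("statsmodels.api")
        frame = build_model_frame(dataset, "outpatient_visits", ModelSpec.STATIC_BASE)
        res = fit(frame, MixingSpec(family="normal", parameter=0.0, fixed=True))
        glm = sm.GLM(frame.y, frame.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params.values, glm.params.values, atol=1e-5)
        np.testing.assert_allclose(res.se.values, glm.bse.values, rtol=1e-3)

    def test_determinism(self, dataset):
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        r1 = fit(frame)
        r2 = fit(frame)
        assert (r1.params.values == r2.params.values).all()
        assert r1.loglik == r2.loglik
        assert r1.mixing_estimate == r2.mixing_estimate

    def test_irr_is_exp_of_coef(self, dataset):
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        res = fit(frame)
        np.testing.assert_array_equal(res.irr.values, np.exp(res.params.values))

    def test_scaling_invariance(self, dataset):
        frame = build_model_frame(dataset, "rx_fills", ModelSpec.STATIC_BASE)
        res1 = fit(frame)
        frame2 = build_model_frame(dataset, "rx_fills", ModelSpec.STATIC_BASE)
        frame2.X = frame2.X.assign(age=frame2.X["age"] * 10.0)
        res2 = fit(frame2)
        assert res2.params["age"] == pytest.approx(res1.params["age"] / 10.0, rel=1e-4)
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-4)

    def test_rank_deficiency_names_columns(self, dataset):
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        frame.X = frame.X.assign(age_copy=frame.X["age"])
        with pytest.raises(ValueError, match="age"):
            fit(frame)

    def test_nested_loglik_ordering(self, dataset):
        base = fit(build_model_frame(dataset, "outpatient_visits", ModelSpec.STATIC_BASE))
        cre = fit(build_model_frame(dataset, "outpatient_visits", ModelSpec.STATIC_CRE))
        assert cre.loglik >= base.loglik - 1e-6

    def test_gamma_and_normal_agree_roughly(self, dataset):
        """Both mixing families should find similar covariate effects."""
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        g = fit(frame, MixingSpec(family="gamma"))
        n = fit(frame, MixingSpec(family="normal", quadrature_nodes=24))
        assert g.converged and n.converged
        assert n.params["healthy"] == pytest.approx(g.params["healthy"], abs=0.05)
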