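"""NB GLM core: closed forms, the Poisson limit against an independent
implementation, dispersion estimation and squeezing, AIC behaviour."""

import numpy as np
import pytest
import statsmodels.api as sm

from nbdex.glm import (
    adjusted_profile_loglik,
    drop_aliased,
    estimate_dispersions,
    estimate_genewise_dispersion,
    fit_nb_glm,
    nb_loglik,
    squeeze_dispersions,
)


def test_intercept_only_closed_form():
    L = 250.0
    y = np.array([10.0, 10.0, 10.0, 10.0])
    off = np.full(4, np.log(L))
    fit = fit_nb_glm(y, np.ones((4, 1)), off, a=0.1)
    assert fit.beta[0] == pytest.approx(np.log(10.0 / L), abs=1e-8)


def test_poisson_limit_matches_independent_poisson_irls():
    rng = np.random.default_rng(1)
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    off = np.log(rng.uniform(1e4, 2e4, n))
    mu = np.exp(-8.0 + 0.4 * X[:, 1] - 0.3 * X[:, 2] + off)
    y = rng.poisson(mu).astype(float)
    fit = fit_nb_glm(y, X, off, a=1e-10)
    ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
    assert np.allclose(fit.beta, ref.params, atol=1e-6)


def test_nb_fit_matches_statsmodels_at_fixed_dispersion():
    rng = np.random.default_rng(2)
    n, a = 60, 0.15
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    off = np.full(n, np.log(5e4))
    mu = np.exp(-6.0 + 0.5 * X[:, 1] + off)
    y = rng.poisson(rng.gamma(1.0 / a, a * mu)).astype(float)
    fit = fit_nb_glm(y, X, off, a=a)
    ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=a), offset=off).fit()
    assert np.allclose(fit.beta, ref.params, atol=1e-6)
    assert np.allclose(fit.cov, ref.cov_params(), rtol=1e-4, atol=1e-8)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
    assert fit.aic == pytest.approx(-2 * ref.llf + 2 * X.shape[1], abs=1e-5)


def test_diet_effect_recovery_simulation():
    """Mean estimated coefficient close to the generating log-FC of 0.5."""
    rng = np.random.default_rng(3)
    n, a = 400, 0.1
    grp = np.repeat([0.0, 1.0], n // 2)
    X = np.column_stack([np.ones(n), grp])
    off = np.full(n, np.log(1e4))
    est = []
    for _ in range(200):
        mu = np.exp(np.log(50.0) + 0.5 * grp)
        y = rng.poisson(rng.gamma(1.0 / a, a * mu)).astype(float)
        est.append(fit_nb_glm(y, X, off, a).beta[1])
    assert abs(np.mean(est) - 0.5) < 0.02


def test_aliased_columns_dropped_in_order():
    """Pens nest in diet: the later redundant pen dummy goes, diet stays."""
    n = 12
    diet = np.repeat([0.0, 1.0], 6)
    pen = np.repeat(np.arange(4), 3)  # pens 0,1 in CTRL; 2,3 in REST
    pen_d = np.column_stack([(pen == k).astype(float) for k in range(1, 4)])
    X = np.column_stack([np.ones(n), diet, pen_d])
    names = ["Intercept", "diet", "pen1", "pen2", "pen3"]
    Xr, keep, dropped = drop_aliased(X, names)
    assert "diet" not in dropped
    assert len(dropped) == 1 and dropped[0].startswith("pen")
    assert np.linalg.matrix_rank(Xr) == Xr.shape[1]


def test_covariance_is_positive_semidefinite(small_muscle):
    cm, design, _ = small_muscle
    rng = np.random.default_rng(0)
    n = cm.shape[1]
    X = np.column_stack([np.ones(n), (design["diet"] == "REST").to_numpy(float)])
    off = np.log(cm.sum(axis=0).to_numpy(float))
    for g in rng.choice(cm.shape[0], 10, replace=False):
        fit = fit_nb_glm(cm.iloc[g].to_numpy(float), X, off, 0.1)
        ev = np.linalg.eigvalsh(fit.cov)
        assert ev.min() > -1e-10


class TestDispersion:
    def test_squeeze_limits(self):
        genewise = np.array([0.05, 0.1, 0.4])
        assert np.allclose(
            squeeze_dispersions(genewise, 0.2, residual_df=8, prior_df=np.inf), 0.2
        )
        assert np.allclose(
            squeeze_dispersions(genewise, 0.2, residual_df=8, prior_df=0.0), genewise
        )

    def test_genewise_recovery_median(self):
        """True a = 0.1 at n = 200: median genewise estimate in [0.08, 0.12]."""
        rng = np.random.default_rng(4)
        n = 200
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        off = np.zeros(n)
        Y = np.stack(
            [rng.poisson(rng.gamma(10.0, 0.1 * np.full(n, 200.0))) for _ in range(120)]
        ).astype(float)
        _, _, genewise, _ = estimate_dispersions(Y, X, off, prior_df=0.0)
        assert 0.08 <= np.median(genewise) <= 0.12

    def test_grid_estimate_agrees_with_scalar_optimizer(self):
        rng = np.random.default_rng(5)
        n = 80
        X = np.ones((n, 1))
        off = np.zeros(n)
        Y = np.stack(
            [rng.poisson(rng.gamma(5.0, 0.2 * np.full(n, 100.0))) for _ in range(5)]
        ).astype(float)
        _, _, genewise, _ = estimate_dispersions(Y, X, off, prior_df=0.0)
        for g in range(5):
            precise = estimate_genewise_dispersion(Y[g], X, off)
            assert genewise[g] == pytest.approx(precise, rel=0.1)

    def test_apl_penalizes_loglik(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(rng.gamma(10.0, 0.1 * np.full(30, 50.0))).astype(float)
        X = np.ones((30, 1))
        off = np.zeros(30)
        fit = fit_nb_glm(y, X, off, 0.1)
        assert adjusted_profile_loglik(0.1, y, X, off) < fit.loglik


def test_nested_model_aic_bound():
    """When extra coefficients are 0 at the ML solution, the larger model's
    AIC cannot beat the smaller's, and can lose by at most 2*extra params."""
    rng = np.random.default_rng(7)
    n = 50
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    off = np.zeros(n)
    mu = np.exp(3.0 + 0.4 * x1)
    y = rng.poisson(rng.gamma(10.0, 0.1 * mu)).astype(float)
    small = fit_nb_glm(y, np.column_stack([np.ones(n), x1]), off, 0.1)
    large = fit_nb_glm(y, np.column_stack([np.ones(n), x1, x2]), off, 0.1)
    assert large.loglik >= small.loglik - 1e-8
    assert large.aic >= small.aic - 1e-6  # can only lose via the penalty
    assert large.aic - small.aic <= 2.0 + 1e-6


def test_gaussian_limit_matches_least_squares():
    """Large counts, tiny dispersion: NB fit ~ log-scale least squares."""
    rng = np.random.default_rng(8)
    n = 200
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    off = np.zeros(n)
    mu = np.exp(9.0 + 0.3 * x)
    y = rng.poisson(mu).astype(float)
    fit = fit_nb_glm(y, X, off, a=1e-10)
    ols = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    assert np.allclose(fit.beta, ols, atol=5e-3)
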