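import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from famews.polygenic import (
    EigenRelationship,
    decompose_relationship,
    fit_polygenic,
    fixed_effect_test,
    heritability_test,
)
from famews.simulate import (
    SimConfig,
    simulate_binary_trait,
    simulate_pedigrees,
    simulate_polygenic_trait,
)


def _design(n, seed=0):
    rng = np.random.default_rng(seed)
    return np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])


def test_identity_A_matches_ols_likelihood():
    """With unrelated individuals the polygenic model collapses to OLS."""
    rng = np.random.default_rng(1)
    n = 300
    X = _design(n)
    y = X @ [1.0, 0.5, -0.3] + rng.standard_normal(n)
    fit = fit_polygenic(y, X, np.eye(n))
    ols = sm.OLS(y, X).fit()
    assert fit.h2 == pytest.approx(0.0, abs=0.05)
    assert fit.logL == pytest.approx(ols.llf, abs=1e-6)
    np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, atol=1e-4)


def test_eigen_path_equals_dense_gaussian_loglik(small_study):
    """The rotated likelihood equals the dense MVN density on n <= 200."""
    ped, A, eig = small_study
    n = min(len(ped), 200)
    idx = np.arange(n)
    Av = A.to_numpy()[np.ix_(idx, idx)]
    rng = np.random.default_rng(3)
    y = simulate_polygenic_trait(None, decompose_relationship(Av), 0.5, seed=9)
    X = np.ones((n, 1))
    fit = fit_polygenic(y, X, Av)
    V = fit.sigma2_g * Av + fit.sigma2_e * np.eye(n)
    dense = stats.multivariate_normal.logpdf(y, mean=X @ [fit.beta.iloc[0]], cov=V)
    assert fit.logL == pytest.approx(dense, abs=1e-8)


def test_h2_recovery_on_study_design(study):
    ped, _, eig = study
    X = np.ones((len(ped), 1))
    ests = [
        fit_polygenic(simulate_polygenic_trait(ped, eig, 0.52, seed=s), X, eig).h2
        for s in range(15)
    ]
    assert np.mean(ests) == pytest.approx(0.52, abs=0.07)


def test_heritability_lrt_mixture_reference():
    """The boundary LRT refers to the half-half chi-square mixture."""
    n = 60
    rng = np.random.default_rng(4)
    y = rng.standard_normal(n)
    X = np.ones((n, 1))
    fit = fit_polygenic(y, X, np.eye(n))
    p = heritability_test(fit, y, X, np.eye(n))
    lam = 2.0 * 0.0  # identity A: statistic should be ~0
    assert 0.25 <= p <= 0.5
    # mixture arithmetic: P = 0.5 * chi2_1 tail
    assert 0.5 * stats.chi2.sf(2.706, 1) == pytest.approx(0.05, abs=2e-4)


def test_fixed_effect_matches_ols_lrt():
    rng = np.random.default_rng(5)
    n = 250
    X = pd.DataFrame(_design(n, 5), columns=["intercept", "x1", "x2"])
    y = X.to_numpy() @ [0.3, 0.25, 0.0] + rng.standard_normal(n)
    b, se, p = fixed_effect_test(y, X, np.eye(n), "x1")
    full = sm.OLS(y, X).fit()
    red = sm.OLS(y, X.drop(columns="x1")).fit()
    p_ols = stats.chi2.sf(2.0 * (full.llf - red.llf), 1)
    assert p == pytest.approx(p_ols, abs=1e-4)
    assert b == pytest.approx(full.params["x1"], abs=1e-3)


def test_fixed_effect_zero_column():
    n = 50
    X = np.column_stack([np.ones(n), np.zeros(n)])
    y = np.random.default_rng(0).standard_normal(n)
    b, se, p = fixed_effect_test(y, X, np.eye(n), 1)
    assert b == 0.0 and p == 1.0


def test_rank_deficient_design_names_columns():
    n = 40
    x = np.random.default_rng(1).standard_normal(n)
    X = pd.DataFrame({"intercept": np.ones(n), "a": x, "b": 2 * x})
    with pytest.raises(np.linalg.LinAlgError, match="a|b"):
        fit_polygenic(x + 1.0, X, np.eye(n))


def test_degenerate_two_founders_flagged():
    y = np.array([0.3, -1.2])
    X = np.ones((2, 1))
    fit = fit_polygenic(y, X, np.eye(2))
    assert not fit.converged
    assert fit.message


def test_affine_invariance_of_h2(small_study):
    ped, _, eig = small_study
    y = simulate_polygenic_trait(ped, eig, 0.4, seed=11)
    X = np.ones((len(ped), 1))
    f1 = fit_polygenic(y, X, eig)
    f2 = fit_polygenic(5.0 * y + 3.0, X, eig)
    assert f2.h2 == pytest.approx(f1.h2, abs=1e-5)
    assert f2.beta.iloc[0] == pytest.approx(5.0 * f1.beta.iloc[0] + 3.0, rel=1e-5)


def test_unconstrained_dominates_constrained(small_study):
    ped, _, eig = small_study
    X = np.ones((len(ped), 1))
    for s in range(5):
        y = simulate_polygenic_trait(ped, eig, 0.3, seed=100 + s)
        fit = fit_polygenic(y, X, eig)
        p = heritability_test(fit, y, X, eig)  # raises if logL ordering violated
        assert 0.0 <= p <= 0.5 + 1e-12


def test_liability_fit_recovers_h2_and_prevalence(study):
    ped, _, eig = study
    X = np.ones((len(ped), 1))
    ests, prevs = [], []
    for s in range(20):
        liab = simulate_polygenic_trait(ped, eig, 0.52, seed=500 + s)
        y = simulate_binary_trait(liab, 0.26)
        fit = fit_polygenic(y, X, eig, kind="liability")
        ests.append(fit.h2)
        prevs.append(fit.prevalence)
    assert np.mean(ests) == pytest.approx(0.52, abs=0.08)
    assert np.mean(prevs) == pytest.approx(0.26, abs=0.02)


def test_liability_requires_both_classes():
    n = 30
    with pytest.raises(ValueError, match="both classes"):
        fit_polygenic(np.zeros(n), np.ones((n, 1)), np.eye(n), kind="liability")


def test_planted_fixed_effect_power(study):
    ped, _, eig = study
    n = len(ped)
    rng = np.random.default_rng(12)
    hits = 0
    for s in range(10):
        x = rng.standard_normal(n)
        y = simulate_polygenic_trait(ped, eig, 0.4, seed=900 + s) + 0.5 * x
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        _, _, p = fixed_effect_test(y, X, eig, "x")
        hits += p < 0.001
    assert hits >= 9
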