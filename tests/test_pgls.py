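import numpy as np
import pytest
import statsmodels.api as sm

from phyloallom import (
    VCVMatrix,
    fit_pgls,
    gls_estimate,
    lambda_transform,
    profile_loglik,
    significant_positive,
    vcv,
    yule_tree,
)
from phyloallom.simulate import _LambdaSampler


def brute_force_gls(x, y, V):
    """Dense-inverse textbook GLS, independent of the package's solver path."""
    X = np.column_stack([np.ones_like(x), x])
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.inv(A) @ X.T @ Vi @ y
    r = y - X @ beta
    sigma2 = (r @ Vi @ r) / (len(y) - 2)
    return beta, sigma2 * np.linalg.inv(A), sigma2


class TestGLSEstimate:
    def test_identity_v_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        y = 0.3 + 0.8 * x + rng.standard_normal(12) * 0.2
        beta, cov, _, _ = gls_estimate(x, y, np.eye(12))
        res = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(beta, res.params, atol=1e-10)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), res.bse, atol=1e-10)

    def test_matches_statsmodels_gls_on_tree(self):
        tree = yule_tree(10, 1.0, seed=11)
        V = vcv(tree)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        y = 1.0 + 0.5 * x + rng.standard_normal(10) * 0.3
        beta, cov, _, _ = gls_estimate(x, y, V)
        res = sm.GLS(y, sm.add_constant(x), sigma=V.values).fit()
        np.testing.assert_allclose(beta, res.params, atol=1e-10)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), res.bse, atol=1e-10)

    def test_matches_dense_inverse_oracle(self):
        tree = yule_tree(6, 1.0, seed=3)
        V = vcv(tree).values
        rng = np.random.default_rng(2)
        x = rng.standard_normal(6)
        y = 1.2 + 0.45 * x + rng.standard_normal(6) * 0.3
        beta, cov, sigma2, _ = gls_estimate(x, y, V)
        b0, c0, s0 = brute_force_gls(x, y, V)
        np.testing.assert_allclose(beta, b0, atol=1e-8)
        np.testing.assert_allclose(cov, c0, atol=1e-8)
        assert sigma2 == pytest.approx(s0, abs=1e-8)

    def test_singular_v_raises(self):
        V = np.ones((5, 5))
        with pytest.raises(np.linalg.LinAlgError):
            gls_estimate(np.arange(5.0), np.arange(5.0), V)

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError):
            gls_estimate(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.eye(2))


class TestProfileLoglik:
    def test_star_tree_profile_is_flat(self, star20):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        vals = [profile_loglik(lam, x, y, star20) for lam in (-0.5, 0.0, 0.7, 1.0)]
        assert np.ptp(vals) < 1e-8

    def test_nonpd_lambda_hits_sentinel(self):
        tree = yule_tree(12, 1.0, seed=6)
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        assert profile_loglik(-50.0, x, y, tree) < -1e200

    def test_true_lambda_beats_zero_on_simulated_data(self):
        # strong-signal data should prefer lambda = 1 over 0 nearly always
        hits = 0
        for r in range(25):
            tree = yule_tree(100, 1.0, seed=300 + r)
            samp = _LambdaSampler(tree)
            rng = np.random.default_rng(r)
            y = samp.draw(1.0, rng)
            x = samp.draw(1.0, rng)
            if profile_loglik(1.0, x, y, tree) > profile_loglik(0.0, x, y, tree):
                hits += 1
        assert hits >= 22


class TestFitPGLS:
    def test_star_tree_equals_ols(self, star20):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20)
        y = 0.5 + 0.3 * x + rng.standard_normal(20) * 0.4
        fit = fit_pgls(x, y, star20)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.lambda_flag == "unidentifiable"
        assert fit.slope == pytest.approx(res.params[1], abs=1e-8)
        assert fit.intercept == pytest.approx(res.params[0], abs=1e-8)
        assert fit.se_slope == pytest.approx(res.bse[1], abs=1e-8)
        assert fit.p_slope == pytest.approx(res.pvalues[1], abs=1e-8)

    def test_optimum_dominates_canonical_lambdas(self):
        tree = yule_tree(60, 1.0, seed=21)
        samp = _LambdaSampler(tree)
        rng = np.random.default_rng(8)
        x = samp.draw(1.0, rng)
        y = 1.0 + 0.4 * x + 0.4 * samp.draw(0.7, rng)
        fit = fit_pgls(x, y, tree)
        ll_hat = profile_loglik(fit.lam, x, y, tree)
        for lam in (0.0, 0.5, 1.0):
            assert ll_hat >= profile_loglik(lam, x, y, tree) - 1e-7

    def test_branch_length_scaling_invariance(self):
        tree = yule_tree(40, 1.0, seed=22)
        samp = _LambdaSampler(tree)
        rng = np.random.default_rng(9)
        x = samp.draw(1.0, rng)
        y = 0.8 + 0.5 * x + 0.3 * samp.draw(0.8, rng)
        fit1 = fit_pgls(x, y, tree)
        scaled = type(tree)(tree.tip_labels, tree.parent.copy(), tree.branch_length * 7.3)
        fit2 = fit_pgls(x, y, scaled)
        assert fit2.slope == pytest.approx(fit1.slope, abs=1e-8)
        assert fit2.lam == pytest.approx(fit1.lam, abs=1e-6)
        assert fit2.p_slope == pytest.approx(fit1.p_slope, abs=1e-8)
        assert fit2.sigma2 == pytest.approx(fit1.sigma2 / 7.3, rel=1e-6)

    def test_reml_vs_ml_switch(self):
        tree = yule_tree(30, 1.0, seed=23)
        rng = np.random.default_rng(10)
        samp = _LambdaSampler(tree)
        x = samp.draw(1.0, rng)
        y = 0.2 + 0.3 * x + 0.3 * samp.draw(0.9, rng)
        f_reml = fit_pgls(x, y, tree, criterion="REML")
        f_ml = fit_pgls(x, y, tree, criterion="ML")
        assert f_reml.criterion == "REML" and f_ml.criterion == "ML"
        # the two criteria agree approximately but not exactly
        assert f_ml.slope == pytest.approx(f_reml.slope, abs=0.05)
        assert f_ml.loglik != pytest.approx(f_reml.loglik, abs=1e-6)

    def test_ci_lambda_brackets_estimate(self):
        tree = yule_tree(120, 1.0, seed=24)
        samp = _LambdaSampler(tree)
        rng = np.random.default_rng(11)
        x = samp.draw(1.0, rng)
        y = 0.1 + 0.45 * x + 0.3 * samp.draw(0.9, rng)
        fit = fit_pgls(x, y, tree)
        lo, hi = fit.ci_lambda
        assert lo < fit.lam < hi


class TestSignificantPositive:
    @pytest.mark.parametrize(
        "slope,p,expected",
        [(0.45, 0.005, True), (0.01, 0.86, False), (-0.2, 0.001, False)],
    )
    def test_rule(self, slope, p, expected):
        from phyloallom import PGLSFit

        fit = PGLSFit(
            n=10, slope=slope, intercept=0.0, se_slope=0.1, se_intercept=0.1,
            ci_slope=(slope - 0.1, slope + 0.1), ci_intercept=(-1, 1),
            p_slope=p, p_intercept=0.5, lam=0.9, ci_lambda=(0.5, 1.1),
            sigma2=1.0, loglik=0.0,
        )
        assert significant_positive(fit) is expected
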