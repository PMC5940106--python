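import math

import numpy as np
import pytest

from cpglife.pgls import (
    PhyloCov, SkippedLocus, UnfitLocusError, gls_fit, lambda_transform,
    pgls, phylo_cov, profile_lambda_ml,
)
from cpglife.simulate import gen_tree, sim_bm


def gls_explicit_inverse(y, x, V):
    """Independent oracle: closed-form GLS via an explicit matrix inverse."""
    n = len(y)
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    cov_unscaled = np.linalg.inv(X.T @ Vi @ X)
    beta = cov_unscaled @ X.T @ Vi @ y
    e = y - X @ beta
    rss = float(e @ Vi @ e)
    sigma2_ml = rss / n
    loglik = -0.5 * (
        n * math.log(2 * math.pi * sigma2_ml) + np.linalg.slogdet(V)[1] + n
    )
    se = math.sqrt(rss / (n - 2) * cov_unscaled[1, 1])
    return beta[1], beta[0], se, loglik


class TestPhyloCov:
    def test_three_tip_example(self, three_tip_tree):
        cov = phylo_cov(three_tip_tree, ["A", "B", "C"])
        np.testing.assert_allclose(cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_identity(self, star_tree):
        cov = phylo_cov(star_tree, ["A", "B", "C"])
        np.testing.assert_allclose(cov.C, np.eye(3))

    def test_subset_restriction(self, three_tip_tree):
        cov = phylo_cov(three_tip_tree, ["A", "B"])
        np.testing.assert_allclose(cov.C, [[2, 1], [1, 2]])

    def test_respects_species_order(self, three_tip_tree):
        cov = phylo_cov(three_tip_tree, ["C", "A", "B"])
        np.testing.assert_allclose(cov.C, [[2, 0, 0], [0, 2, 1], [0, 1, 2]])

    def test_missing_species_listed(self, three_tip_tree):
        with pytest.raises(ValueError, match="Zebra"):
            phylo_cov(three_tip_tree, ["A", "Zebra"])

    def test_too_few_species(self, three_tip_tree):
        with pytest.raises(ValueError):
            phylo_cov(three_tip_tree, ["A"])

    def test_diagonal_dominates_rows(self, rng):
        phylo = gen_tree(20, rng)
        cov = phylo_cov(phylo, sorted(phylo.tip_labels))
        assert np.all(np.diag(cov.C)[:, None] >= cov.C - 1e-12)
        np.testing.assert_allclose(cov.C, cov.C.T)


class TestLambdaTransform:
    def test_limits(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(lambda_transform(C, 0.0), np.diag([2.0, 2.0]))
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        np.testing.assert_allclose(
            lambda_transform(C, 0.5), [[2.0, 0.5], [0.5, 2.0]]
        )

    def test_out_of_range(self):
        C = np.eye(2)
        for lam in (-0.1, 1.1):
            with pytest.raises(ValueError):
                lambda_transform(C, lam)


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        fit = gls_fit(y, x, np.eye(12))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.se_slope == pytest.approx(ols.bse[1], abs=1e-10)
        assert fit.p == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_perfect_fit_flagged_degenerate(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = gls_fit(2 * x + 1, x, np.eye(4))
        assert fit.degenerate
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_zero_variance_predictor_unfit(self):
        with pytest.raises(UnfitLocusError):
            gls_fit(np.arange(4.0), np.ones(4), np.eye(4))

    def test_matches_explicit_inverse_oracle(self, rng):
        """200 random small-tree instances agree with the closed form to 1e-8."""
        for _ in range(200):
            n = int(rng.integers(4, 9))
            phylo = gen_tree(n, rng)
            C = phylo_cov(phylo, sorted(phylo.tip_labels)).C
            V = lambda_transform(C, float(rng.uniform(0, 1)))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = gls_fit(y, x, V)
            b, a, se, ll = gls_explicit_inverse(y, x, V)
            assert fit.slope == pytest.approx(b, rel=1e-8, abs=1e-10)
            assert fit.intercept == pytest.approx(a, rel=1e-8, abs=1e-10)
            assert fit.se_slope == pytest.approx(se, rel=1e-8, abs=1e-10)
            assert fit.loglik == pytest.approx(ll, rel=1e-8, abs=1e-8)


class TestLambdaProfile:
    def test_star_tree_profile_is_flat(self, rng):
        C = np.eye(8)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        fit = profile_lambda_ml(y, x, C)
        assert fit.boundary_flag == "flat"
        assert fit.lam == 1.0
        ols = gls_fit(y, x, np.eye(8))
        assert fit.slope == pytest.approx(ols.slope, abs=1e-12)

    def test_loglik_at_optimum_dominates_bounds(self, rng):
        phylo = gen_tree(16, rng)
        C = phylo_cov(phylo, sorted(phylo.tip_labels)).C
        for _ in range(20):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            fit = profile_lambda_ml(y, x, C)
            ll0 = gls_fit(y, x, lambda_transform(C, 0.0)).loglik
            ll1 = gls_fit(y, x, lambda_transform(C, 1.0)).loglik
            assert fit.loglik >= ll0 - 1e-9
            assert fit.loglik >= ll1 - 1e-9

    def test_lambda_zero_equals_ols_exactly(self, rng):
        phylo = gen_tree(10, rng)
        C = phylo_cov(phylo, sorted(phylo.tip_labels)).C
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        pgls_fit = gls_fit(y, x, lambda_transform(C, 0.0))
        # diagonal of an ultrametric depth-1 tree is the identity, so λ=0 is OLS
        ols = gls_fit(y, x, np.eye(10))
        assert pgls_fit.slope == pytest.approx(ols.slope, abs=1e-10)
        assert pgls_fit.se_slope == pytest.approx(ols.se_slope, abs=1e-10)
        assert pgls_fit.p == pytest.approx(ols.p, abs=1e-10)

    def test_recovers_high_lambda_for_bm_traits(self, rng):
        """Brownian y on a 64-tip tree should profile to λ near 1."""
        phylo = gen_tree(64, rng)
        tips = sorted(phylo.tip_labels)
        C = phylo_cov(phylo, tips).C
        lams = []
        for _ in range(200):
            ym = sim_bm(phylo, 0.0, 1.0, 1.0, rng)
            y = np.array([ym[sp] for sp in tips])
            x = rng.normal(size=64)
            lams.append(profile_lambda_ml(y, x, C).lam)
        assert np.mean(lams) >= 0.85

    def test_recovers_low_lambda_for_iid_traits(self, rng):
        phylo = gen_tree(64, rng)
        tips = sorted(phylo.tip_labels)
        C = phylo_cov(phylo, tips).C
        lams = []
        for _ in range(200):
            y = rng.normal(size=64)
            x = rng.normal(size=64)
            lams.append(profile_lambda_ml(y, x, C).lam)
        assert np.mean(lams) <= 0.15

    def test_continuity_of_loglik_in_lambda(self, rng):
        phylo = gen_tree(12, rng)
        C = phylo_cov(phylo, sorted(phylo.tip_labels)).C
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        grid = np.linspace(0, 1, 101)
        lls = [gls_fit(y, x, lambda_transform(C, g)).loglik for g in grid]
        assert np.max(np.abs(np.diff(lls))) < 1.0  # no jumps


class TestSlopeRecovery:
    def test_planted_slope_unbiased(self, rng):
        """Mean bias of the planted slope below 10% at 64 tips, 200 loci."""
        phylo = gen_tree(64, rng)
        tips = sorted(phylo.tip_labels)
        C = phylo_cov(phylo, tips).C
        beta = 8.0
        slopes = []
        for _ in range(200):
            xm = sim_bm(phylo, 0.06, 0.01**2, 1.0, rng)
            x = np.array([xm[sp] for sp in tips])
            noise = sim_bm(phylo, 0.0, 0.25, 1.0, rng)
            y = 3.0 + beta * x + np.array([noise[sp] for sp in tips])
            slopes.append(profile_lambda_ml(y, x, C).slope)
        assert abs(np.mean(slopes) - beta) < 0.1 * beta


class TestPglsWrapper:
    def test_min_n_skip(self, three_tip_tree):
        pairs = {"A": (0.05, 20.0), "B": (0.07, 40.0)}
        out = pgls(pairs, three_tip_tree, min_n=5)
        assert isinstance(out, SkippedLocus)
        assert out.reason == "too-few-species"
        assert out.n == 2

    def test_log_transform_of_lifespan(self):
        assert math.log(90.0) == pytest.approx(4.4998, abs=1e-4)

    def test_species_outside_tree_dropped(self, three_tip_tree):
        pairs = {
            "A": (0.05, 20.0), "B": (0.07, 40.0), "C": (0.06, 30.0),
            "NotInTree": (0.02, 10.0),
        }
        fit = pgls(pairs, three_tip_tree, min_n=3)
        assert fit.n == 3

    def test_fixed_lambda_passthrough(self, three_tip_tree):
        pairs = {"A": (0.05, 20.0), "B": (0.07, 40.0), "C": (0.06, 30.0)}
        fit = pgls(pairs, three_tip_tree, min_n=3, lam=0.5)
        assert fit.lam == 0.5

    def test_pearson_diagnostic_reported(self, three_tip_tree, rng):
        pairs = {sp: (float(rng.uniform(0.02, 0.1)), float(rng.uniform(5, 80)))
                 for sp in ("A", "B", "C")}
        fit = pgls(pairs, three_tip_tree, min_n=3)
        assert -1.0 <= fit.pearson_r <= 1.0
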