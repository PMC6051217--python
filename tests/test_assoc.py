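"""Logistic IRLS fitter, association wrappers, splines and nonlinearity LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heightmr.assoc import (
    SeparationError,
    Z95,
    fit_logistic,
    grs_association,
    nonlinearity_test,
    rcs_basis,
    tertile_association,
)
from heightmr.grs import ScoreVector, assign_tertiles


def _two_by_two(a, b, c, d):
    """Cases exposed/unexposed a/b; controls exposed/unexposed c/d."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_saturated_2x2_equals_log_odds_ratio(self):
        y, X = _two_by_two(20, 10, 10, 20)
        fit = fit_logistic(y, X)
        assert fit.beta[1] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_constant_outcome_is_separation(self):
        y = np.ones(20)
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_perfectly_separating_covariate_detected(self):
        x = np.r_[np.zeros(15), np.ones(15)]
        y = x.copy()
        X = np.column_stack([np.ones(30), x])
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(20.0)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(np.r_[np.zeros(10), np.ones(10)], X)

    def test_matches_independent_irls_oracle(self, rng):
        n = 2000
        X = np.column_stack(
            [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n), rng.normal(2, 3, n)]
        )
        eta = -0.5 + 0.4 * X[:, 1] - 0.3 * X[:, 2] + 0.1 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, oracle.params, atol=1e-6)
        assert np.allclose(fit.se, oracle.bse, atol=1e-6)

    def test_loglik_nondecreasing_over_iterations(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_logistic(y, X)
        assert np.all(np.diff(fit.loglik_path) >= -1e-10)


def _pheno(y, rng, n_extra_cols=2):
    n = len(y)
    df = pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "status": y.astype(int),
            "subtype": np.where(y == 1, "adenocarcinoma", "control"),
            "age": rng.normal(60, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
        }
    )
    return df


class TestGrsAssociation:
    def test_covariate_free_fit_matches_2x2_closed_form(self, rng):
        y = np.r_[np.ones(30), np.zeros(30)]
        x = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        sv = ScoreVector([f"P{i}" for i in range(60)], x, "weighted", 1)
        res = grs_association(sv, _pheno(y, rng))
        assert res.beta == pytest.approx(np.log(20 * 20 / (10 * 10)), abs=1e-7)
        assert res.n_cases == 30 and res.n_controls == 30

    def test_ci_is_exact_wald_transform(self, rng):
        y = (rng.random(200) < 0.5).astype(float)
        sv = ScoreVector([f"P{i}" for i in range(200)], rng.normal(size=200), "weighted", 1)
        res = grs_association(sv, _pheno(y, rng), ("age", "sex"))
        lo, hi = res.ci95
        assert lo == pytest.approx(np.exp(res.beta - Z95 * res.se))
        assert hi == pytest.approx(np.exp(res.beta + Z95 * res.se))
        assert res.or_ > 0

    def test_invariant_to_affine_covariate_shift(self, rng):
        y = (rng.random(400) < 0.5).astype(float)
        score = rng.normal(size=400)
        pheno = _pheno(y, rng)
        sv = ScoreVector(pheno["subject_id"].tolist(), score, "weighted", 1)
        res1 = grs_association(sv, pheno, ("age",))
        shifted = pheno.copy()
        shifted["age"] = 3.0 * shifted["age"] - 120.0
        res2 = grs_association(sv, shifted, ("age",))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-8)

    def test_subtype_filter_drops_other_cases_keeps_controls(self, rng):
        y = np.r_[np.ones(40), np.zeros(40)]
        pheno = _pheno(y, rng)
        pheno.loc[:19, "subtype"] = "squamous"
        sv = ScoreVector(pheno["subject_id"].tolist(), rng.normal(size=80), "weighted", 1)
        res = grs_association(sv, pheno, (), subtype_filter="adenocarcinoma")
        assert res.n_cases == 20
        assert res.n_controls == 40

    def test_empty_case_set_after_filter_errors(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)]
        pheno = _pheno(y, rng)
        sv = ScoreVector(pheno["subject_id"].tolist(), rng.normal(size=20), "weighted", 1)
        with pytest.raises(ValueError, match="cases"):
            grs_association(sv, pheno, (), subtype_filter="squamous")


class TestTertileAssociation:
    def test_wald_and_score_trend_agree_asymptotically(self, rng):
        n = 3000
        score = rng.normal(size=n)
        eta = -0.3 + 0.4 * score
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pheno = _pheno(y, rng)
        sv = ScoreVector(pheno["subject_id"].tolist(), score, "weighted", 1)
        tert = assign_tertiles(sv)
        wald = tertile_association(tert, pheno, trend="wald")
        scoret = tertile_association(tert, pheno, trend="score")
        assert wald.trend.p == pytest.approx(scoret.trend.p, rel=0.15)
        assert wald.q3.or_ > wald.q2.or_ > 1.0

    def test_constant_scores_give_null_odds_ratios(self, rng):
        y = np.tile([1.0, 0.0], 60)  # statuses interleaved across stable order
        pheno = _pheno(y, rng)
        sv = ScoreVector(pheno["subject_id"].tolist(), np.zeros(120), "weighted", 1)
        tert = assign_tertiles(sv)
        res = tertile_association(tert, pheno)
        # tertiles by stable order are independent of status: ORs near 1
        assert res.q2.or_ == pytest.approx(1.0, abs=0.6)
        assert res.trend.p > 0.05


class TestRcsBasis:
    KNOTS = [-1.0, 0.0, 1.0, 2.5]

    def test_below_first_knot_spline_terms_vanish(self):
        x = np.array([-5.0, -2.0, -1.0])
        b = rcs_basis(x, self.KNOTS)
        assert b.shape == (3, 3)
        assert np.allclose(b[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        x = np.linspace(3.0, 8.0, 200)
        b = rcs_basis(x, self.KNOTS)
        second_diff = np.diff(b, n=2, axis=0)
        assert np.max(np.abs(second_diff)) < 1e-9

    def test_c2_continuity_at_knots(self):
        eps = 1e-5
        for t in self.KNOTS:
            x = np.array([t - 2 * eps, t - eps, t, t + eps, t + 2 * eps])
            b = rcs_basis(x, self.KNOTS)
            for col in range(1, b.shape[1]):
                d2 = np.diff(b[:, col], n=2) / eps**2
                assert abs(d2[0] - d2[-1]) < 1e-3  # curvature continuous across knot
        # and the function itself is smooth: values are finite and ordered
        assert np.all(np.isfinite(b))

    def test_unsorted_or_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 1.0, 1.0, 2.0])


class TestNonlinearity:
    def test_near_linear_region_gives_tiny_lrt(self, rng):
        n = 800
        y = (rng.random(n) < 0.5).astype(float)
        pheno = _pheno(y, rng)
        # scores concentrated inside one knot interval: spline terms ~ collinear
        score = rng.normal(size=n)
        sv = ScoreVector(pheno["subject_id"].tolist(), score, "weighted", 1)
        res = nonlinearity_test(sv, pheno)
        assert res.df == 2
        assert res.statistic >= 0.0
        assert 0 < res.p <= 1

    def test_planted_quadratic_effect_detected(self, rng):
        n = 4000
        score = rng.normal(size=n)
        eta = -0.5 + 0.8 * score**2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pheno = _pheno(y, rng)
        sv = ScoreVector(pheno["subject_id"].tolist(), score, "weighted", 1)
        res = nonlinearity_test(sv, pheno)
        assert res.p < 1e-6
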