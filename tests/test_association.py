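import numpy as np
import pytest
from itertools import permutations

import statsmodels.api as sm
from scipy import stats
from scipy.special import ndtri

from glycocc import (
    DesignError,
    SeparationError,
    bh_adjust,
    fit_intracase,
    fit_logistic,
    inverse_normal_transform,
    ivw_meta,
    symptom_burden_trend,
)
from glycocc.association import dichotomize_duration

from helpers_oracles import bh_bruteforce


class TestInverseNormalTransform:
    def test_three_point_example(self):
        out = np.asarray(inverse_normal_transform([10, 20, 15]))
        expected = ndtri([(1 - 0.5) / 3, (3 - 0.5) / 3, (2 - 0.5) / 3])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [-0.9674, 0.9674, 0.0], atol=1e-4)

    def test_average_rank_for_ties(self):
        out = np.asarray(inverse_normal_transform([1, 1, 5, 9]))
        expected_tied = ndtri((1.5 - 0.5) / 4)
        assert out[0] == pytest.approx(expected_tied)
        assert out[1] == pytest.approx(expected_tied)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, size=101)
        a = np.asarray(inverse_normal_transform(x))
        b = np.asarray(inverse_normal_transform(-x))
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_moments_near_standard_normal(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=800)
        t = np.asarray(inverse_normal_transform(x))
        assert abs(t.mean()) < 1e-8
        assert t.std() == pytest.approx(1.0, abs=0.01)
        assert abs(stats.skew(t)) < 0.1
        assert abs(stats.kurtosis(t)) < 0.3

    def test_constant_vector_rejected(self):
        with pytest.raises(DesignError):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_blom_offset(self):
        out = np.asarray(inverse_normal_transform([1, 2, 3], offset="blom"))
        np.testing.assert_allclose(out, ndtri((np.array([1, 2, 3]) - 0.375) / 3.25))


class TestLogistic:
    def test_two_by_two_closed_form(self):
        """Cell counts (cases 30/20 exposed/unexposed; controls 10/40) give
        OR (30*40)/(20*10) = 6 with SE sqrt(sum of reciprocal cells)."""
        x = np.concatenate([np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        res = fit_logistic(x, y)
        assert res.or_ == pytest.approx(6.0, abs=1e-4)
        assert res.beta == pytest.approx(np.log(6.0), abs=1e-4)
        assert res.se == pytest.approx(np.sqrt(1 / 30 + 1 / 20 + 1 / 10 + 1 / 40), abs=1e-4)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        age = rng.uniform(20, 70, n)
        sex = rng.choice(["F", "M"], n, p=[0.9, 0.1])
        logits = -0.2 + 0.5 * x + 0.01 * (age - 45)
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        ours = fit_logistic(x, y, age, sex)
        X = sm.add_constant(np.column_stack([x, age, (sex == "M").astype(float)]))
        ref = sm.Logit(y, X).fit(disp=0)
        assert ours.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert ours.se == pytest.approx(ref.bse[1], abs=1e-6)
        assert ours.p == pytest.approx(ref.pvalues[1], rel=1e-4)

    def test_null_type_one_error(self):
        rejections = 0
        reps = 100
        rng = np.random.default_rng(7)
        for _ in range(reps):
            x = rng.standard_normal(500)
            y = rng.permutation(np.repeat([0, 1], 250))
            res = fit_logistic(x, y)
            if abs(res.beta) > 3 * res.se:
                rejections += 1
        assert rejections <= 2  # ~0.3% nominal; allow a little slack

    def test_separation_raises(self):
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = np.concatenate([np.ones(20), np.zeros(20)])
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            fit_logistic(np.arange(10.0), np.ones(10))

    def test_known_effect_recovery_and_coverage(self):
        """Planted log-OR 0.5 per SD: estimates near truth, CI covers ~95%."""
        rng = np.random.default_rng(11)
        b = 0.5
        covered, est = 0, []
        reps = 200
        for _ in range(reps):
            n = 2000
            y = np.repeat([0, 1], n // 2)
            x = rng.standard_normal(n) + y * b  # exact logistic slope b per unit
            # per-unit slope is b; predictor already ~unit within-class SD
            res = fit_logistic(x, y)
            est.append(res.beta)
            if abs(res.beta - b) <= 1.959963984540054 * res.se:
                covered += 1
        assert np.mean(est) == pytest.approx(b, abs=0.1)
        assert covered / reps == pytest.approx(0.95, abs=0.03)


class TestIntracase:
    def test_null_trait(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            g = rng.standard_normal(200)
            t = rng.integers(0, 2, 200).astype(float)
            res = fit_intracase(g, t)
            if abs(res.beta) > 3 * res.se:
                hits += 1
        assert hits <= 2

    def test_planted_half_sd_shift(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 2, 300).astype(float)
        g = rng.standard_normal(300) + 0.5 * t
        age = rng.uniform(20, 70, 300)
        sex = rng.choice(["F", "M"], 300)
        res = fit_intracase(g, t, age, sex)
        assert res.beta == pytest.approx(0.5, abs=0.15)

    def test_insufficient_df(self):
        with pytest.raises(DesignError):
            fit_intracase([0.1, 0.2], [0.0, 1.0])

    def test_constant_trait(self):
        with pytest.raises(DesignError):
            fit_intracase(np.arange(20.0), np.ones(20))

    def test_duration_dichotomization(self):
        np.testing.assert_array_equal(
            dichotomize_duration([2.0, 8.0, 8.1, 30.0]), [0, 0, 1, 1]
        )


class TestMeta:
    def test_closed_form_example(self):
        m = ivw_meta([(0.5, 0.1), (0.1, 0.2)])
        assert m.beta == pytest.approx(0.42, abs=1e-6)
        assert m.se == pytest.approx(1 / np.sqrt(125), abs=1e-6)

    def test_single_study_passthrough(self):
        m = ivw_meta([(0.3, 0.05)])
        assert (m.beta, m.se) == (pytest.approx(0.3), pytest.approx(0.05))
        assert m.q == pytest.approx(0.0)

    def test_identical_studies_halve_variance(self):
        m = ivw_meta([(0.2, 0.1), (0.2, 0.1)])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            ivw_meta([(0.1, 0.0)])

    def test_matches_pooled_gaussian_fit(self):
        """IVW equals the pooled estimate in the equal-variance linear case."""
        rng = np.random.default_rng(6)
        x1, x2 = rng.standard_normal(300), rng.standard_normal(300)
        y1 = 0.4 * x1 + rng.standard_normal(300)
        y2 = 0.4 * x2 + rng.standard_normal(300)
        f1 = sm.OLS(y1, sm.add_constant(x1)).fit()
        f2 = sm.OLS(y2, sm.add_constant(x2)).fit()
        m = ivw_meta([(f1.params[1], f1.bse[1]), (f2.params[1], f2.bse[1])])
        pooled = sm.OLS(np.concatenate([y1, y2]),
                        sm.add_constant(np.concatenate([x1, x2]))).fit()
        assert m.beta == pytest.approx(pooled.params[1], abs=0.02)


class TestBH:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_singleton(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_bounds_check(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_all_permutations(self):
        base = [0.001, 0.013, 0.04, 0.04, 0.2, 0.9]
        for perm in permutations(base):
            np.testing.assert_allclose(
                bh_adjust(list(perm)), bh_bruteforce(list(perm)), atol=1e-12
            )

    def test_monotone_and_dominates_input(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 50)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSymptomBurden:
    def test_null_slope(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            g = rng.standard_normal(300)
            c = rng.integers(0, 5, 300)
            res, _ = symptom_burden_trend(g, c)
            if abs(res.beta) > 3 * res.se:
                hits += 1
        assert hits <= 2

    def test_planted_monotone_shift(self):
        rng = np.random.default_rng(13)
        c = rng.integers(0, 5, 400)
        g = rng.standard_normal(400) + 0.2 * c
        res, groups = symptom_burden_trend(g, c)
        assert res.beta == pytest.approx(0.2, abs=0.08)
        assert set(groups.columns) == {"count", "n", "median", "q1", "q3"}

    def test_constant_counts_rejected(self):
        with pytest.raises(DesignError):
            symptom_burden_trend(np.arange(10.0), np.ones(10))
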