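"""Estimation, offset GLM, GLMM quadrature, LRT, power, multiplicity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, special, stats

from meiodrive import inference as inf

from conftest import toy_config


class TestEstimateK:
    def test_abxab_printed_example(self):
        """330 AB x AB transmissions, 164 Australian: k ~ 0.497."""
        est = inf.estimate_k(164, 330)
        assert round(est.k, 4) == 0.4970
        assert est.ci95[0] < est.k < est.ci95[1]
        assert est.p_binomial > 0.9

    def test_exact_half_gives_p_one(self):
        assert inf.estimate_k(100, 200).p_binomial == 1.0

    def test_central_p_matches_independent_tail_sum(self):
        """45/100 vs 0.5: doubled lower tail computed directly."""
        expect = 2 * sum(
            math.comb(100, i) * 0.5**100 for i in range(0, 46)
        )
        assert abs(inf.estimate_k(45, 100).p_binomial - expect) < 1e-12
        assert round(expect, 3) == 0.368

    def test_minlike_available(self):
        p = inf.binomial_p_two_sided(45, 100, 0.5, method="minlike")
        assert p == pytest.approx(stats.binomtest(45, 100, 0.5).pvalue)

    @pytest.mark.parametrize("s,n", [(1, 10), (7, 11), (164, 330), (0, 5)])
    def test_wilson_ci_contains_estimate(self, s, n):
        lo, hi = inf.wilson_ci(s, n)
        assert lo <= s / n <= hi

    def test_zero_n_rejected(self):
        with pytest.raises(inf.EstimateError):
            inf.estimate_k(0, 0)


class TestOffsetGLM:
    def test_analytic_formula_example(self):
        """k = 0.489 against background 0.495: beta0 ~ -0.0240."""
        fit = inf.glm_offset_fit(489, 1000, 0.495)
        expect = special.logit(0.489) - special.logit(0.495)
        assert fit.beta0 == pytest.approx(expect)
        assert round(expect, 4) == -0.0240

    def test_identity_at_background(self):
        assert inf.glm_offset_fit(495, 1000, 0.495).beta0 == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "s,n,p0", [(30, 100, 0.5), (7, 11, 0.3), (489, 1000, 0.495),
                   (164, 330, 0.52), (999, 1000, 0.5)]
    )
    def test_mle_matches_numeric_optimiser(self, s, n, p0):
        """Analytic beta0 equals maximisation of the offset binomial
        likelihood to 1e-8."""
        if s in (0, n):
            pytest.skip("boundary handled separately")
        # the likelihood is concave: solve the score equation numerically
        root = optimize.brentq(
            lambda b: s - n * special.expit(special.logit(p0) + b),
            -30, 30, xtol=1e-12,
        )
        assert abs(inf.glm_offset_fit(s, n, p0).beta0 - root) < 1e-8

    def test_boundary_uses_profile_likelihood(self):
        fit = inf.glm_offset_fit(0, 20, 0.5)
        assert fit.boundary
        assert fit.beta0 == -math.inf
        assert fit.ci95[0] == -math.inf and np.isfinite(fit.ci95[1])
        assert 0 < fit.p_wald < 1e-4


class TestBackgroundRate:
    @staticmethod
    def _records(pairs):
        rows = []
        for marker, s, n in pairs:
            rows += [("p1", "M", "F1", f"o{i}", marker, "chr1", "centromeric", 1)
                     for i in range(s)]
            rows += [("p1", "M", "F1", f"o{i}", marker, "chr1", "centromeric", 0)
                     for i in range(n - s)]
        return pd.DataFrame(
            rows, columns=["parent_id", "parent_sex", "parent_cohort",
                           "offspring_id", "marker_id", "chromosome",
                           "position_class", "transmitted"],
        )

    def test_raw_mode_is_pooled_proportion(self):
        recs = self._records([("m1", 495, 1000), ("m2", 495, 1000)])
        assert inf.background_rate(recs, mode="raw") == pytest.approx(0.495)

    def test_glmm_and_raw_agree_when_balanced(self):
        recs = self._records([("m1", 250, 500), ("m2", 250, 500)])
        assert inf.background_rate(recs, mode="glmm") == pytest.approx(
            0.5, abs=1e-4
        )

    def test_glmm_differs_from_raw_when_unbalanced_and_heterogeneous(self):
        """Unbalanced marker sizes + real among-marker spread: the
        random-intercept estimate down-weights the huge marker."""
        recs = self._records([("m1", 1400, 2000), ("m2", 20, 100),
                              ("m3", 30, 100), ("m4", 25, 100)])
        raw = inf.background_rate(recs, mode="raw")
        glmm = inf.background_rate(recs, mode="glmm")
        assert abs(glmm - raw) > 0.02

    def test_no_males_instructs_half(self):
        recs = self._records([("m1", 5, 10)])
        recs["parent_sex"] = "F"
        with pytest.raises(inf.EstimateError, match="0.5"):
            inf.background_rate(recs)


class TestGLMM:
    def test_sigma_zero_degenerates_to_offset_glm(self):
        counts = pd.DataFrame({"group": list("abcd"),
                               "successes": [30] * 4, "n": [50] * 4})
        fit = inf.glmm_fit(counts, 0.5)
        glm = inf.glm_offset_fit(120, 200, 0.5)
        assert fit.sigma == 0.0
        assert abs(fit.beta[0] - glm.beta0) < 1e-6

    @pytest.mark.parametrize("beta0,sigma", [(0.0, 0.3), (0.3, 0.7), (-0.5, 1.2)])
    def test_quadrature_matches_numeric_integration(self, beta0, sigma):
        """Marginal likelihood equals brute-force integration to 1e-6."""
        counts = pd.DataFrame({"group": ["a", "b", "c"],
                               "successes": [8, 5, 2], "n": [10, 10, 10]})
        ll = inf.glmm_marginal_loglik(beta0, sigma, counts, 0.5)

        def group_ll(s, n):
            def f(u):
                p = special.expit(special.logit(0.5) + beta0 + u)
                return stats.binom.pmf(s, n, p) * stats.norm.pdf(u, 0, sigma)
            v, _ = integrate.quad(f, -10 * sigma, 10 * sigma, limit=200)
            return math.log(v)

        oracle = sum(group_ll(s, n) for s, n in
                     zip(counts["successes"], counts["n"]))
        assert abs(ll - oracle) < 1e-6

    def test_multirow_groups_integrate_jointly(self):
        """Rows sharing a group share one random intercept: the joint
        marginal differs from treating rows as separate groups."""
        counts = pd.DataFrame({
            "group": ["g1", "g1", "g2", "g2"],
            "level": ["x", "y", "x", "y"],
            "successes": [8, 7, 2, 3], "n": [10, 10, 10, 10],
        })
        beta = [0.1, -0.1]
        sigma = 0.8
        ll_joint = inf.glmm_marginal_loglik(beta, sigma, counts, 0.5,
                                            fixed="eight_level")

        def cell(s, n, b):
            def f(u):
                p = special.expit(special.logit(0.5) + b + u)
                return stats.binom.pmf(s, n, p)
            return f

        oracle = 0.0
        for g in ("g1", "g2"):
            sub = counts[counts["group"] == g]
            def integrand(u, sub=sub):
                val = stats.norm.pdf(u, 0, sigma)
                for row in sub.itertuples():
                    b = beta[0] if row.level == "x" else beta[1]
                    val *= cell(row.successes, row.n, b)(u)
                return val
            v, _ = integrate.quad(integrand, -8, 8, limit=200)
            oracle += math.log(v)
        assert abs(ll_joint - oracle) < 1e-6

    def test_sigma_recovered_from_simulated_groups(self):
        """56 markers of n = 350 with true among-marker SD 0.3 on the
        logit scale: median absolute error of sigma-hat below 0.1."""
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(20):
            u = rng.normal(0, 0.3, 56)
            p = special.expit(u)
            s = rng.binomial(350, p)
            counts = pd.DataFrame({"group": [f"m{i}" for i in range(56)],
                                   "successes": s, "n": 350})
            fit = inf.glmm_fit(counts, 0.5)
            errs.append(abs(fit.sigma - 0.3))
        assert np.median(errs) < 0.1

    def test_needs_two_groups(self):
        counts = pd.DataFrame({"group": ["a"], "successes": [5], "n": [10]})
        with pytest.raises(inf.EstimateError):
            inf.glmm_fit(counts, 0.5)


class TestLRT:
    def test_zero_lr_gives_p_one(self):
        res = inf.lrt_random_effect(-10.0, -10.0)
        assert res.p_nominal == 1.0 and res.p_boundary == 1.0

    def test_chi_square_quantile_identity(self):
        res = inf.lrt_random_effect(0.0, 3.841458820694124 / 2)
        assert res.p_nominal == pytest.approx(0.05, abs=1e-6)
        assert res.p_boundary == pytest.approx(0.025, abs=1e-6)

    def test_negative_lr_is_optimisation_failure(self):
        with pytest.raises(inf.EstimateError):
            inf.lrt_random_effect(-5.0, -6.0)

    def test_nominal_lrt_conservative_under_homogeneity(self):
        """With no real among-group variance the nominal chi-square(1)
        LRT rejects in at most ~5% of replicates (boundary effect)."""
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 200
        for _ in range(reps):
            s = rng.binomial(60, 0.5, 12)
            counts = pd.DataFrame({"group": [f"g{i}" for i in range(12)],
                                   "successes": s, "n": 60})
            fit = inf.glmm_fit(counts, 0.5)
            res = inf.lrt_random_effect(fit.loglik_sigma0, fit.loglik)
            rejections += res.p_nominal <= 0.05
        assert rejections / reps <= 0.07


class TestContrast:
    @staticmethod
    def _fit(props, n=400):
        rng = np.random.default_rng(2)
        rows = []
        for j, p in enumerate(props):
            for g in range(6):
                rows.append((f"m{g}", f"lev{j}", rng.binomial(n, p), n))
        counts = pd.DataFrame(rows, columns=["group", "level", "successes", "n"])
        return inf.glmm_fit(counts, 0.5, fixed="eight_level")

    def test_equal_levels_give_large_p(self):
        fit = self._fit([0.5] * 4)
        res = inf.contrast_level(fit, "lev0")
        assert res.p > 0.2

    def test_displaced_level_detected(self):
        fit = self._fit([0.62, 0.5, 0.5, 0.5])
        res = inf.contrast_level(fit, "lev0")
        assert res.p < 1e-3

    def test_matches_hand_built_linear_combination(self):
        fit = self._fit([0.55, 0.5, 0.48, 0.52])
        res = inf.contrast_level(fit, "lev1")
        idx = fit.levels.index("lev1")
        c = np.zeros(len(fit.levels))
        c[idx] = 1.0
        others = [i for i in range(len(fit.levels)) if i != idx]
        w = fit.level_n[others] / fit.level_n[others].sum()
        c[others] = -w
        est = c @ fit.beta
        se = math.sqrt(c @ fit.vcov @ c)
        assert res.estimate == pytest.approx(est)
        assert res.se == pytest.approx(se)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(est / se)))

    def test_missing_level_errors(self):
        fit = self._fit([0.5] * 3)
        with pytest.raises(inf.EstimateError, match="missing"):
            inf.contrast_level(fit, "lev9")


class TestPower:
    def test_arcsine_closed_form(self):
        """k_bound solves Phi(h sqrt(n) - z) + Phi(-h sqrt(n) - z) = 0.8;
        for one-sided-dominant h this is 0.5 + 0.5 sin((z+z_80)/sqrt(n))."""
        n = 9469
        spec = inf.power_detectable_k(n)
        h = (stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) / math.sqrt(n)
        assert spec.k_bound == pytest.approx(0.5 + 0.5 * math.sin(h), abs=1e-4)

    @pytest.mark.parametrize("n", [500, 2000, 9469])
    def test_arcsine_agrees_with_exact_binomial_power(self, n):
        a = inf.power_detectable_k(n, method="arcsine").k_bound
        e = inf.power_detectable_k(n, method="exact").k_bound
        assert abs(a - e) < 0.003

    def test_bound_strictly_decreasing_in_n(self):
        ks = [inf.power_detectable_k(n).k_bound for n in (200, 1000, 5000, 20000)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_required_n_roundtrip(self):
        n = inf.required_n(0.52)
        assert inf.power_detectable_k(n).k_bound <= 0.5201

    def test_zero_effect_infeasible(self):
        with pytest.raises(inf.EstimateError):
            inf.required_n(0.5)

    def test_infeasible_power_rejected(self):
        with pytest.raises(inf.EstimateError):
            inf.power_detectable_k(100, alpha=0.5, target_power=0.4)


class TestMultiplicityAndSexRatio:
    def test_registry_product(self):
        led = inf.bonferroni_ledger((56, 2, 2, 2))
        assert led["m"] == 448

    def test_single_test_uncorrected(self):
        assert float(inf.bonferroni_correct(0.04, 1)) == pytest.approx(0.04)

    def test_fmr_arithmetic(self):
        res = inf.sex_ratio_test(107, 100)
        assert res.fmr == pytest.approx(1.07)

    def test_equal_counts(self):
        res = inf.sex_ratio_test(50, 50)
        assert res.fmr == 1.0 and res.p == 1.0

    def test_ci_coverage_under_fair_sex_ratio(self):
        """Delta-method 95% CI on the FMR covers the true value ~95% of
        the time at the study's sample size."""
        rng = np.random.default_rng(3)
        n = 1348
        hits = 0
        reps = 400
        for _ in range(reps):
            nf = rng.binomial(n, 0.5)
            res = inf.sex_ratio_test(nf, n - nf)
            hits += res.ci95[0] <= 1.0 <= res.ci95[1]
        assert 0.92 <= hits / reps <= 0.985
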