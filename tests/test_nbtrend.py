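import numpy as np
import pytest
from scipy.stats import chi2

from hypoxtc.nbtrend import (
    build_designs,
    estimate_dispersion_mom,
    fit_dispersion_trend,
    fit_nb_glm,
    lrt_pvalue,
    nb_trend_scan,
)
from hypoxtc.preprocess import total_count_normalize
from hypoxtc.simulate import DEFAULT_TIMES, SyntheticTruth, TrajectorySpec, simulate_counts

from conftest import make_matrix

TIMES = np.array(DEFAULT_TIMES)


class TestBuildDesigns:
    def test_hypoxia_course(self):
        pair = build_designs(TIMES)
        assert pair.full_design.shape == (8, 3)
        np.testing.assert_allclose(pair.full_design[0], [1, 0, 0])
        np.testing.assert_allclose(pair.full_design[-1], [1, 1, 1])
        np.testing.assert_allclose(pair.reduced_design, np.ones((8, 1)))

    def test_too_few_distinct_times(self):
        with pytest.raises(ValueError, match="4 distinct"):
            build_designs([0, 5])
        with pytest.raises(ValueError, match="4 distinct"):
            build_designs([0, 5, 5, 10])


class TestDispersionMom:
    def test_subpoisson_variance_clamps_to_zero(self):
        # sample variance (1) below the mean (100) -> clamped at 0
        assert estimate_dispersion_mom([99, 100, 101]) == 0.0

    def test_arithmetic(self):
        # mean 100, ddof-1 variance 600 -> alpha = 500/10000 = 0.05
        x = np.array([100 - np.sqrt(300), 100 + np.sqrt(300)])
        assert x.var(ddof=1) == pytest.approx(600)
        assert estimate_dispersion_mom(x) == pytest.approx(0.05)

    def test_constant_vector(self):
        assert estimate_dispersion_mom([50.0] * 8) == 0.0


class TestDispersionTrend:
    def test_recovers_constant_alpha(self):
        rng = np.random.default_rng(0)
        mus = np.exp(rng.uniform(np.log(10), np.log(10_000), 2000))
        alpha = 0.05
        r = 1 / alpha
        hats = []
        for mu in mus:
            y = rng.negative_binomial(r, r / (r + mu), size=8)
            hats.append(estimate_dispersion_mom(y) if y.mean() > 0 else 0.0)
        trend = fit_dispersion_trend(mus, hats)
        assert 0.03 <= trend.a0 <= 0.07
        assert abs(trend.a1 / 1000) < 0.02  # 1/mu term negligible at large mu

    def test_recovers_mean_dependent_trend(self):
        rng = np.random.default_rng(1)
        mus = np.exp(rng.uniform(np.log(10), np.log(10_000), 5000))
        hats = []
        for mu in mus:
            alpha = 0.01 + 2.0 / mu
            r = 1 / alpha
            y = rng.negative_binomial(r, r / (r + mu), size=8)
            hats.append(estimate_dispersion_mom(y) if y.mean() > 0 else 0.0)
        trend = fit_dispersion_trend(mus, hats)
        assert 0.005 <= trend.a0 <= 0.015
        assert 1.0 <= trend.a1 <= 3.0

    def test_all_zero_estimates_fall_back(self):
        trend = fit_dispersion_trend(np.arange(1, 31), np.zeros(30))
        assert trend(100.0) == pytest.approx(1e-8)

    def test_few_positive_estimates_use_median(self):
        alphas = np.zeros(30)
        alphas[:5] = [0.1, 0.2, 0.3, 0.4, 0.5]
        trend = fit_dispersion_trend(np.arange(1, 31), alphas)
        assert trend(50.0) == pytest.approx(0.3)


class TestFitNbGlm:
    def test_intercept_closed_form_any_alpha(self):
        y = np.array([3, 7, 5, 9, 4, 6, 8, 2])
        for alpha in (0.0, 0.1, 1.0):
            fit = fit_nb_glm(y, np.ones((8, 1)), np.full(8, 0.7), alpha)
            assert fit.converged
            assert fit.coefficients[0] == pytest.approx(np.log(y.mean()) - 0.7, abs=1e-7)

    def test_poisson_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = build_designs(TIMES).full_design
        y = rng.poisson(np.exp(4 + 0.8 * X[:, 1]))
        off = np.log(rng.uniform(0.9, 1.1, 8))
        ours = fit_nb_glm(y, X, off, alpha=0.0)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_negative_binomial_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = build_designs(TIMES).full_design
        alpha = 0.08
        r = 1 / alpha
        mu = np.exp(5 + 1.2 * X[:, 1] - 0.5 * X[:, 2])
        y = rng.negative_binomial(r, r / (r + mu))
        ours = fit_nb_glm(y, X, np.zeros(8), alpha=alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-5)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-5)

    def test_all_zero_counts_flagged(self):
        fit = fit_nb_glm(np.zeros(8), np.ones((8, 1)), np.zeros(8), alpha=0.1)
        assert not fit.converged
        assert np.isfinite(fit.log_likelihood)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="nonnegative integers"):
            fit_nb_glm([1.5, 2, 3, 4], np.ones((4, 1)), np.zeros(4), 0.0)
        with pytest.raises(ValueError, match="alpha"):
            fit_nb_glm([1, 2, 3, 4], np.ones((4, 1)), np.zeros(4), -0.1)


class TestLrtPvalue:
    def test_equal_likelihoods(self):
        assert lrt_pvalue(-10.0, -10.0) == (0.0, 1.0)

    @pytest.mark.parametrize("stat,p", [(5.991, 0.05), (13.816, 0.001)])
    def test_chi2_tail(self, stat, p):
        got_stat, got_p = lrt_pvalue(-10.0 + stat / 2, -10.0)
        assert got_stat == pytest.approx(stat)
        assert got_p == pytest.approx(p, rel=1e-2)
        assert got_p == pytest.approx(chi2.sf(stat, 2), rel=1e-12)

    def test_nested_violation_flagged(self):
        with pytest.raises(RuntimeError, match="optimization failure"):
            lrt_pvalue(-11.0, -10.0)


def _flat_truths(n, mu=500.0, alpha=0.05):
    return [
        SyntheticTruth(f"g{i:05d}", TrajectorySpec("flat", mu), alpha, 1.0)
        for i in range(n)
    ]


class TestScan:
    def test_type_one_error_with_true_alpha(self):
        truths = _flat_truths(3000)
        m = simulate_counts(truths, TIMES, seed=11)
        norm = total_count_normalize(m)
        res = nb_trend_scan(
            m, norm.scale_factors, dispersions=np.full(3000, 0.05)
        )
        p = np.array([r.p_raw for r in res])
        assert 0.03 <= np.mean(p <= 0.05) <= 0.07

    def test_power_increases_with_fold(self):
        sens = {}
        for fold in (2.0, 8.0):
            truths = [
                SyntheticTruth(
                    f"g{i:04d}",
                    TrajectorySpec("smooth", 200.0, fold=fold, k=0.05, t50=60.0),
                    0.05,
                    fold,
                )
                for i in range(400)
            ]
            m = simulate_counts(truths, TIMES, seed=13)  # paired seeds
            norm = total_count_normalize(m)
            res = nb_trend_scan(m, norm.scale_factors, dispersions=np.full(400, 0.05))
            sens[fold] = np.mean([r.p_raw <= 0.05 for r in res])
        assert sens[8.0] > sens[2.0]

    def test_pooled_dispersion_inflated_for_trended_genes(self):
        flat = _flat_truths(300, mu=400.0, alpha=0.05)
        trended = [
            SyntheticTruth(
                f"t{i:04d}",
                TrajectorySpec("smooth", 100.0, fold=4.0, k=0.05, t50=60.0),
                0.05,
                4.0,
            )
            for i in range(300)
        ]
        m = simulate_counts(flat + trended, TIMES, seed=17)
        norm = total_count_normalize(m)
        alpha_hat = {
            g: estimate_dispersion_mom(row * norm.scale_factors)
            for g, row in zip(m.gene_ids, m.values)
        }
        mean_flat = np.mean([alpha_hat[t.gene_id] for t in flat])
        mean_trend = np.mean([alpha_hat[t.gene_id] for t in trended])
        assert mean_trend > mean_flat

    def test_outlier_gene_found_by_lrt_not_autocor(self):
        """A flat gene with one extreme spike: the quadratic LRT reacts while
        the smoothness-seeking permutation test does not."""
        from hypoxtc.autocor import exhaustive_autocor_pvalue

        values = np.array([[100, 1600, 100, 100, 100, 100, 100, 100]], dtype=float)
        m = make_matrix(values, gene_ids=["spike"])
        res = nb_trend_scan(m, np.ones(8), dispersions=np.array([0.05]))
        p_autocor = exhaustive_autocor_pvalue(values[0]).p_raw
        assert res[0].p_raw < 0.01 < p_autocor

    def test_offset_rescaling_absorbed_into_intercept(self):
        truths = _flat_truths(50)
        m = simulate_counts(truths, TIMES, seed=19)
        a = nb_trend_scan(m, np.ones(8), dispersions=np.full(50, 0.05))
        b = nb_trend_scan(m, np.full(8, 2.0), dispersions=np.full(50, 0.05))
        for ra, rb in zip(a, b):
            assert ra.lrt_stat == pytest.approx(rb.lrt_stat, abs=1e-5)

    def test_empty_gene_set(self):
        m = simulate_counts(_flat_truths(5), TIMES, seed=1)
        assert nb_trend_scan(m, np.ones(8), []) == []
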