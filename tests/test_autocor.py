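import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypoxtc.autocor import (
    autocor_scan,
    enumerate_permutations,
    exhaustive_autocor_pvalue,
    lag1_autocorrelation,
    montecarlo_autocor_pvalue,
)

from conftest import make_matrix

# Brute-force-verified p for the strictly increasing 8-point series: 134 of
# the 40,320 orderings reach the observed lag-1 numerator (the sorted order
# does not maximize it — e.g. orderings pairing the extremes reach more).
LINEAR_P = 134 / 40320
OUTLIER = [20.0] + [320.0] * 7


def brute_force_pvalue(x):
    """Independent naive enumerator: per-permutation numerator in pure Python."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    c = [v - mean for v in x]
    denom = sum(v * v for v in c)
    obs = sum(c[i] * c[i + 1] for i in range(n - 1))
    tol = 1e-9 * denom
    count = 0
    for p in itertools.permutations(range(n)):
        num = sum(c[p[i]] * c[p[i + 1]] for i in range(n - 1))
        if num >= obs - tol:
            count += 1
    return count / math.factorial(n)


series = st.lists(
    st.floats(-100, 100, allow_nan=False, allow_infinity=False), min_size=3, max_size=8
)


class TestLag1Autocorrelation:
    def test_linear_series(self):
        assert lag1_autocorrelation(range(1, 9)) == pytest.approx(26.25 / 42)

    def test_alternating_series(self):
        assert lag1_autocorrelation([1, 2, 1, 2, 1, 2, 1, 2]) == pytest.approx(-1.75 / 2)

    def test_constant_series_is_undefined(self):
        assert math.isnan(lag1_autocorrelation([5.0] * 8))

    def test_too_short(self):
        with pytest.raises(ValueError, match="n >= 3"):
            lag1_autocorrelation([1, 2])

    @given(series, st.floats(0.1, 10), st.floats(-50, 50))
    def test_affine_and_reversal_invariance(self, x, a, b):
        r = lag1_autocorrelation(x)
        if math.isnan(r):
            return
        # skip series whose variance is lost to rounding once b is added
        spread = max(x) - min(x)
        if spread < 1e-9 * (1 + abs(b) + max(abs(v) for v in x)):
            return
        assert lag1_autocorrelation([a * v + b for v in x]) == pytest.approx(
            r, abs=1e-6
        )
        assert lag1_autocorrelation(x[::-1]) == pytest.approx(r, abs=1e-9)


class TestEnumeratePermutations:
    def test_eight_points_gives_40320(self):
        count, perms = enumerate_permutations(8)
        assert count == 40320
        seen = list(perms)
        assert len(seen) == 40320
        assert len(set(seen)) == 40320
        assert tuple(range(8)) in set(seen)

    def test_three_points(self):
        count, perms = enumerate_permutations(3)
        assert count == 6
        assert len(list(perms)) == 6

    def test_beyond_limit_directs_to_montecarlo(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            enumerate_permutations(11)


class TestExhaustive:
    def test_one_outlier_series(self):
        res = exhaustive_autocor_pvalue(OUTLIER)
        assert res.p_raw == 10080 / 40320 == 0.25
        assert res.n_permutations == 40320
        assert res.method == "exhaustive"

    def test_linear_series(self):
        res = exhaustive_autocor_pvalue(list(range(1, 9)))
        assert res.p_raw == LINEAR_P

    def test_constant_series_convention(self):
        res = exhaustive_autocor_pvalue([5.0] * 8)
        assert res.p_raw == 1.0
        assert math.isnan(res.r1)

    def test_p_is_multiple_of_min_and_at_least_min(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=7)
            res = exhaustive_autocor_pvalue(x)
            k = res.p_raw * math.factorial(7)
            assert k == pytest.approx(round(k))
            assert res.p_raw >= 1 / math.factorial(7)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_on_random_series(self, n):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = np.round(rng.normal(size=n) * 10, 2)
            assert exhaustive_autocor_pvalue(x).p_raw == brute_force_pvalue(x)

    def test_ties_match_brute_force(self):
        # repeated values make permutation numerators tie heavily
        for x in ([1, 1, 2, 2, 3], [0, 0, 0, 1, 1, 2], [5, 1, 1, 1, 1, 5]):
            assert exhaustive_autocor_pvalue(x).p_raw == brute_force_pvalue(x)

    @given(series)
    def test_one_sidedness_under_deviation_negation(self, x):
        """x -> 2*mean - x flips deviations but leaves r1 and p unchanged."""
        res = exhaustive_autocor_pvalue(x)
        mean = sum(x) / len(x)
        flipped = [2 * mean - v for v in x]
        assert exhaustive_autocor_pvalue(flipped).p_raw == res.p_raw


def test_estimator_convention_equivalence():
    """Any estimator monotone-equivalent over relabelings of the same
    multiset (e.g. the n-1-pairs normalization) yields identical
    permutation p-values: only the numerator ordering matters."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=6)
    c = x - x.mean()
    denom = float(c @ c)
    nums = []
    for p in itertools.permutations(range(6)):
        cp = c[list(p)]
        nums.append(float(cp[:-1] @ cp[1:]))
    obs = nums[0]
    p_biased = np.mean([(n / denom) >= (obs / denom) - 1e-12 for n in nums])
    p_npairs = np.mean(
        [(n / denom * 6 / 5) >= (obs / denom * 6 / 5) - 1e-12 for n in nums]
    )
    assert p_biased == p_npairs == exhaustive_autocor_pvalue(x).p_raw


class TestMonteCarlo:
    def test_deterministic_given_seed(self):
        x = list(range(1, 9))
        a = montecarlo_autocor_pvalue(x, B=1000, seed=3)
        b = montecarlo_autocor_pvalue(x, B=1000, seed=3)
        assert a.p_raw == b.p_raw
        assert a.method == "montecarlo"

    def test_agrees_with_exhaustive_within_3_se(self):
        x = list(range(1, 9))
        B = 100_000
        mc = montecarlo_autocor_pvalue(x, B=B, seed=1)
        se = math.sqrt(LINEAR_P * (1 - LINEAR_P) / B)
        assert abs(mc.p_raw - LINEAR_P) <= 3 * se + 1 / B

    def test_small_B_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            montecarlo_autocor_pvalue(range(8), B=10, seed=0)

    def test_constant_series(self):
        assert montecarlo_autocor_pvalue([3.0] * 8, B=100, seed=0).p_raw == 1.0


class TestScan:
    def _matrix(self):
        # scale factors of 1 keep the constant gene genuinely constant
        from hypoxtc.preprocess import NormalizedMatrix

        linear = [20, 40, 60, 80, 100, 120, 140, 160]
        const = [50.0] * 8
        m = make_matrix([linear, const], gene_ids=["lin", "const"])
        return NormalizedMatrix(
            m.gene_ids, m.samples, m.values, scale_factors=np.ones(8), floor=1.0
        )

    def test_per_gene_results_match_single_gene_path(self):
        results = {r.gene_id: r for r in autocor_scan(self._matrix())}
        norm = self._matrix()
        assert results["lin"].p_raw == exhaustive_autocor_pvalue(
            norm.gene_row("lin")
        ).p_raw
        assert results["const"].p_raw == 1.0

    def test_empty_gene_set(self):
        assert autocor_scan(self._matrix(), []) == []

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError, match="unknown"):
            autocor_scan(self._matrix(), ["nope"])

    def test_results_independent_of_gene_order(self):
        m = self._matrix()
        a = autocor_scan(m, ["const", "lin"])
        b = autocor_scan(m, ["lin", "const"])
        assert {r.gene_id: r.p_raw for r in a} == {r.gene_id: r.p_raw for r in b}
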