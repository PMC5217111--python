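"""AutoCor: exhaustive permutation test for time-dependence of a series.

The statistic is the lag-1 sample autocorrelation

    r1 = sum_{t=1}^{n-1} (x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2,

high when consecutive values persist, i.e. the series forms a smooth curve.
The observed series is compared against *all* n! orderings of its values
(40,320 for the 8-point hypoxia course) and the one-sided p-value is the
proportion of orderings whose autocorrelation is >= the observed one. The
identity ordering is in the enumeration, so the smallest attainable p is
1/n!. Because the value multiset — hence the mean and the denominator — is
permutation-invariant, only the numerator ordering matters; comparisons are
done on numerators with a small relative tolerance so ties at machine
precision count as >=.

For series longer than the exhaustive limit (n <= 10) a Monte-Carlo mode
samples B random orderings and applies the add-one correction
p = (1 + #{>= observed}) / (B + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from .preprocess import NormalizedMatrix

__all__ = [
    "AutocorResult",
    "EXHAUSTIVE_LIMIT",
    "lag1_autocorrelation",
    "enumerate_permutations",
    "exhaustive_autocor_pvalue",
    "montecarlo_autocor_pvalue",
    "autocor_scan",
]

EXHAUSTIVE_LIMIT = 10
# relative tolerance on the permutation-invariant denominator scale; ties at
# machine precision count as >=
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class AutocorResult:
    """Per-gene outcome of the permutation test."""

    gene_id: str | None
    r1: float  # nan when the series is constant (statistic undefined)
    p_raw: float
    n_permutations: int
    method: str  # "exhaustive" | "montecarlo"


def lag1_autocorrelation(x: Iterable[float]) -> float:
    """Lag-1 sample autocorrelation; nan for a constant series.

    Invariant under affine maps a*x + b (a > 0) and under reversal.
    """
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 values, got {x.size}")
    c = x - x.mean()
    denom = float(c @ c)
    if denom == 0.0:
        return float("nan")
    return float(c[:-1] @ c[1:]) / denom


def enumerate_permutations(n: int) -> tuple[int, Iterator[tuple[int, ...]]]:
    """(n!, iterator over all orderings of range(n)), identity included."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if n > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"n = {n} exceeds the exhaustive limit {EXHAUSTIVE_LIMIT} "
            f"({math.factorial(EXHAUSTIVE_LIMIT)} orderings); use Monte-Carlo mode"
        )
    return math.factorial(n), itertools.permutations(range(n))


@lru_cache(maxsize=4)
def _adjacency_matrix(n: int) -> sp.csr_matrix:
    """Sparse (n! x n(n-1)/2) matrix of adjacent-pair indicators.

    Row k flags the n-1 unordered index pairs adjacent in permutation k, so
    the permuted numerator for centered values c is the row-sum of pair
    products c_i * c_j — an exact regrouping of the direct sum, evaluated
    for all permutations and many genes as one sparse matmul.
    """
    total, perms = enumerate_permutations(n)
    p = np.fromiter(
        itertools.chain.from_iterable(perms), dtype=np.int8, count=total * n
    ).reshape(total, n)
    lo = np.minimum(p[:, :-1], p[:, 1:]).astype(np.int64)
    hi = np.maximum(p[:, :-1], p[:, 1:]).astype(np.int64)
    # canonical pair id for i<j among C(n,2) pairs
    pair_id = lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)
    rows = np.repeat(np.arange(total), n - 1)
    data = np.ones(pair_id.size, dtype=np.float64)
    return sp.csr_matrix(
        (data, (rows, pair_id.ravel())), shape=(total, n * (n - 1) // 2)
    )


def _pair_products(centered: np.ndarray) -> np.ndarray:
    """(G x C(n,2)) products c_i*c_j for i<j, matching _adjacency_matrix ids."""
    n = centered.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return centered[:, iu] * centered[:, ju]


def _exhaustive_counts(centered: np.ndarray) -> np.ndarray:
    """#{orderings with numerator >= observed} per gene (rows of centered)."""
    n = centered.shape[1]
    M = _adjacency_matrix(n)
    obs = (centered[:, :-1] * centered[:, 1:]).sum(axis=1)
    denom = (centered**2).sum(axis=1)
    tol = _TIE_RTOL * denom
    counts = np.empty(centered.shape[0], dtype=np.int64)
    chunk = max(1, int(2**25 // M.shape[0]))  # keep dense block ~256 MB max
    for start in range(0, centered.shape[0], chunk):
        block = centered[start : start + chunk]
        nums = M @ _pair_products(block).T  # (n!, chunk)
        counts[start : start + block.shape[0]] = (
            nums >= obs[start : start + block.shape[0]] - tol[start : start + block.shape[0]]
        ).sum(axis=0)
    return counts


def exhaustive_autocor_pvalue(
    x: Iterable[float], gene_id: str | None = None
) -> AutocorResult:
    """One-sided exhaustive permutation p-value for lag-1 autocorrelation.

    A constant series carries no evidence of time structure: p = 1 by
    convention, r1 = nan.
    """
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    total, _ = enumerate_permutations(x.size)
    c = x - x.mean()
    if float(c @ c) == 0.0:
        return AutocorResult(gene_id, float("nan"), 1.0, total, "exhaustive")
    count = int(_exhaustive_counts(c[None, :])[0])
    return AutocorResult(
        gene_id, lag1_autocorrelation(x), count / total, total, "exhaustive"
    )


def montecarlo_autocor_pvalue(
    x: Iterable[float], B: int, seed: int, gene_id: str | None = None
) -> AutocorResult:
    """Monte-Carlo permutation p-value with the add-one correction.

    p = (1 + #{sampled orderings >= observed}) / (B + 1); reproducible
    given the seed.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 values, got {x.size}")
    c = x - x.mean()
    denom = float(c @ c)
    if denom == 0.0:
        return AutocorResult(gene_id, float("nan"), 1.0, B, "montecarlo")
    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(x.size), (B, 1)), axis=1)
    permuted = c[idx]
    nums = (permuted[:, :-1] * permuted[:, 1:]).sum(axis=1)
    obs = float(c[:-1] @ c[1:])
    count = int((nums >= obs - _TIE_RTOL * denom).sum())
    return AutocorResult(
        gene_id, lag1_autocorrelation(x), (1 + count) / (B + 1), B, "montecarlo"
    )


def autocor_scan(
    matrix: NormalizedMatrix,
    genes: Iterable[str] | None = None,
    mode: str = "exhaustive",
    B: int = 100_000,
    seed: int = 0,
) -> list[AutocorResult]:
    """Run the permutation test on the normalized (floored) counts of many genes.

    The test uses the actual normalized count values in time order, making
    no distributional assumption. Results are independent of gene
    processing order; unknown gene ids raise.
    """
    gene_list = sorted(genes) if genes is not None else list(matrix.gene_ids)
    sub = matrix.subset(gene_list)
    if not gene_list:
        return []
    n = sub.n_samples
    if mode == "exhaustive":
        total, _ = enumerate_permutations(n)
        centered = sub.values - sub.values.mean(axis=1, keepdims=True)
        denom = (centered**2).sum(axis=1)
        counts = _exhaustive_counts(centered)
        results = []
        for g, row, d, cnt in zip(gene_list, sub.values, denom, counts):
            if d == 0.0:
                results.append(AutocorResult(g, float("nan"), 1.0, total, "exhaustive"))
            else:
                results.append(
                    AutocorResult(
                        g, lag1_autocorrelation(row), cnt / total, total, "exhaustive"
                    )
                )
        return results
    if mode == "montecarlo":
        return [
            montecarlo_autocor_pvalue(row, B=B, seed=seed + i, gene_id=g)
            for i, (g, row) in enumerate(zip(gene_list, sub.values))
        ]
    raise ValueError(f"unknown mode {mode!r}")
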