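"""Significance calling: BH adjustment, thresholds, and set arithmetic.

Raw p-values from each detector are adjusted by the Benjamini–Hochberg
step-up procedure *within* the fold-change-gated gene subset, one method at
a time; a gene is called significant when adjusted p <= alpha and its
maximum fold change is >= the gate. The two methods' call sets are then
combined by union, and overlap against any reference set is summarized as
a Venn partition together with the overlap expected if both sets were
random draws from the universe (|A|*|B|/N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneTestResult",
    "VennPartition",
    "bh_adjust",
    "build_results",
    "call_significant",
    "venn",
    "combine_methods",
]


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    method: str  # "autocor" | "nbtrend"
    p_raw: float
    p_adj: float
    max_fold_change: float
    significant: bool


@dataclass(frozen=True)
class VennPartition:
    only_a: int
    only_b: int
    both: int
    union: int
    expected_both: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def build_results(
    method: str,
    p_raw: Mapping[str, float],
    max_fc: Mapping[str, float],
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> list[GeneTestResult]:
    """Adjust one method's raw p-values over its gated subset and flag calls.

    ``p_raw`` should already be restricted to the fold-change-gated genes;
    BH is applied across exactly those genes.
    """
    genes = sorted(p_raw)
    missing = [g for g in genes if g not in max_fc]
    if missing:
        raise KeyError(f"genes missing a fold change: {missing[:10]}")
    adj = bh_adjust([p_raw[g] for g in genes])
    return [
        GeneTestResult(
            g,
            method,
            p_raw[g],
            float(a),
            max_fc[g],
            bool(a <= alpha and max_fc[g] >= min_fc),
        )
        for g, a in zip(genes, adj)
    ]


def call_significant(
    results: Sequence[GeneTestResult], alpha: float = 0.05, min_fc: float = 2.0
) -> set[str]:
    """Gene ids with adjusted p <= alpha (inclusive) and fold change >= min_fc.

    Mixing methods in one call is an error: BH must be applied within one
    method at a time.
    """
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError(f"results mix methods {sorted(methods)}; call per method")
    return {
        r.gene_id
        for r in results
        if r.p_adj <= alpha and r.max_fold_change >= min_fc
    }


def venn(set_a: Iterable[str], set_b: Iterable[str], universe_size: int) -> VennPartition:
    """Exact partition counts plus the expected overlap of random sets."""
    a, b = set(set_a), set(set_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError(
            f"universe_size {universe_size} smaller than a set ({len(a)}, {len(b)})"
        )
    both = len(a & b)
    return VennPartition(
        only_a=len(a) - both,
        only_b=len(b) - both,
        both=both,
        union=len(a | b),
        expected_both=len(a) * len(b) / universe_size,
    )


def combine_methods(autocor_set: Iterable[str], nbtrend_set: Iterable[str]) -> list[str]:
    """Union of the two methods' call sets, in deterministic sorted order."""
    return sorted(set(autocor_set) | set(nbtrend_set))
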