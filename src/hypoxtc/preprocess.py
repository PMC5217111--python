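"""Quality-control and normalization chain for the hypoxia count matrix.

The chain, in order: remove genes with zero reads in every sample, remove a
named gene family (the 24 seripauperin *PAU* genes, whose near-identical
sequences confound read assignment), total-count normalize so every sample
has the same number of reads mapping to annotated features, floor all
values below 20 at 20 (low counts are unreliable), then compute fold
changes. Flooring guarantees positivity, which fold changes require.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .counts_io import CountMatrix, SampleInfo

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "remove_zero_genes",
    "remove_gene_family",
    "total_count_normalize",
    "floor_values",
    "max_fold_change",
    "fold_change_filter",
    "log2_ratio_to_t0",
    "DEFAULT_FLOOR",
    "DEFAULT_MIN_FOLD_CHANGE",
]

DEFAULT_FLOOR = 20.0
DEFAULT_MIN_FOLD_CHANGE = 2.0


@dataclass
class NormalizedMatrix(CountMatrix):
    """A CountMatrix after total-count normalization.

    ``scale_factors[j]`` is the multiplier applied to sample j's raw
    counts; after normalization every column sums to the mean raw total.
    ``floor`` records the flooring threshold once applied (None before).
    """

    scale_factors: np.ndarray = field(default=None)  # type: ignore[assignment]
    floor: float | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.scale_factors is None:
            raise ValueError("NormalizedMatrix requires scale_factors")
        self.scale_factors = np.asarray(self.scale_factors, dtype=float)
        if self.scale_factors.shape != (self.n_samples,):
            raise ValueError("one scale factor per sample required")
        if np.any(self.scale_factors <= 0):
            raise ValueError("scale factors must be positive")
        if self.floor is not None and np.any(self.values < self.floor):
            raise ValueError("floor recorded but values below it present")

    def subset(self, genes: Sequence[str]) -> "NormalizedMatrix":
        sub = CountMatrix.subset(self, genes)
        return NormalizedMatrix(
            sub.gene_ids,
            sub.samples,
            sub.values,
            scale_factors=self.scale_factors.copy(),
            floor=self.floor,
        )


def remove_zero_genes(matrix: CountMatrix) -> tuple[CountMatrix, int]:
    """Drop genes with zero reads in all samples; return (matrix, n removed)."""
    keep = np.any(matrix.values > 0, axis=1)
    removed = int((~keep).sum())
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    out = CountMatrix(kept_ids, list(matrix.samples), matrix.values[keep])
    if removed:
        logger.info("removed %d all-zero genes", removed)
    return out, removed


def remove_gene_family(
    matrix: CountMatrix, ids_or_prefix: Iterable[str] | str
) -> tuple[CountMatrix, int]:
    """Remove an explicit id list, or all genes matching a name prefix.

    Requested ids that are absent trigger a warning, not an error, since
    identifier sets vary by annotation release.
    """
    if isinstance(ids_or_prefix, str):
        targets = {g for g in matrix.gene_ids if g.startswith(ids_or_prefix)}
    else:
        targets = set(ids_or_prefix)
        absent = targets.difference(matrix.gene_ids)
        if absent:
            warnings.warn(
                f"{len(absent)} requested gene ids not in matrix: "
                f"{sorted(absent)[:10]}",
                stacklevel=2,
            )
            targets -= absent
    keep = [g not in targets for g in matrix.gene_ids]
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    out = CountMatrix(kept_ids, list(matrix.samples), matrix.values[np.array(keep)])
    return out, len(targets)


def total_count_normalize(matrix: CountMatrix) -> NormalizedMatrix:
    """Rescale each sample so all column totals equal the mean raw total.

    Sample j is multiplied by mean(totals)/totals[j]; the mean target keeps
    values on the raw-count scale (any common target gives identical fold
    changes).
    """
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        bad = [s.sample_id for s, t in zip(matrix.samples, totals) if t <= 0]
        raise ValueError(f"samples with zero total counts: {bad}")
    factors = totals.mean() / totals
    return NormalizedMatrix(
        list(matrix.gene_ids),
        list(matrix.samples),
        matrix.values * factors,
        scale_factors=factors,
    )


def floor_values(matrix: NormalizedMatrix, floor: float = DEFAULT_FLOOR) -> NormalizedMatrix:
    """Set every value below ``floor`` to ``floor`` (elementwise max)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return NormalizedMatrix(
        list(matrix.gene_ids),
        list(matrix.samples),
        np.maximum(matrix.values, floor),
        scale_factors=matrix.scale_factors.copy(),
        floor=floor,
    )


def max_fold_change(gene_values: np.ndarray) -> float:
    """max/min over the whole time course; requires positive values."""
    x = np.asarray(gene_values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fold change requires positive values (apply flooring first)")
    return float(x.max() / x.min())


def fold_change_filter(
    matrix: NormalizedMatrix, min_fc: float = DEFAULT_MIN_FOLD_CHANGE
) -> set[str]:
    """Genes whose maximum fold change over the course is >= min_fc (inclusive)."""
    if matrix.floor is None:
        raise ValueError("fold_change_filter expects a floored matrix")
    fc = matrix.values.max(axis=1) / matrix.values.min(axis=1)
    return {g for g, f in zip(matrix.gene_ids, fc) if f >= min_fc}


def log2_ratio_to_t0(matrix: NormalizedMatrix) -> np.ndarray:
    """log2(value_t / value_0) per gene; the t=0 column is identically 0."""
    if matrix.floor is None:
        raise ValueError("log2 ratios expect a floored (positive) matrix")
    if matrix.samples[0].time_minutes != 0:
        raise ValueError(
            f"first sample must be at time 0, got {matrix.samples[0].time_minutes}"
        )
    return np.log2(matrix.values / matrix.values[:, [0]])
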