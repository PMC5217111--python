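"""Environmental stress response (ESR) membership and overlap.

The ESR is the set of ~900 yeast genes that respond in common to diverse
stressors. Membership here follows the published rule: a gene belongs if
it was originally called by the source microarray study, or if its
log2 response exceeds 1 in magnitude (strictly more than twofold) in at
least 10 of the 13 stress treatments. Missing treatment measurements count
as unchanged — a conservative bias against membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calling import VennPartition, venn

__all__ = ["EsrInput", "classify_esr", "overlap_with_esr", "read_esr_table"]

MAX_TREATMENTS = 13


@dataclass(frozen=True)
class EsrInput:
    """One gene's evidence: the original call plus up to 13 log2 responses."""

    gene_id: str
    original_call: bool
    log2_responses: tuple[float | None, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.log2_responses) > MAX_TREATMENTS:
            raise ValueError(
                f"{self.gene_id}: {len(self.log2_responses)} treatments supplied, "
                f"maximum is {MAX_TREATMENTS}"
            )
        for v in self.log2_responses:
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{self.gene_id}: non-finite response {v}")

    @property
    def n_changed(self) -> int:
        return sum(1 for v in self.log2_responses if v is not None and abs(v) > 1.0)


def classify_esr(inputs: Iterable[EsrInput], min_changed: int = 10) -> set[str]:
    """Genes in the ESR: original call OR |log2| > 1 in >= min_changed treatments."""
    return {
        g.gene_id for g in inputs if g.original_call or g.n_changed >= min_changed
    }


def overlap_with_esr(
    oxygen_set: Iterable[str], esr_set: Iterable[str], universe_size: int
) -> VennPartition:
    """Venn partition of the oxygen-regulated set against the ESR.

    The oxygen set must be pre-restricted to genes examined by the ESR
    study (the shared universe); counts and the random-expectation overlap
    |A|*|B|/N follow from that universe.
    """
    return venn(oxygen_set, esr_set, universe_size)


def read_esr_table(path: str | Path) -> list[EsrInput]:
    """Read a TSV: gene_id, original_call (0/1), then <= 13 log2 columns.

    Empty cells are missing measurements.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "original_call":
        raise ValueError(
            f"{path}: first two columns must be gene_id, original_call"
        )
    response_cols = list(df.columns[2:])
    if len(response_cols) > MAX_TREATMENTS:
        raise ValueError(f"{path}: more than {MAX_TREATMENTS} treatment columns")
    out = []
    for row in df.itertuples(index=False):
        responses = tuple(
            None if pd.isna(v) else float(v) for v in row[2:]
        )
        out.append(EsrInput(str(row[0]), bool(int(row[1])), responses))
    return out
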