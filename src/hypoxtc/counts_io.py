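"""Reading, writing and assembly of gene-count matrices.

The deposited data format is the HTSeq two-column count file: one feature
per line as ``identifier<TAB>integer``, with trailing summary rows whose
identifiers start with ``__`` (``__no_feature``, ``__ambiguous``, ...).
Sample time metadata is not part of that format, so it travels in a
sidecar sample sheet (TSV with columns ``sample_id``, ``time_minutes``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "read_htseq_counts",
    "assemble_count_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
]


@dataclass(frozen=True)
class SampleInfo:
    """A single sequenced sample: a label and its time point in minutes."""

    sample_id: str
    time_minutes: float

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if not np.isfinite(self.time_minutes) or self.time_minutes < 0:
            raise ValueError(
                f"time_minutes must be finite and nonnegative, got {self.time_minutes}"
            )


@dataclass
class CountMatrix:
    """Genes x time-ordered samples of nonnegative counts.

    The pipeline's universal currency: every stage consumes or produces one.
    Gene order is deterministic (callers assemble lexicographically) and
    samples are sorted by strictly increasing time.
    """

    gene_ids: list[str]
    samples: list[SampleInfo]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        times = [s.time_minutes for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"sample times must be strictly increasing, got {times}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("count values must be finite and nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_minutes for s in self.samples], dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[s.sample_id for s in self.samples],
        )

    def subset(self, genes: Sequence[str]) -> "CountMatrix":
        """Row-subset in the given gene order; unknown ids raise."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:10]}")
        rows = [index[g] for g in genes]
        return CountMatrix(list(genes), list(self.samples), self.values[rows])


def read_htseq_counts(path: str | Path) -> dict[str, int]:
    """Parse one HTSeq count file into a gene_id -> count mapping.

    ``__``-prefixed summary rows (no-feature, ambiguous, ...) are not
    annotated features; they are dropped from the mapping but their values
    are logged for auditability.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    summaries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'identifier<TAB>integer', got {line!r}"
                )
            ident, raw = parts
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: count {raw!r} is not an integer"
                ) from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            if ident.startswith("__"):
                summaries[ident] = value
                continue
            if ident in counts:
                raise ValueError(f"{path}:{lineno}: duplicate feature {ident!r}")
            counts[ident] = value
    if summaries:
        logger.info("%s: dropped summary rows %s", path, summaries)
    return counts


def assemble_count_matrix(
    per_sample: Sequence[tuple[SampleInfo, Mapping[str, int]]],
) -> CountMatrix:
    """Build a time-ordered CountMatrix from per-sample count mappings.

    All samples must share an identical gene universe; output gene order is
    lexicographic and column order follows time, regardless of input order.
    """
    if len(per_sample) < 2:
        raise ValueError("need at least 2 samples")
    times = [info.time_minutes for info, _ in per_sample]
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate time_minutes among samples: {sorted(times)}")

    universe = set(per_sample[0][1])
    for info, mapping in per_sample[1:]:
        if set(mapping) != universe:
            diff = sorted(universe.symmetric_difference(mapping))
            raise ValueError(
                f"sample {info.sample_id!r}: gene universe mismatch; "
                f"symmetric difference {diff[:20]}"
            )

    ordered = sorted(per_sample, key=lambda pair: pair[0].time_minutes)
    gene_ids = sorted(universe)
    values = np.array(
        [[mapping[g] for _, mapping in ordered] for g in gene_ids], dtype=float
    )
    return CountMatrix(gene_ids, [info for info, _ in ordered], values)


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "time_minutes": [s.time_minutes for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_minutes"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet {path} must have columns {sorted(required)}")
    return [
        SampleInfo(str(row.sample_id), float(row.time_minutes))
        for row in df.itertuples()
    ]


def write_matrix_tsv(
    matrix: CountMatrix, path: str | Path, samples_path: str | Path | None = None
) -> None:
    """Write a gene x sample TSV plus (optionally) the sidecar sample sheet.

    Floats are written at full precision so write->read is the identity.
    """
    matrix.to_frame().to_csv(path, sep="\t")
    if samples_path is not None:
        write_sample_sheet(matrix.samples, samples_path)


def read_matrix_tsv(path: str | Path, samples_path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values in matrix")
    samples = read_sample_sheet(samples_path)
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in df.columns if c not in by_id]
    if missing or len(df.columns) != len(samples):
        raise ValueError(
            f"{path}: matrix columns {list(df.columns)} do not match sample sheet "
            f"ids {sorted(by_id)}"
        )
    ordered = sorted(samples, key=lambda s: s.time_minutes)
    values = df[[s.sample_id for s in ordered]].to_numpy(dtype=float)
    return CountMatrix(list(df.index.astype(str)), ordered, values)
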