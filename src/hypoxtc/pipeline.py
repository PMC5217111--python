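"""End-to-end orchestration: preprocess -> both detectors -> BH calling ->
global structure -> optional ESR comparison, with a manifest that records
every decision flag so published-number comparisons are auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autocor import autocor_scan
from .calling import build_results, call_significant, combine_methods, venn
from .counts_io import (
    CountMatrix,
    read_htseq_counts,
    read_matrix_tsv,
    write_matrix_tsv,
)
from .esr import classify_esr, overlap_with_esr, read_esr_table
from .nbtrend import nb_trend_scan
from .preprocess import (
    DEFAULT_FLOOR,
    DEFAULT_MIN_FOLD_CHANGE,
    floor_values,
    fold_change_filter,
    log2_ratio_to_t0,
    remove_gene_family,
    remove_zero_genes,
    total_count_normalize,
)
from .structure import average_linkage_cluster, euclidean_distance_matrix, pca_timepoints

__all__ = ["PipelineConfig", "run_pipeline", "load_geo_counts"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults mirror the study's stated values."""

    counts: str | None = None  # matrix TSV
    samples: str | None = None  # sample sheet TSV
    geo_counts: str | None = None  # directory of per-sample HTSeq files
    out_dir: str = "results"
    floor: float = DEFAULT_FLOOR
    min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE
    alpha: float = 0.05
    autocor_mode: str = "exhaustive"
    autocor_B: int = 100_000
    seed: int = 0
    universe_size: int | None = None  # default: post-preprocessing gene count
    pca_convention: str = "log2_ratio"  # or "log2_counts"
    family_ids: str | None = None  # one gene id per line (e.g. the PAU family)
    esr_table: str | None = None
    esr_universe_size: int | None = None
    cluster_calls: bool = True
    max_cluster_genes: int = 2000

    def __post_init__(self) -> None:
        if self.pca_convention not in ("log2_ratio", "log2_counts"):
            raise ValueError(f"unknown pca_convention {self.pca_convention!r}")


def load_geo_counts(directory: str | Path, samples_path: str | Path) -> CountMatrix:
    """Assemble a matrix from a local directory of per-sample HTSeq files.

    The sample sheet needs columns sample_id, time_minutes and optionally
    ``file`` (relative filename; default ``<sample_id>.txt``).
    """
    from .counts_io import SampleInfo, assemble_count_matrix

    directory = Path(directory)
    df = pd.read_csv(samples_path, sep="\t")
    per_sample = []
    for row in df.to_dict("records"):
        fname = row.get("file") or f"{row['sample_id']}.txt"
        mapping = read_htseq_counts(directory / fname)
        per_sample.append(
            (SampleInfo(str(row["sample_id"]), float(row["time_minutes"])), mapping)
        )
    return assemble_count_matrix(per_sample)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes the report bundle and returns a summary.

    Two runs with identical config and seed produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.geo_counts:
        if not config.samples:
            raise ValueError("geo_counts requires a sample sheet")
        raw = load_geo_counts(config.geo_counts, config.samples)
    elif config.counts and config.samples:
        raw = read_matrix_tsv(config.counts, config.samples)
    else:
        raise ValueError("provide counts+samples or geo_counts+samples")

    raw, n_zero_removed = remove_zero_genes(raw)
    n_family_removed = 0
    if config.family_ids:
        ids = [
            line.strip()
            for line in Path(config.family_ids).read_text().splitlines()
            if line.strip()
        ]
        raw, n_family_removed = remove_gene_family(raw, ids)

    normalized = total_count_normalize(raw)
    floored = floor_values(normalized, config.floor)
    gated = sorted(fold_change_filter(floored, config.min_fold_change))
    write_matrix_tsv(floored, out / "normalized_floored.tsv", out / "samples.tsv")

    fc = {
        g: float(row.max() / row.min())
        for g, row in zip(floored.gene_ids, floored.values)
    }

    ac_results = autocor_scan(
        floored, gated, mode=config.autocor_mode, B=config.autocor_B, seed=config.seed
    )
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "r1": r.r1,
                "p_raw": r.p_raw,
                "n_permutations": r.n_permutations,
                "method": r.method,
            }
            for r in ac_results
        ]
    ).to_csv(out / "autocor.tsv", sep="\t", index=False)

    nb_results = nb_trend_scan(raw, normalized.scale_factors, gated)
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "lrt_stat": r.lrt_stat,
                "df": r.df,
                "p_raw": r.p_raw,
                "alpha": r.alpha,
                "converged": r.converged,
            }
            for r in nb_results
        ]
    ).to_csv(out / "nbtrend.tsv", sep="\t", index=False)

    calls = {}
    for method, praw in (
        ("autocor", {r.gene_id: r.p_raw for r in ac_results}),
        ("nbtrend", {r.gene_id: r.p_raw for r in nb_results}),
    ):
        results = build_results(
            method, praw, fc, alpha=config.alpha, min_fc=config.min_fold_change
        )
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "max_fc": r.max_fold_change,
                    "significant": r.significant,
                }
                for r in results
            ]
        ).to_csv(out / f"calls_{method}.tsv", sep="\t", index=False)
        calls[method] = call_significant(
            results, alpha=config.alpha, min_fc=config.min_fold_change
        )

    universe = config.universe_size or floored.n_genes
    partition = venn(calls["autocor"], calls["nbtrend"], universe)
    combined = combine_methods(calls["autocor"], calls["nbtrend"])
    (out / "combined_calls.txt").write_text("\n".join(combined) + "\n" if combined else "")
    venn_summary = {
        "only_autocor": partition.only_a,
        "only_nbtrend": partition.only_b,
        "both": partition.both,
        "union": partition.union,
        "expected_both": partition.expected_both,
        "universe_size": universe,
    }
    (out / "venn.json").write_text(json.dumps(venn_summary, indent=2) + "\n")

    log2_ratios = log2_ratio_to_t0(floored)
    pca_input = (
        log2_ratios.T if config.pca_convention == "log2_ratio" else np.log2(floored.values).T
    )
    pca = pca_timepoints(pca_input)
    sample_ids = [s.sample_id for s in floored.samples]
    pd.DataFrame(
        pca.scores,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    ).to_csv(out / "pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(pca.variance_fraction.size)],
         "variance_fraction": pca.variance_fraction}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)

    dist = euclidean_distance_matrix(pca_input)
    pd.DataFrame(dist, index=sample_ids, columns=sample_ids).to_csv(
        out / "distances.tsv", sep="\t"
    )

    summary: dict = {
        "n_genes_input": raw.n_genes + n_zero_removed + n_family_removed,
        "n_zero_removed": n_zero_removed,
        "n_family_removed": n_family_removed,
        "n_genes_analyzed": floored.n_genes,
        "n_fold_change_gated": len(gated),
        "n_autocor_calls": len(calls["autocor"]),
        "n_nbtrend_calls": len(calls["nbtrend"]),
        "n_combined_calls": len(combined),
        "venn": venn_summary,
        "pca_variance_fraction": [float(v) for v in pca.variance_fraction],
    }

    if config.cluster_calls and len(combined) >= 2:
        cluster_genes = combined[: config.max_cluster_genes]
        idx = [floored.gene_ids.index(g) for g in cluster_genes]
        dend = average_linkage_cluster(log2_ratios[idx], cluster_genes)
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        summary["n_clustered_genes"] = len(cluster_genes)

    if config.esr_table:
        esr_inputs = read_esr_table(config.esr_table)
        esr_set = classify_esr(esr_inputs)
        esr_universe = {e.gene_id for e in esr_inputs}
        restricted = [g for g in combined if g in esr_universe]
        n_univ = config.esr_universe_size or len(esr_universe)
        esr_part = overlap_with_esr(restricted, esr_set, n_univ)
        summary["esr"] = {
            "n_oxygen_in_esr_universe": len(restricted),
            "n_esr_genes": len(esr_set),
            "observed_overlap": esr_part.both,
            "expected_overlap": esr_part.expected_both,
            "universe_size": n_univ,
        }

    config_record = asdict(config)
    config_record.pop("out_dir")  # bundle location, not an analysis parameter
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_record,
        "decisions": {
            "preprocessing_order": "zero-removal, family-removal, normalize, floor, fold-change",
            "normalization_target": "mean of sample totals",
            "floor_applied_to": "normalized counts",
            "fold_change": "max/min over all time points",
            "autocor_identity_included": True,
            "autocor_tie_rule": "numerator comparison, relative tolerance 1e-9",
            "bh_within": "fold-change-gated subset, per method",
            "dispersion": "pooled method-of-moments with a0 + a1/mu trend",
            "pca_convention": config.pca_convention,
            "pca_centering": "per-gene mean, no scaling",
            "upgma_metric": "1 - uncentered correlation",
        },
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary
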