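# hypoxtc

Time-course analysis of the yeast hypoxic transcriptome.

When *Saccharomyces cerevisiae* is switched from aerobic growth to hypoxia,
hundreds of genes change expression — some by more than 500-fold — over the
first four hours. A typical experimental design samples one RNA-seq library
at each of 8 time points (0, 5, 10, 30, 60, 120, 180, 240 min) with **no
replicates**, which rules out ordinary per-time-point differential
expression testing. `hypoxtc` implements the analysis pipeline for exactly
this situation:

* **AutoCor** — an exhaustive permutation test for time-dependence. For a
  gene's series x₁…x₈ of normalized counts, the lag-1 sample
  autocorrelation

  r₁ = Σₜ(xₜ − x̄)(xₜ₊₁ − x̄) / Σₜ(xₜ − x̄)²

  is high when consecutive values persist (the series forms a smooth
  curve). The observed r₁ is compared against **all 8! = 40,320**
  reorderings of the same values, and the one-sided p-value is the
  proportion of orderings with r₁ at least as large. No distributional
  assumption is made; the smallest attainable p is 1/40,320.

* **NB trend LRT** — a likelihood-ratio test comparing a quadratic
  negative-binomial count model E[Yₜ] = exp(β₀ + β₁t + β₂t²) against the
  intercept-only model, with 2Δℓ referred to χ²₂. Dispersion α (variance
  μ + αμ²) is estimated by pooling all time points as pseudo-replicates and
  borrowing strength across genes through a mean–dispersion trend
  α(μ) = a₀ + a₁/μ.

* The surrounding machinery: HTSeq count-file I/O, total-count
  normalization, flooring at 20 counts, a ≥2-fold maximum-fold-change gate,
  Benjamini–Hochberg adjustment at FDR 0.05, Venn/overlap arithmetic with
  random-expectation baselines, Q-mode PCA over time points, Euclidean
  sample distances, UPGMA gene clustering with uncentered correlation,
  environmental stress response (ESR) membership classification — and a
  synthetic negative-binomial count generator with per-gene ground truth,
  so that power, false-discovery proportion and calibration of every stage
  can be measured without any data download.

The two detectors are complementary: AutoCor is nearly blind to genes that
jump at a single time point and then stay put (only one value breaks the
smoothness), while the quadratic LRT and the fold-change gate still catch
them; conversely AutoCor picks up smooth trends that a pooled-dispersion
count model, its dispersion inflated by the trend itself, can miss.

## Worked example

```python
from hypoxtc.autocor import exhaustive_autocor_pvalue

x = [20, 35, 60, 110, 180, 240, 260, 255]   # a smooth ~13-fold rise
res = exhaustive_autocor_pvalue(x)
print(res.r1, res.p_raw)
```

prints `0.7212543554006968 0.001140873015873016`: the series' lag-1
autocorrelation is 0.721, and only 46 of the 40,320 orderings of those
eight values do as well or better, so p = 46/40320 ≈ 0.00114 — strong
evidence the ordering is not exchangeable, i.e. the gene tracks time.

The full pipeline on a simulated course (2,000 genes, 8 time points):

```python
from hypoxtc.counts_io import write_matrix_tsv
from hypoxtc.pipeline import PipelineConfig, run_pipeline
from hypoxtc.simulate import default_scenario

matrix, truths = default_scenario(seed=1, n_genes=2000)
write_matrix_tsv(matrix, "counts.tsv", "samples.tsv")
summary = run_pipeline(PipelineConfig(
    counts="counts.tsv", samples="samples.tsv", out_dir="out", seed=1))
```

The returned summary (also written to `out/manifest.json`, alongside
per-method result tables, the combined call list, PCA/distance tables and
a Newick dendrogram) reads:

```
n_fold_change_gated: 544      # genes with max/min >= 2 after flooring
n_autocor_calls:     131      # BH <= 0.05 within the gated subset
n_nbtrend_calls:     141
n_combined_calls:    181      # union: the "oxygen-regulated" set
venn.both:           91       # vs 9.2 expected for random sets
pca_variance_fraction: [0.68, 0.14, ...]
```

The detectors agree on 91 genes where ~9 would be expected by chance, and
the first two principal components carry ~82% of the variance of the log2
trajectories — the time course is dominated by one large, smooth
transition, with most movement early and a plateau after ~120 min.

The same steps are available as subcommands of the `hypoxtc` console
script (`simulate`, `preprocess`, `autocor`, `nbtrend`, `call`, `pca`,
`dist`, `cluster`, `esr-compare`, `run`); `run --geo-counts <dir>` accepts
a directory of per-sample two-column HTSeq count files for users who have
downloaded a deposited data set.

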