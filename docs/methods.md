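# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would need
to know.

## The setting

A single hypoxia time course: one RNA-seq library at each of 8 time points
(0, 5, 10, 30, 60, 120, 180, 240 min), no biological replicates. Counts
per annotated feature arrive in the two-column HTSeq format. Without
replicates there is no within-condition variance estimate, so both
detectors lean on structure *across* time points.

## Preprocessing

The chain is: remove genes with zero reads in every sample → remove a
named gene family (typically the 24 seripauperin *PAU* genes, whose
near-identical sequences make read assignment unreliable; the family is
supplied as an explicit id list because identifiers vary by annotation
release) → total-count normalization → floor at 20 → fold changes.

*Total-count normalization* multiplies sample *j* by
mean(totals)/totals\_j, so every column sums to the mean raw total. The
mean target keeps values on the raw-count scale; any common target yields
identical fold changes. This estimator assumes the transcriptome
composition is roughly conserved — a strongly asymmetric global shift
would leak into every gene's apparent trajectory (see the generator notes
below).

*Flooring* replaces every normalized value below 20 with 20. Counts below
~20 are dominated by sampling noise; flooring suppresses spurious fold
changes from that regime and guarantees positivity for ratios and logs.
The floor is applied to *normalized* counts: flooring raw counts and then
rescaling would produce sample-dependent effective floors. The order is
recorded in the run manifest so the alternative can be diagnosed by
rerunning.

*Maximum fold change* is max/min across all 8 time points — not relative
to t = 0 — so a transient excursion counts fully. The gate is ≥ 2,
inclusive. The ratio-to-baseline view is exposed separately as
log2(value\_t/value\_0).

## AutoCor: exhaustive permutation test on lag-1 autocorrelation

Statistic: r₁ = Σₜ₌₁ⁿ⁻¹ (xₜ−x̄)(xₜ₊₁−x̄) / Σₜ(xₜ−x̄)², the textbook
biased-denominator sample autocorrelation. The test compares the observed
series against all n! orderings of its values; p is the proportion with
r₁ ≥ observed (one-sided: only *high* autocorrelation — smoothness — is
evidence).

Numerical decisions:

* The value multiset, hence the mean and the denominator, is invariant
  under permutation, so only the numerator ordering matters. Any statistic
  monotone-equivalent under relabelings of the same multiset (e.g. the
  (n−1)-pairs normalization) yields identical p-values; this equivalence
  is a property test.
* Comparisons are made on numerators with a relative tolerance of 1e-9 on
  the denominator scale, so ties at machine precision count as ≥. This
  removes float-ordering fragility for series with repeated values
  (common after flooring).
* The identity ordering is included in numerator and denominator, so
  p ≥ 1/n! and the test is exact (never anti-conservative) under
  exchangeability.
* A constant series carries no ordering information: p = 1, r₁ undefined
  (NaN).
* Exhaustive mode is limited to n ≤ 10 (10! ≈ 3.6M orderings); longer
  series use Monte-Carlo with the add-one correction
  p = (1 + #{≥ observed})/(B+1), B ≥ 100, seeded.

Implementation: for each permutation the numerator is the sum of the n−1
adjacent pair products, so over all permutations it equals a sparse 0/1
matrix (n! × C(n,2) adjacency indicators, cached per n) times the vector
of pairwise products of centered values. One sparse matmul evaluates all
40,320 numerators for a block of genes at once; a 10,000-gene scan takes
seconds. This is an exact regrouping of the direct sum; tests verify
bit-identical p-values against a naive per-permutation enumerator.

A caution discovered while freezing oracle values: intuition about which
orderings maximize r₁ is unreliable. For the strictly linear series
1..8 the sorted order is *not* the argmax of the lag-1 numerator — 134 of
the 40,320 orderings do at least as well (p ≈ 3.3e-3, brute-force
verified), because orderings that pair extreme values adjacently can beat
the monotone arrangement.

## Negative-binomial trend test

Full model: log μₜ = β₀ + β₁s + β₂s² with s = t/t\_max (rescaling is pure
conditioning; the LRT is invariant to it). Reduced model: intercept only.
Statistic 2(ℓ\_full − ℓ\_reduced) against χ²₂.

Counts are modelled on the raw scale with offsets −log(scale factor) from
total-count normalization, so one normalization scheme governs the whole
pipeline; exp(x'β) is the normalized-scale expectation.

*Dispersion.* With no replicates, each gene's α is estimated by pooling
all time points: α̂ = max(0, (s² − m̄)/m̄²) from the pooled mean and
variance. Across genes, a trend α(μ) = a₀ + a₁/μ is fitted by least
squares of α̂ against 1/μ over genes with α̂ > 0 (falling back to the
median positive α̂, or 1e-8, when fewer than 20 genes qualify), clamped at
α ≥ 1e-8, and each gene's working dispersion is the trend value at its
mean — the "genes expressed at similar levels" idea with no
empirical-Bayes shrinkage or Cox–Reid adjustment. This is a deliberate,
documented simplification: the no-replicate pooled design already departs
from what shrinkage machinery assumes, and pooling has a known cost that
the test suite reproduces — genuinely trended genes receive inflated α̂
(their trend masquerades as dispersion), which depresses their LRT power.
Consequently the package does not claim numerical agreement with any
specific published count-model tool's gene lists; those comparisons are
diagnostics, not contracts.

*Fitting.* Fisher-scoring IRLS with log link and fixed α, vectorized
across genes sharing one design: per iteration the weighted normal
equations (weights μ/(1+αμ)) are solved as a batched 3×3 (or 1×1) system.
Convergence at max|Δβ| < 1e-8 or 100 iterations; the linear predictor is
clipped to [log(1e-8), 40] so degenerate genes (e.g. all-zero rows, whose
intercept diverges to −∞) stay finite and are flagged non-converged.
Tests check the intercept-model closed form (β̂₀ = log ȳ − o for equal
offsets, any α) and agreement with statsmodels GLM fits (Poisson and NB)
to 1e-5.

Under the null with the true α supplied, the empirical size at nominal
0.05 over 10,000 simulated null genes is ≈ 0.05 (the acceptance suite
asserts [0.03, 0.07]); χ²₂ asymptotics are adequate at n = 8 for this
design.

## Calling and set arithmetic

Benjamini–Hochberg step-up adjustment (adjᵢ = min over j ≥ i of
p₍ⱼ₎·m/j, capped at 1) is applied *within* the fold-change-gated subset,
separately per method — exhaustive permutation p-values are discrete with
minimum 1/40,320 and are adjusted as-is, with no mid-p or discreteness
correction. A gene is significant when adjusted p ≤ 0.05 (inclusive) and
max fold change ≥ 2. The two methods' calls combine by union. Overlap
against any reference set is reported as a Venn partition plus the
expected overlap |A|·|B|/N of random sets from an N-gene universe; N has
no default and must be supplied explicitly, because published expectation
figures depend on it.

## Global structure

* **PCA** is Q-mode: SVD of the time points × genes matrix with each gene
  column mean-centered, no variance scaling. Scores place time points in
  component space; variance fractions come from squared singular values.
  Two input conventions exist in practice — log2 normalized counts and
  log2 ratios to t = 0 — so the convention is an explicit parameter,
  defaulting to log2 ratios (the view that isolates movement over the
  course). Component signs are arbitrary; all tests are sign-invariant.
* **Distances** between time points are plain Euclidean over genes.
* **Gene clustering** is UPGMA (average linkage) on 1 − uncentered
  correlation, s = Σxy/√(Σx²Σy²). The linkage is computed by scipy's
  nearest-neighbor-chain algorithm, which is deterministic; exact-tie
  merge order follows scipy rather than a documented lexicographic rule,
  which matters only for exactly tied distances (measure-zero for
  continuous profiles). Tests validate heights against a brute-force
  UPGMA oracle on tie-free instances. Dendrograms are written as Newick
  with branch lengths equal to height differences.

## ESR membership

A gene belongs to the environmental stress response if it was originally
called by the source microarray study **or** its |log2 response| exceeds 1
(strictly more than twofold) in ≥ 10 of the 13 stress treatments. Missing
measurements count as unchanged — a conservative bias against membership.
The treatments × genes table is an external input; the generator can
fabricate structurally identical tables for testing.

## Synthetic data

The generator produces what the analysis assumes: negative-binomial counts
(variance μ + αμ², α = 0 degenerating to Poisson) over known mean
trajectories, one replicate per time point, at the study's 8 time points.

Trajectory classes, defined on the log-mean scale so the nominal fold is
exact at the plateau or peak:

| class | form | emulates |
|---|---|---|
| flat | μ₀ | null genes |
| smooth | μ₀·fold^(1/(1+e^(−k(t−t₅₀)))) | transition to a new steady state |
| transient | μ₀·fold^(exp(−(t−t_peak)²/2w²)) | ESR-like pulse peaking near 30 min |
| step | μ₀ then μ₀·fold from t_step | abrupt persistent induction |

Default scenario (~6,000 genes): 80% flat, 10% smooth (fold log-uniform
2–550, both directions, t₅₀ ∈ [10, 120] min, steepness k ∈ [0.03, 0.15]
/min so transitions complete within the course), 5% transient (peak at
30 min, fold 2–16, width ∈ [10, 20] min so the pulse relaxes by ~120 min),
5% step (jump at 5 min, fold 2–52). Each gene's *expressed level* — the
maximum of its mean trajectory — is log-uniform over 10–10,000 counts,
the dynamic range of floored normalized counts in the motivating data
set; up-regulated genes therefore start at level/fold. Sampling the
*baseline* and fold independently instead would create genes with plateau
means in the millions, whose rise dominates the column totals and breaks
total-count normalization for every other gene — a composition artifact,
not a property of the data the pipeline targets. With level-anchored
sampling the residual composition drift of totals is 1–2%. Dispersion
follows α(μ) = 0.01 + 2/μ at the gene's time-averaged mean; per-sample
depth factors are uniform in [0.8, 1.25] (what normalization is supposed
to remove).

What the generator does **not** emulate: GC/length bias, batch effects,
read-level noise, correlated gene programs, asymmetric global shifts of
transcriptome composition, and annotation artifacts such as multi-mapping
gene families. Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated model, not robustness to
those real-data complications.

Problem sizes used by the test and acceptance suites — 10,000 null genes
for calibration, the 6,000-gene scenario for sensitivity/FDP, 1,000
random vectors for the BH oracle — are chosen to make binomial error
small relative to the asserted margins while the whole suite stays
desk-scale (seconds to a couple of minutes).

## Known limitations

* Pooled-dispersion conservatism for strongly trended genes (above).
* AutoCor's step-gene blind spot is inherent to a smoothness statistic;
  the package reproduces it quantitatively on synthetic data and relies
  on the LRT and the fold-change gate to cover that class.
* Total-count normalization assumes composition balance; medians-of-ratios
  or TMM style estimators are out of scope.
* Exhaustive mode is capped at 10 time points; beyond that only the
  seeded Monte-Carlo path is available.
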