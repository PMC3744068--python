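# Methods

## Statistical model

### Prior from study-level effects

For each gene the meta-analysis effect table carries one row per study:
a log2-ratio mean, its standard error, and a detection ("presence")
p-value.  Only studies with presence p < 0.1 contribute (the default
`presence_alpha`).  The prior for the gene's true log2 effect θ is
normal with

* θ₀ = arithmetic mean of the qualifying studies' log2-ratio means,
* σ₀ = their sample standard deviation (n−1 denominator — unbiased at
  the small study counts typical here).

Genes with fewer than two qualifying studies carry no usable spread and
are excluded with a report entry rather than an error.  So are genes
whose qualifying means are all identical: σ₀ = 0 means infinite prior
precision and a degenerate posterior, so the exclusion keeps the
formulas intact instead of special-casing a division by zero.

### Surrogate meta-analysis score

The meta-analysis candidate score used upstream of the Bayesian step is
a Stouffer combination over qualifying studies,
score = |Σ_s z_s|/√S with z_s = mean_s/se_s.  It is deliberately a
*surrogate*: it ranks genes by the coherence of their study-level
evidence on a z-like scale and is swappable — precomputed scores can be
supplied through an input column, and the candidate cutoff (default
3.4, compared inclusively) is configurable because the surrogate's
scale need not match any externally produced score.

### Case/control standardization and shrinkage t

Expression values are assumed log2 scale.  Each gene's overall control
mean is subtracted from every sample, so control ratios average exactly
zero per gene and each case sample carries its own log2 ratio versus
the control reference.

Differential expression uses a variance-shrinkage t statistic with the
median gene variance as target:

    λ* = min(1, Σ_g V̂ar(v_g) / Σ_g (v_g − v_median)²)
    v*_g = λ* v_median + (1 − λ*) v_g
    t*_g = mean_diff_g / sqrt(v*_g (1/n_case + 1/n_ctrl))

v_g is the pooled two-group variance and V̂ar(v_g) the standard unbiased
variance-of-variance estimate from centered squared deviations,
n/(n−1)³ Σ_k (w_k − w̄)², pooled with the squared group weights.  When
every v_g equals the median the denominator vanishes and λ* is set to 1
(full shrinkage, which is then a no-op).  p-values use the Student t
reference with n_case + n_ctrl − 2 degrees of freedom, two-sided by
default (`alternative` switches sidedness).  Note the consequences on
homoskedastic data: λ* correctly tends to 1 (between-gene spread of v_g
is pure noise), making the test mildly conservative — the null
selection rate at α = 0.1 sits near 0.09 rather than 0.10.  λ* → 0 with
growing sample size only when the true gene variances actually differ.

### Conjugate posterior and TBV

With a normal prior N(θ₀, σ₀²) and a known-variance normal likelihood
summarized by (x̄, σ, n) — x̄ and σ the mean and SD of the case log2
ratios, n the case count — the posterior is normal with

    1/σ₁² = 1/σ₀² + n/σ² ,  θ₁ = σ₁² (θ₀/σ₀² + n x̄/σ²).

σ is estimated from the case samples only by default (each case is a
ratio against the control mean); a config option widens it to all
samples.  The decision statistic TBV = θ₁/σ₁ is compared strictly
against 2.58, the conventional rounding of the two-sided 99 % normal
quantile 2.5758; both cuts are supported and the genes flipping between
them are listed in the run report.  No multiplicity correction is
applied — the fixed cut *is* the procedure.  Genes present in only one
input (prior-only or data-only) receive no TBV and are reported
separately.

### GSEA

Preranked mode with the weighted Kolmogorov–Smirnov running sum
(weight exponent 1 by default; weight 0 makes the score rank-only and
invariant under monotone metric transforms).  Ranking metrics: the
signed Stouffer combination for the meta study and t* for the heart
study — the choice is exposed because either is defensible.  The null
is gene-label permutation, size-matched per set, with an add-one
correction so p is never zero; every set draws its own null so
p-values are independent across sets.  NES divides ES by the mean
|null ES| of the same sign, and FDR q follows the pooled-null NES
procedure with a monotonicity pass (q never increases with |NES|).
Significance defaults to q < 0.05, with q < 0.1 available in config.

### ISA biclustering

The matrix is standardized two ways (rows for gene scores, columns for
sample scores, both with the n−1 SD; zero-variance rows/columns are
dropped).  From a random 10-gene seed the update alternates:

* sample score = mean of the sample-standardized matrix over the
  current gene set; keep samples with score > T_C · sd(scores);
* gene score = mean of the gene-standardized matrix over the kept
  samples; keep genes with score > T_G · sd(scores).

Convergence is gene-set equality, with a score-correlation fallback
(r > 0.999 between consecutive iterations) to absorb slow oscillation;
runs exceeding 100 iterations are discarded with a warning.  The sweep
runs 100 seeds per threshold pair over the grid
{2, 2.2, 2.4, 2.5} × {2, 2.2, 2.4, 2.5} and deduplicates modules at
gene-set Jaccard > 0.9, keeping a seed-recovery count as robustness.

Anchor handling: modules containing the anchor with **more than** 5
samples (strict) are kept; pairs sharing more than 80 % of their genes
are merged into their union, to closure.  The sharing fraction is
|A∩B| / min(|A|, |B|): it is the only convention under which merging a
148- and a 154-gene module overlapping in 121 genes (share 0.818)
cleanly produces the 181-gene union; Jaccard would give 0.668 and never
trigger.  The convention is configurable.

Two practical notes.  First, because the threshold is measured against
the spread of the score vector — which includes the planted block's own
scores and the seeding noise (~1/√|seed|) per column — recovery from
random seeds depends on block geometry: blocks occupying a large
fraction of a small sample set (e.g. 7 of 15 samples) sit within 2 SD
of the score spread and are usually *not* recoverable at the default
grid, regardless of how strong the shift is.  The recovery tests
therefore use a wide matrix (500 genes × 120 samples, 25 × 16 block)
where the regime is well-posed.  Second, the sample/gene filters keep
*positive* scores only, so coherently *down*-shifted blocks are found
via their mirrored gene scores only when seeded accordingly; the
planted blocks in the generator are up-shifted.

The detection filter ("detection p < 0.1 in at least half the
samples") applies when per-gene detection p-values are supplied; the
50 % fraction is a package default, exposed in `IsaParams`, since no
canonical value is available.

### Overlap, correlation, clustering

Overlap tests are one-sided hypergeometric tails P(X ≥ k) (equivalent
to one-sided Fisher), with the cross-product odds ratio (∞ when a
denominator cell is zero).  The universe is the genes measured in both
studies for cross-study overlaps and the evaluated candidates for the
disease-list statistics; the run report additionally tests the
TBV-significant set against the disease list over the full measured
universe, because when nearly all evaluated candidates are significant
the candidate-universe test is powerless by construction.  Anchor
correlations are Pearson, pairwise-complete with at least 3
observations; zero-variance profiles yield a missing value, never a
silent zero.  Concordance requires the same non-zero sign in both
studies.  Heatmap dendrograms use the Canberra distance
(Σ|xᵢ−yᵢ|/(|xᵢ|+|yᵢ|), both-zero terms contribute 0 — scipy's
convention) with complete linkage on genes and on samples, exported as
Newick trees plus the reordered matrix.  Exact distance ties are broken
by scipy's deterministic internal order; on continuous data ties have
measure zero.

## Synthetic data

The generator emulates the study design the pipeline targets: a
16-study meta-analysis effect table, a 5-control / 10-case expression
study, an interaction network, a pathway collection and a 52-gene
disease list.  Choices and defaults:

* **Network**: Barabási–Albert preferential attachment (m = 1) over
  2,000 genes, with the anchor relabeled from an early node (index 2)
  so its radius-2 neighborhood spans roughly 100–300 genes — the scale
  of a well-connected extracellular-matrix hub in a curated
  interactome.
* **Effects**: half the anchor neighborhood is perturbed, plus a
  quarter as many genes outside it (seeded into the planted pathway).
  Effect sizes are ~N(1.0, 0.2²) log2 units, 80 % upregulated, the
  anchor always perturbed upward.  Per-study means are
  N(θ_g, se²) with se ~ U(0.15, 0.30).
* **Presence**: each (gene, study) pair is "absent" with probability
  0.3; present pairs draw detection p from Beta(0.1, 10) (mass near 0),
  absent pairs from U(0, 1).  Only the position relative to the 0.1
  cutoff matters downstream.
* **Expression**: baseline ~N(8, 1.5²) log2 units, noise SD 0.5, the
  true effect added to case samples, and one up-shifted bicluster
  (40 genes × 7 samples, +2.0) containing the anchor and spanning both
  groups.  The heart platform drops 10 % of the null genes, emulating
  differing array universes.
* **Disease list**: 40 % drawn from perturbed genes, 30 % from null
  universe genes, the rest from outside the universe (genes a
  literature survey would name but the arrays never measured).

All randomness flows through a single seeded `numpy.random.Generator`
(PCG64); identical parameters give byte-identical output files.

What the generator does **not** emulate: array-level probe effects,
normalization artifacts, correlated noise between genes (beyond the
planted bicluster), inter-study heterogeneity of true effects, or
realistic pathway overlap structure.  Passing tests therefore
demonstrate that the machinery recovers what it is designed to recover
under its own model assumptions — not performance on real arrays.

## Problem sizes and numerical tolerances

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in a few minutes: a 2,000-gene universe for end-to-end
runs (10 seeds for the recovery suite, 5 for the acceptance script),
500 × 120 matrices for ISA recovery (10 seeds, 20 ISA seeds per
threshold pair), 200 random sets at 200 permutations for the GSEA
null-uniformity check, and 300–1,000 random parameter draws for the
posterior-vs-quadrature comparison (grid integration over 20,001
points spanning ±12 combined SDs; observed agreement ~1e−15, asserted
at 1e−6).  The readers/writers round-trip doubles exactly via `%.17g`
formatting.

## Known limitations

* The surrogate meta score is not the score of any published
  meta-analysis pipeline; its 3.4 cutoff is a configurable convention.
* The shrinkage-t null reference (Student t with pooled df) is a
  pragmatic choice; the cited construction of the statistic leaves the
  null distribution open.
* ISA as configured finds up-coherent modules; the sample-threshold
  regime limits recoverable blocks on very small sample sets (see
  above), which is why co-expression modules contribute little on a
  15-sample study.
* TBV thresholds are fixed-cut decisions without multiplicity control
  by design; interpret the significant-set size accordingly.
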