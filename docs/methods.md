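# Methods

## Pathway activity score

The score chain operates on a nonnegative genes × cells matrix and a
cell → cell-type map with at least two types.

1. **Normalization.** By default each cell is rescaled so its total
   expression equals the median library size (`normalize="median-libsize"`);
   cells with zero total stay zero. Averaging is then done on this linear
   scale — the per-type summary E<sub>i,j</sub> is a plain arithmetic mean,
   so a linear input scale is the consistent choice. `normalize="none"`
   passes the matrix through for data already normalized upstream.
2. **Relative expression.** r<sub>i,j</sub> divides each per-type mean by the
   unweighted average of the gene's per-type means. Genes whose per-type
   means sum to zero (i.e. zero in every cell) are dropped and reported, not
   divided: the quantity is undefined there and such genes carry no relative
   signal. For every retained gene the mean of r over types is exactly 1 up
   to floating point (checked at 1e-9 in tests).
3. **Weighted mean.** The pathway score is the ω-weighted mean of member-gene
   r values, ω<sub>i</sub> = 1/c<sub>i</sub> with c<sub>i</sub> the gene's
   pathway-membership count. The ratio form makes the score invariant to a
   global rescaling of the weights. A pathway is scored only when at least
   `min_genes` members survive in the matrix (default 3 — a weighted mean
   over fewer genes is dominated by single-gene noise); smaller pathways are
   reported as unscored with the reason rather than silently omitted.

A score of 1 means "average activity across types"; the all-equal-expression
matrix produces exactly 1 everywhere.

## Permutation test

The null hypothesis for "pathway t specifically activated in type j" is that
cell-type labels are exchangeable. Labels are shuffled across all cells
(type sizes preserved), the full chain — per-type means, relative
expression, weighted mean — is recomputed each round, and the one-sided
empirical p-value is (1 + #{permuted ≥ observed}) / (n_perm + 1). Choices:

- **Ties count toward the null** (the `≥`), which is conservative and makes
  the degenerate constant-expression case give p = 1 exactly.
- **Add-one correction** bounds p below by 1/(n_perm + 1); p = 0 is never
  reported. Default n_perm = 999.
- **Seed is a required argument** — there is no hidden global RNG state.
- **No multiplicity adjustment by default**; raw p-values are reported
  per (pathway, type) pair, with an optional Benjamini–Hochberg flag
  (`adjust="bh"`) across all scored pairs.

The observed score and every permuted score go through the same vectorized
arithmetic (one matrix product per block of shuffles), so tie comparisons
are exact and the permutation loop costs one BLAS call per chunk. The set of
retained genes is label-invariant (a gene's per-type means sum to zero iff
the gene is zero in every cell), so the weighted-membership matrix is built
once.

Category aggregation is the unweighted mean of member-pathway scores per
category — the simplest summary of a per-category display; an
`weight_by_size` flag switches to weighting each pathway by its retained
member count.

## DEG calling and meta-intersection

Within a cohort, each gene is tested with a Welch two-sample t-test on
log2-scale values; declared-linear inputs are log2-transformed after a
strict positivity check (microarray-style intensities, no pseudocount).
Welch was chosen over the pooled-variance t because cohort group variances
are rarely equal, and its statistic is checkable against a closed-form
oracle; a moderated/shrinkage t is deliberately out of scope. log2FC is
mean(case) − mean(control). Calls use strict inequalities — p < 0.05 and
|log2FC| > 1 by default — so a gene at exactly the threshold is not called.
Genes with zero variance and equal means in both groups get p = 1.

The meta step intersects non-ns calls across all cohorts and keeps the genes
with unanimous sign, split into up and down lists; genes significant
everywhere with conflicting signs are reported separately and excluded from
both lists. With three independent cohorts of ~500 null genes at these
cut-offs, the expected count of false consistent overlaps is well below 1,
which is what makes the intersection a meaningful filter.

## Cluster statistics

- **Proportions.** Per-sample cell-type fractions are compared between
  conditions with a Wilcoxon rank-sum on the fractions. For a combined
  sample count ≤ 20 the p-value is exact by full enumeration of label
  assignments using midranks (so ties are handled, and the all-tied case
  gives p = 1); beyond that a normal approximation with tie-corrected
  variance is used. The rank-sum was chosen because per-sample fractions at
  n of a few per group are far from normal and the test is exact at this
  scale.
- **Co-expression.** Pearson correlation between a focal gene and each
  marker across the cells of one cluster, on log2(x+1) values (counts are
  heavily right-skewed; the log stabilizes the correlation). Classification
  is by sign at p < alpha (default 0.05, no |r| floor; both configurable).
  Zero-variance markers are reported as unclassified with the reason. The
  marker list is a user input; deriving per-cluster markers is upstream of
  this package.
- **Paired correlation.** Pearson r with the two-sided t-based p on n − 2
  degrees of freedom, for clinical/protein tables; requires n ≥ 3, finite
  values, nonzero variance.

## Synthetic data generator

The generator emulates the input structure of the pipeline, not any
particular tissue:

- **Pathways.** Each pathway after the first borrows
  k = round(f·P·g / (2(P−1))) genes from the pool of genes used exactly once
  so far (f = `overlap_fraction`, P pathways, g genes each), so the fraction
  of membership slots held by multi-pathway genes tracks f. Categories cycle
  round-robin through up to 11 KEGG metabolism class names.
- **Single cell.** Gene baselines are log-normal around `baseline_mean`
  (default 2 counts); counts are gamma-Poisson (negative binomial) with
  shared `dispersion` (default 2) and per-cell log-normal library factors at
  `libsize_cv` = 0.2. Planted (pathway, type, fold) effects multiply member
  gene means in that type before sampling — the multiplicative form matches
  the ratio semantics of r. `celltype_baseline_sd` defaults to 0 so that,
  with nothing planted, cells are exchangeable across type labels and the
  permutation test's null calibration can be verified; set it > 0 to give
  types distinct baseline profiles (planted effects already create
  type-distinct structure when present). Cells are spread round-robin over
  `n_samples_per_condition` case and control samples each (default 3 + 3).
- **Bulk.** log2 expression is normal (sd `bulk_log2_sd`, default 0.2 —
  array-like noise at which a |log2FC| = 3 effect at n = 10/10 is near-surely
  called) around per-gene baselines, plus a cohort-wide offset
  (sd `bulk_scale_sd` = 0.5) standing in for platform/scale differences.
  Values are emitted on the linear scale.
- **Defaults** describe the reference study scale used in the tests and the
  acceptance script: 5 types × 200 cells, 500 genes, 20 pathways × 20 genes
  at 25% overlap; 3 cohorts of 10 vs 10 samples.

What the generator does **not** emulate: doublets, ambient RNA, dropout
zero-inflation beyond NB sampling, batch effects beyond a global cohort
scale, probe-level artifacts, or correlated gene programs. Passing recovery
and calibration tests therefore demonstrates correctness of the statistics
under the stated noise models, not robustness to every artifact of real
tissue data.

## Numerical and interface choices

- All CSV outputs use fixed column order and `%.6g` floats, so identical
  runs are byte-identical and diffable.
- One mandatory top-level pipeline seed; per-stage child seeds are derived
  deterministically from it. Config validation is strict: unknown keys are
  rejected with a closest-match suggestion, and every violation is reported
  at once.
- Volcano exports cap −log10(p) at 300 (p = 0 maps to the cap).
- Degenerate inputs are contract errors, not silent NaNs: annotation
  referencing unknown cells, fewer than 2 cell types, empty
  pathway/matrix overlap, groups with < 2 samples, nonpositive values on a
  declared-linear bulk scale.

## Known limitations

- The permutation test asks "is this (pathway, type) score high relative to
  label-shuffled data"; it does not model per-sample pseudoreplication
  (cells from one sample are treated as exchangeable units).
- Welch t on log2 microarray-style values is a reasonable default but not a
  moderated test; with very small groups per cohort, variance estimates are
  noisy.
- The scoring operates on whatever expression scale it is given after the
  optional library-size normalization; results on log-transformed input will
  differ from linear input, and the choice is the caller's.
- Category aggregation assumes each pathway has exactly one category label.
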