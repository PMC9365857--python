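# Methods

This note describes the models and procedures implemented in `tuftnet`,
the defaults they ship with, and the choices made where the design was
genuinely open. The package maps a set of candidate target genes (for
example, trans-eQTL targets of a regulatory locus) to a specific, possibly
rare, transcriptional cell cluster in multi-sample scRNA-seq, using
pseudo-bulk co-expression networks and abundance modelling.

## Synthetic cohorts (`tuftnet.simulate`)

The generator emulates a small multi-sample cohort of the kind studied in
colonic epithelium: ~11 samples of ~455 cells each, ~1,500 genes, 12
transcriptional clusters of which one ("the rare cluster", a tuft-cell
analogue) holds ~1.5% of cells. A latent per-sample *driver activity*
`a_s ~ N(0, 1)` stands in for genotype-driven cis-gene expression:

- the driver gene's expression has mean `driver_mean * exp(a_s)` in every
  cell of sample `s`, so observed driver expression is a noisy proxy of
  the latent activity;
- a 60-gene target module is expressed at `module_mean_rare = 3` counts
  per cell inside the rare cluster and `module_mean_other = 0.02` outside
  (detection fractions outside of ~2%, of the order seen for real
  rare-cell markers); inside the rare cluster its means are multiplied by
  `module_effect ** a_s` (default fold 4 per unit activity);
- the rare cluster's per-sample abundance follows
  `logit(p_s) = logit(0.015) + abundance_coupling * a_s` (default slope
  1), with the remaining probability mass redistributed proportionally
  over the other clusters;
- every cluster (including the rare one) carries 30 disjoint marker genes
  at 6-fold elevation — distinct cell types in real tissue are separated
  by tens to hundreds of such genes;
- counts are gamma-Poisson (negative binomial, variance `mu + 0.3 mu^2`)
  with per-cell lognormal library scaling (sd 0.25 on the log scale);
  per-sample cell numbers are themselves NB around the mean.

What the generator does **not** emulate: batch effects (batch integration
is out of scope), doublets, ambient RNA, UMI saturation, and any gene-gene
correlation beyond the planted module and cluster identities. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under clean, well-separated conditions; they do not bound its behaviour
under batch confounding or contamination.

## Quality control (`tuftnet.qc`)

Four filters in a fixed order: empty-droplet removal at the inflection of
the barcode-rank curve, genes in < 20 cells removed, cells with expression
sparsity > 0.99 removed (strict inequality), cells with mitochondrial
proportion above `median + 2.5 * MAD` removed. Choices the originating
descriptions leave open:

- the MAD is unscaled (no 1.4826 consistency factor) and the cut is
  one-sided — high mitochondrial content is the damaged-cell signature;
- the inflection estimator resamples log10(count) versus log10(rank) onto
  an even log-rank grid, smooths with a 3-point moving average, and takes
  the *first sustained steep excursion* of the derivative (first segment
  reaching half the steepest slope, descended to its local minimum). The
  global minimum is deliberately not used: the discrete low-count tail
  (counts 2 → 1) always produces artefactually steep segments;
- sparsity is the fraction of genes with zero count in the cell.

The gene and sparsity filters are idempotent. The mitochondrial filter
recomputes the median/MAD on the filtered population, so re-application
can tighten further; it never resurrects removed cells.

## Pseudo-bulk and normalisation (`tuftnet.pseudobulk`)

Counts are summed per sample (or per sample-within-cluster), normalised
with trimmed-mean-of-M-values factors (reference sample by upper-quartile
proximity to the mean upper quartile; 30% two-sided M trim, 5% A trim,
inverse binomial-variance weights, factors rescaled to geometric mean 1 —
the standard TMM recipe, cross-checked against edgeR in the test suite),
log2-CPM transformed with a 0.5-CPM pseudocount, and standardised per gene
across samples with the sample (n−1) standard deviation. Zero-variance
genes become zero columns and are flagged.

## Clustering (`tuftnet.cluster`)

Variance-stabilised gene selection (lowess of log10 variance on log10
mean, standardised values clipped at sqrt(n_cells)), PCA (50 components,
deterministic sign convention), a shared-nearest-neighbour graph weighted
by Jaccard overlap of (k+1)-sets with the standard 1/15 pruning cutoff,
and Louvain community detection at resolution 0.6 with an explicit seed.
`k` defaults to `min(250, n_cells / 20)`: the reference value of 250
presumes tens of thousands of cells. Cluster pairs separated by fewer
than 30 genes at a two-sided ROC AUC ≥ 0.6 are merged iteratively,
smallest separation first.

## Markers (`tuftnet.markers`)

Expression is depth-normalised as log-TP10K, `ln(c / total * 1e4 + 1)`.
The marker test is a self-contained two-part (hurdle) likelihood-ratio
test of one cluster against all other cells: a binomial LRT on the
detection rate plus an equal-variance Gaussian LRT on the positive
log-TP10K values, combined as chi-square with 2 df. This captures the
hurdle structure of the published MAST model without its covariate
machinery, so p-values on real data will differ numerically from that
package while the record arithmetic — `avg_log2FC = log2(mean expm1 in +
1) − log2(mean expm1 out + 1)`, detection fractions `pct.1`/`pct.2`, and
Bonferroni `p_val_adj = min(1, p * G)` over all G tested genes — matches
the reporting conventions exactly. No detection-fraction or fold-change
pre-filter is applied before testing.

## Co-expression networks (`tuftnet.coexpr`)

Signed weighted networks on z-scored pseudo-bulk: `a_ij = ((1 +
cor_ij)/2)^beta` with Pearson correlation throughout. The soft power is
the smallest in 1..20 whose scale-free fit (signed R² of log-frequency on
log-connectivity over 10 bins) reaches 0.85, falling back to the argmax.
The topological overlap matrix uses the standard signed formula; it is
validated against a triple-loop oracle to 1e-12.

Module detection cuts the average-linkage tree on 1 − TOM recursively
from the root: a node splits when its two children's eigengenes are
separated by at least `merge_height = 0.25` (1 − correlation); closer
children form a single module; children smaller than `min_module_size =
30` that fall off a split are unassigned. A final robust refinement
removes module members whose kME is below the module's median − 3 MAD,
and modules with eigengene dissimilarity < 0.25 are merged. The
dissimilarity-driven recursive cut replaces a static height cut because,
with ~11 samples, average linkage chains chance-correlated noise genes
onto coherent branches one at a time; a height cut absorbs them (module
Jaccard against planted truth dropped to 0.2–0.7), while the
eigengene/kME criteria strip them using the same dissimilarity notion as
the merge step. The PAM-like reassignment stage of the reference hybrid
algorithm is not implemented.

Module eigengenes are the first singular direction of the standardised
module submatrix, unit-norm over samples and sign-oriented along the
module's average expression. Module–trait statistics are Pearson
correlations with two-sided Student t p-values (n − 2 df) and BH
correction across the whole module × trait grid; multi-level covariates
should be one-hot binarised. Per-gene statistics: MM (kME, correlation
with the own-module eigengene), GS (correlation with a trait), scaled
intramodular connectivity kIM (within-module adjacency sum over the
module maximum; singletons 0), and the maximum intramodular adjacency.
Hub genes require MM > 0.7, scaled kIM > 0.7 and max intramodular
adjacency > 0.3 — the adjacency cut is interpreted per gene, as its
strongest within-module edge.

## Enrichment (`tuftnet.enrich`)

Preranked GSEA with the classic running sum: hit increments
`|stat|^weight` (weight 1 by default) normalised over the set, miss
decrements `1/(N − N_hit)`; ES is the extremum of the walk (exact
magnitude ties resolve positive). The null samples random same-size gene
sets (10,000 by default); `NES = ES / mean(|null| of the same sign)` and
the p-value is one-tailed with +1 smoothing. BH across sets when several
sets are tested together. Gene-set sampling, not phenotype permutation,
matches the preranked setting.

## Specificity machinery (`tuftnet.specificity`)

**Sample grouping.** Samples are clustered by complete linkage on
Euclidean distance over hub-gene z-scores and split at the dendrogram
root; the branch with lower mean hub expression is "low". The permutation
null redraws 10 random genes 10,000 times and counts exact unordered
bipartition matches; `empirical_p = matches / n_perm` with no smoothing —
the count/total convention. This quantity is a *reproducibility
frequency*, not a hypothesis-test p-value: with ~11 samples the space of
bipartitions is large, so under a null cohort the frequency of any
observed split is small regardless of structure, and its distribution is
the size-biased null-frequency distribution rather than uniform. It is
reported (and tested) as such.

**Auxiliary module and preservation.** Within the designated cluster's
own network (soft power 6, top-5000 variable genes where applicable),
target genes with GS > 0.5 (nominal p < 0.05) and MM > 0.5 form the
auxiliary module. In every cluster the auxiliary eigengene is recomputed
and each auxiliary gene's kME taken; `cor.kME` is the Pearson correlation
between a test cluster's kME vector and the reference's, with a two-sided
Student t p-value on the number of usable genes. Clusters with fewer than
two auxiliary genes of non-zero variance are excluded; the reference's
own cor.kME is 1 by construction. Average MM per cluster is reported
alongside. Note that with ~10 null clusters tested at nominal 0.05,
roughly one chance-significant cluster per two cohorts is expected; the
per-cluster p-values are deliberately left uncorrected to match the
reporting convention, and users drawing family-wise conclusions should
adjust.

**Variability tables.** Per gene × cluster: variance of pseudo-bulk
z-scores (aggregated by sample-within-cluster and standardised jointly
across all units so clusters are comparable), raw single-cell variance,
and vst-standardised single-cell variance. For genes that are near-silent
outside their home cluster, the pseudo-bulk log-CPM of the other clusters
is dominated by shot noise at moderate cohort sizes, so the raw
single-cell variance is the more faithful within-cohort localisation
measure — the same reasoning given for preferring raw variance in
low-expression regimes in the source analyses.

**Between-cohort variance test.** Fold changes of normalised variance
A/B for a target set are summarised by median/mean; the null draws
same-size gene sets without replacement from the shared expressed universe
(100,000 draws), p is +1-smoothed, and the 95% CI of the mean fold change
is a percentile bootstrap (10,000 resamples) over target genes.

## Abundance (`tuftnet.abundance`)

**Univariate model.** OLS of cluster abundance on a single gene's
pseudo-bulk expression, with the two-sided t p-value.

**Genome-wide moderated scan.** Per gene, OLS of log2 pseudo-bulk
expression on abundance, with empirical-Bayes variance moderation
(hyperparameters by moment-matching of log s² to a scaled-F model,
trigamma-inverse by Newton iteration; `d0 = inf` handled), moderated t
with `d0 + df_res` df, and BH. The abundance covariate is standardised to
unit variance, so the reported logFC is the log2 change per SD of
abundance: a raw cluster fraction spans only a few percent and would
inflate every slope, rendering a fold-change cutoff meaningless.

**Neighbourhood differential abundance.** Index cells sampled at 10%,
refined to the member nearest the neighbourhood centroid and
deduplicated; neighbourhoods are k nearest neighbours in 4 PCs. The
default k is `min(250, max(20, 5 * n_samples))`, following the
cited guideline of a few neighbours per sample — at a few thousand cells,
k = 250 would exceed the rare cluster entirely and no pure rare
neighbourhood could exist. Counts per sample are modelled by an NB GLM
with log(total cells × TMM factor) offsets and a shared moment-matched
dispersion; the likelihood-ratio statistic is referred to F(1, S − 2)
rather than chi-square(1) — the finite-sample correction in the spirit of
the quasi-likelihood F-test, without which the test rejects ~8.5% at
nominal 5% with 11 samples (calibrated to ~5% with the correction).
Spatial FDR is weighted BH with reciprocal kth-NN-distance weights (plain
BH by flag). Neighbourhoods with majority-cluster proportion ≤ 0.8 are
dropped before interpretation.

## Pipeline (`tuftnet.pipeline`)

`run_all` chains the stages with a single JSON-serialisable config whose
defaults are the reference values (min_cells 20, sparsity 0.99, mito 2.5
MAD, resolution 0.6, 5000 HVGs, merge height 0.25, hub cuts 0.7/0.7/0.3,
auxiliary cuts 0.5/0.05/0.5, 10,000 grouping permutations, majority 0.8,
spatial FDR 0.01). One run seed fans out to per-stage generators via a
stage-name hash, so toggling one stage does not shift another's
randomness; identical config and seed give byte-identical outputs. The
target list subset is taken before z-scoring. Artifacts are TSV/JSON plus
a markdown summary.

## Problem sizes used in the tests

Recovery suites run 20 replicate cohorts at the reference conditions
(11 samples, ~5,000 cells, 1,500 genes, 60-gene module, 1.5% rare
cluster) for the network and specificity criteria, one canonical cohort
(seed 0) for the abundance criteria, 200–500 replicates for the
calibration checks, and reduced cohorts (6 samples, ~1,200–1,500 cells,
400 genes) for unit tests. These sizes keep the full suite within a few
minutes per criterion on one CPU.

## Known limitations

- No batch integration; on real multi-batch data the clustering stage
  requires externally integrated embeddings.
- The hurdle marker test approximates, and will not numerically
  reproduce, MAST p-values; ranks and record arithmetic are comparable.
- The NB-LRT differential-abundance test approximates the QL F-test; its
  size is calibrated on simulation, but dispersion trends across
  neighbourhood sizes are not modelled.
- The grouping permutation "p-value" is a reproducibility frequency (see
  above) and should not be compared against a uniform-null threshold.
- Preservation p-values are per cluster and uncorrected by design; with
  many clusters some chance significance is expected.
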