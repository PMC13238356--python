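# Methods

This note documents the models, parameter choices, and numerical
conventions behind `dystromap`, and what the synthetic benchmark does and
does not establish about real tissue.

## Lattice geometry

Visium array coordinates are embedded as `x = 50 um * array_col`,
`y = 50*sqrt(3) um * array_row`, with `(array_row + array_col)` even.
Under this embedding all six hex neighbours of a spot sit at exactly
100 um, so ring and distance computations are exact rather than
tolerance-based.  Neighbour offsets are `(0, ±2)` and `(±1, ±1)`.

## QC and normalization

Spots in annotated folds or gaps are removed unconditionally; remaining
spots need a total count of at least 30 *unless* masked as fat —
adipocytes are transcriptionally sparse, so low counts over fat are
biology, not failure.  Mitochondrial and ribosomal genes are removed by
case-insensitive name prefix (`MT-`, `RPS`, `RPL`, `MRPS`, `MRPL`); the
prefix rule is our own formalization of the gene classes (so e.g. `MTOR`
survives).  Expression is log-normalized per spot:
`v = ln(1 + s*c/total)` with scale `s = 10,000`.

Histology masks are consumed as pixel-space polygons with precedence
fold > gap > fat (artefact regions must never be analysed) and closed
containment (a spot center on a polygon boundary is inside), which makes
lattice-aligned masks deterministic.

## Module scores and mixture thresholding

A module score is the mean expression of the module genes minus the mean
of expression-matched controls: genes are ranked by mean expression and
cut into `nbin = 24` equal-size bins, and each module gene draws
`nctrl = 100` controls from its own bin (without replacement when the bin
is large enough).  Both parameters are configurable; the binned-control
scheme is the standard signature-scoring convention and centers the score
at zero under no enrichment.

High/low thresholding fits a two-component univariate Gaussian mixture by
EM, repeated (default 500 times) from random initializations: means at
two random data quantiles, both variances at the data variance, weights
1/2.  EM stops at a relative log-likelihood change below 1e-8 or 300
steps.  Runs are discarded as degenerate when a variance collapses below
1e-12, a weight below 0.01, or the two means coincide (the symmetric
saddle); discarded runs are redrawn up to five times the requested count,
and if every attempt degenerates the distribution is declared unimodal
and all spots are sent to the low group.  Each surviving run MAP-labels
every spot against its larger-mean component; runs whose final
log-likelihood falls more than 2 nats below the best run are treated as
inferior local optima and excluded from the vote, so the reported vote
fraction reflects the consensus of the maximum-likelihood solution family
rather than an average over optimization failures.  A spot is "high" when
its vote fraction exceeds 1/2; a scalar threshold (midpoint between the
highest low-spot and lowest high-spot score) is reported for
interpretability.

Assignment is hierarchical and exclusive: fat mask > connective-tissue
high > muscle high > not assigned.  Muscle spots take the fiber type of
their maximal myosin; ties break Type I > Type IIa > Type IIx, and spots
with all three myosins at zero are reported as `MuscleUntyped`.
Thresholds are fitted per sample and per module on non-fat spots.

Group comparisons of composition percentages use
`y = arcsin(sqrt(pct/100))` and a pooled-variance two-sample t-test;
sidedness is a parameter (default two-sided).  Identical degenerate
groups return t = 0, p = 1 by convention.

## Deconvolution

Markers are selected one-vs-rest per reference cell type by Wilcoxon
rank-sum on log-normalized single-nucleus expression, requiring an
in-type expressing fraction of at least 0.1 and an average fold-change of
at least 2.5 on the configured log base (base 2 by default; natural log
selectable because published tool versions differ), Bonferroni-adjusted
p < 0.05, positive only, top 50 per type.  Cell populations listed in
`exclude_types` (default the tiny B/T compartment) are removed before
testing.

Spot proportions minimize

    ||Y − W B||_F^2 + lambda * sum_{i~j} ||w_i − w_j||^2,   W >= 0,

where rows of `Y` are spot expression over the marker union and rows of
`B` are per-type reference profiles.  Two design choices matter:

1. **Scale.** The fit is performed on *relative counts* (`expm1` of the
   log-normalized values divided by the scale), with `B` averaged on the
   same scale.  Spots are physical mixtures of cells, so their expected
   counts — not their log-counts — are linear in the mixture weights; on
   synthetic tissue the count-scale fit roughly halves the mean L1 error
   of a log-scale fit (0.13 vs 0.19).  A log-scale mode remains available
   (`scale="log"`).
2. **Smoothing weight.** `lambda` is expressed scale-free, as the ratio of
   spatial to data curvature per spot (internally multiplied by
   `trace(B Bᵀ)/K` and divided by the mean graph degree), so `lambda=0.1`
   means "the neighbourhood pulls with a tenth of the data's weight"
   regardless of expression units.  Default 0.1.

The objective is convex; it is minimized by cyclic per-type block updates,
each a projected gradient step with the exact block Lipschitz constant
(`G_kk + 2*lambda*max_degree`), which is monotone and, at `lambda = 0`,
reduces to exact coordinate minimization so the solution matches
independent per-spot NNLS.  Iteration stops at a relative objective change
below 1e-10 (tighter than the generic 1e-8 so that the NNLS equivalence
holds to 1e-5 after row normalization) or 2,000 sweeps.  Rows summing to
zero are flagged ambiguous and reported uniform; dominant types are row
argmaxes with ties broken by reference order.

## Pseudo-bulk differential expression

Counts are summed per sample, or per (sample, annotated cluster) at
module level; profiles with fewer than 10 spots are dropped.  Genes pass
the expression filter when their CPM exceeds `10 / (median library
size / 1e6)` in at least as many profiles as the smallest group and their
total count is at least 15.  TMM normalization uses M-trim 0.3, A-trim
0.05, precision weights, the profile whose upper CPM quartile is closest
to the mean as reference, and factors rescaled to geometric mean 1.

Each gene follows a negative-binomial log-linear model with offsets
`log(library * factor)`.  Dispersions are estimated on a 45-point
log-spaced grid (1e-4 to ~8) by Cox–Reid adjusted profile likelihood:
the common value maximizes the summed adjusted likelihood, and per-gene
values maximize the gene's own likelihood plus 10 times the gene-averaged
likelihood — an empirical-Bayes shrinkage toward the common value with a
prior weight of roughly ten residual degrees of freedom.  Group contrasts
are likelihood-ratio tests (full model: one intercept per group, fitted
by vectorized Fisher scoring; null: pooled intercept) against chi-square
with 1 df, BH-adjusted; the DEG rule is |log2FC| > 0.5 and adjusted
p < 0.05.  Non-finite fits are flagged and assigned p = 1.

## Fat-niche communication

Fat spots are layer L0; L1–L3 are successive BFS rings on the spot
adjacency graph; everything farther is unassigned.  A context is a
(sample, adjacent layer pair) with pairs L0–L1, L1–L2, L2–L3.  Within a
context, sender and receiver spots are drawn from the union of its two
layers, grouped by dominant deconvolved type, requiring at least 3 spots
per type.  Multi-subunit ligands/receptors score as the minimum subunit
expression per spot; the interaction magnitude is the arithmetic mean of
the sender-side ligand mean and receiver-side receptor mean.  Filters are
inclusive: both expressing fractions ≥ 0.6 (expression meaning > 0 on the
normalized scale) and pair-level mean expression over all L1–L3 spots at
least 2.0 times the mean over unassigned spots (a zero reference with a
nonzero niche counts as infinite enrichment and passes).  Enrichment is
computed pair-level per sample rather than per cell type, which keeps the
filter interpretable as "this interaction's genes concentrate around
fat".

Retained scores fill a contexts × pairs × senders × receivers tensor with
a mask for undefined combinations.  The masked non-negative CP
decomposition alternates exact per-row non-negative least squares over
the four factor matrices, imputing undefined entries with the current
reconstruction at the start of each iteration (EM-style), which makes the
defined-entry loss non-increasing.  Factor updates solve the normal
equations through a Cholesky factor of the Hadamard product of Gramians,
so each row is a rank-sized NNLS.  Random uniform(0.1, 1) initialization
from the seed; stop at relative loss change < 1e-6 or 500 iterations;
default rank 15, clipped in the demo pipeline to the per-mode
least-squares bound when the tensor is small.

## Fat-distance gradients

Distances are Euclidean um from each spot center to the nearest fat spot
center (0 inside fat); measuring to spot centers rather than polygon
boundaries keeps the field lattice-exact and oracle-testable.

The spatial-variability prefilter is Moran's I with row-normalized hex
weights, tested one-sided against `E[I] = −1/(n−1)` with the
normality-assumption variance and BH-adjusted at alpha 0.05.  Genes with
zero total or zero variance are dropped up front.  The analytic z-test is
mildly anticonservative on skewed expression values; the BH step absorbs
this in practice (verified by permutation nulls in the test suite).

For template fitting, non-fat spots are scaled to `t = d/d_max` and cut
into 20 equal-width bins.  Per gene, bin means are min–max rescaled to
[0, 1] (flat profiles are skipped) and compared by RMSE against every
registry template evaluated at each occupied bin's *mean* t — not the bin
center — which is unbiased for locally linear profiles and makes an exact
linear gradient score RMSE 0.  Registry defaults: linear descending
`1−t`, early descending `(1−t)^3`, instant descending `exp(−10t)`,
Gaussian peaks at t = 0.5 with sigma 0.20 / 0.125 / 0.05 (gradual /
medium / small), and ascending mirrors of the descending forms; all
curves are rescaled on the evaluation grid, and the registry is
config-extensible.  A gene is selected when its adjusted p is below 0.05
and its best RMSE below 0.25.

## Synthetic data

The generator is the package's study design: it produces the statistical
structure every downstream stage assumes, plus ground truth for
parameter-recovery tests.

- **Reference**: nine cell types, 60 cells each, 2,000 genes, baseline
  mean 2, 20 markers per type at 2^4-fold elevation, negative-binomial
  counts via Gamma–Poisson with dispersion 0.3.  Marker slots carry
  field-standard symbols (*MYH1/2/7*, *COL1A1/2*, *THBS4*, *ADIPOQ*,
  *LPL*, *LRP1*, ...) so module definitions and L–R tables read
  naturally.
- **Tissue**: a full hex lattice (demo 16×32); fat patches are hex balls
  (all spots within k rings — exact for ring oracles, with an optional
  polygon emitter for mask-reader tests), surrounded by a 3-ring fibrotic
  halo; optional fibrotic patches independent of fat give healthy samples
  their few percent of connective tissue.  Per-spot mixtures are
  Dirichlet draws with zone-specific concentrations (fat:
  adipocyte-dominated; halo: FAP-dominated; bulk: fast/slow fibers),
  then averaged once with same-zone neighbours — neighbouring spots share
  tissue context in real sections, and this is the smoothness the
  spatially regularized deconvolution assumes.  Spot counts are NB draws
  from the proportion-weighted mixture of type profiles at library size
  10,000 (dispersion 0.3).
- **Plants**: group fold-changes multiply DYS expectations
  (`de_genes`); niche pairs multiply the ligand over fat+halo and the
  receptor over the halo by 8x (detected >0 in well over 80 % of those
  spots at default depth); gradient genes multiply baseline by
  `1 + 8 * template(d/d_max)`, making template recovery analytic.
- **Cohort**: the demo mirrors the study design at desk scale — 4 HC + 8
  DYS, seven DYS samples with a fat patch and one without — and emits a
  sequencing-metadata table (reads per site, spots under tissue) in the
  same dialect as the bundled cohort summary.  All seeds derive from a
  single master seed via a stable name hash.

**What passing does not show.** The generator has no doublets, no
segmentation artefacts, no UMI-level noise, no spatial bleed between
spots, no batch effects between sites, and its cell-type profiles differ
only in planted markers.  Recovery results (annotation ≥ 95 %,
deconvolution L1 < 0.15, DE power ≥ 0.8 / FDR ≤ 0.1, gradient recall
≥ 0.8) therefore demonstrate correctness of the algorithms under their
stated assumptions, not expected performance on real sections.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: tissues of
~250 spots (16×32 lattice) with 2,000 genes for single-sample recovery,
12-sample cohorts of ~140 spots and 400–600 genes for the pipeline, and
ten-replicate simulations for power/FDR and niche-recovery rates.  These
sizes put every Monte-Carlo bound comfortably past its threshold while
keeping the whole suite around a minute.

## Known limitations

- The NNLS deconvolution ignores count heteroscedasticity (no per-gene
  weights); CAR-style full posteriors are out of scope.
- Communication scores are magnitude-only; no permutation specificity
  p-values are computed — the niche filters, not the score family, carry
  the selection logic.
- The Moran prefilter tests global autocorrelation, not specifically
  fat-anchored patterning; the template RMSE stage provides that
  specificity.
- Module-level DE treats samples as the only replicates; no additional
  covariates are modeled.
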