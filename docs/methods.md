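# Methods

## Scope and model

`stemcss` operationalizes a two-axis view of colorectal-cancer stemness:
an LGR5-type program (WNT-associated) and a LAPTM4B-type program
(MYC-associated, tied to a chromosome-8q expression gain and to
microsatellite-stable tumors). The package covers the full chain from
single-cell marker discovery to bulk-cohort outcome statistics. All
statistical primitives that are standard in the field are delegated to
established libraries (lifelines for survival, scipy/statsmodels for the
elementary tests, scikit-learn for ROC); the components specific to this
analysis — Ro/e, the rank-based gene-set score, the simplified
expression-CNV arm scorer, the intersection-based marker and signature
calls, the median-quadrant CSS classifier, and the generators — are
implemented here and verified against independent brute-force oracles in
the test suite.

## Normalization

Counts are library-size normalized to 10,000 per cell/sample and
`log1p`-transformed — the field-standard transform; every operation
downstream of raw counts (differential expression, signature scoring,
arm CNV) assumes this scale. Fold changes are reported in log2 on the
de-logged normalized scale with a pseudocount of 1e-9.

## Differential expression

Two-sided Wilcoxon rank-sum per gene (the standard nonparametric
cluster-marker test for single-cell data), asymptotic p-values with tie
correction, BH step-up FDR across all tested genes. Genes constant and
equal in both groups carry no information and are assigned `p = 1`,
`log2FC = 0`. Groups must be disjoint with at least 3 units each.

## Rank-based gene-set score

For each cell, genes are ranked by decreasing expression; ties are broken
by one fixed seeded shuffle of the gene order so results are
deterministic. With `k = ceil(top_fraction · G)` (default
`top_fraction = 0.05`, the published AUCell default), a signature gene at
rank `r ≤ k` contributes `k − r + 1` to the area under the recovery step
curve; the score divides by the maximal area, reached when all
`min(|S|, k)` signature genes occupy the top ranks. The score lies in
[0, 1], is monotone under rank improvement, and is invariant to any
strictly increasing transform of a cell's expression vector.

## Expression-inferred arm CNV

Per gene, log2 expression is centered by the mean over reference cells
(normal epithelial clusters), clamped to ±3 log2 units, and smoothed by a
centered moving average of width 101 genes (both inferCNV defaults,
configurable) within each chromosome, over genes in genomic order taken
from the locus table (1-based starts; arm assignment comes from the
table, no cytoband inference). The per-cell arm value is the mean over
the arm's genes; the cluster score is the mean over its cells; a gain is
called above `gain_threshold = +0.1`, chosen about four times the noise
floor observed on null simulations (max |score| ≈ 0.016–0.027 across
seeds), and only for arms with ≥ 30 located genes. No HMM and no
subclustering: the score is used to flag and compare arm-level gains, not
to segment genomes. Smoothing runs within a chromosome, so a strong
q-arm gain bleeds mildly into the p-arm of the same chromosome near the
boundary; the gained arm remains the maximal score by a wide margin in
all tested conditions.

## Marker and signature calls

The marker call intersects three sets — genes up versus all other tumor
clusters, up versus the sibling stem-like cluster, and genes on the
target arm — at `log2FC > 2`, `FDR < 0.01` (both configurable). An empty
intersection is a valid empty result. Signatures intersect an
epithelium-versus-other contrast with a subpopulation-versus-siblings
contrast at laxer defaults (`log2FC > 0.5`, `FDR < 0.01`): the first
contrast dilutes a subpopulation program by the cluster's share of the
epithelium, so demanding the marker-level fold there would discard true
program genes. Signature genes are ordered by descending fold in the
subpopulation contrast.

## Sample scoring and CSS assignment

A sample's signature score is the **median** log expression over the
signature genes present (median, not mean, because bulk expression is
skewed); at least 50% of the signature must be present (configurable),
missing genes are dropped with a logged warning. The CSS label is the
quadrant of the two scores relative to their cohort medians: strictly
greater counts as "high", ties are "low" — the strict rule keeps the
all-constant cohort well defined (everything CSS1). Median thresholding
makes the assignment invariant under strictly increasing transforms of
either score. When cohorts are pooled, `center_cohorts` applies
gene-wise zero-mean/unit-variance scaling within each cohort first, so
cohort-level location/scale differences do not drive the thresholds. The
combined predictor is `log LAPTM4B − log LGR5`, the monotone equivalent
of the expression ratio, so ROC/AUC and median dichotomization are
unaffected by the log.

## Survival and association statistics

Kaplan–Meier, log-rank, and Cox regression wrap lifelines; ties are
handled by the Breslow approximation (adequate at the tie rates the
generator produces). Separation and non-convergence are surfaced as
errors rather than silently returned. Fisher's exact test is two-sided
(sum of tables no more likely than observed), BH-corrected across genes;
mutation-burden contrasts use Welch's two-sided t-test with the
convention `t = 0, p = 1` for zero-variance equal-mean pairs. ROC/AUC
uses the Mann–Whitney identity with half-credit ties; the positive class
is recurrence and the direction of each predictor is recorded in the
output.

## Synthetic data: what it emulates, and what it does not

The single-cell generator draws negative-binomial counts (shape 2.0,
i.e. variance `μ + μ²/2`) — the minimal overdispersed count model — with
per-gene base means lognormally spread (σ = 1) around 0.5 to produce a
realistic expression-rank spectrum. Default conditions: 3,000 cells,
2,000 genes, six clusters (two stem-like, two non-stem tumor, two normal
epithelial), planted marker programs at 4-fold (marker base mean pinned
at 1.5 so folds are stable), 10% of genes on 8q, and a uniform 2×
mean shift on all 8q genes in the LAPTM4B-type cluster, which is also
restricted to MSS patients. The 8q gain is an expression-level stand-in,
not a DNA-level model — sufficient for an expression-inferred detector.
The quantitative size of the 8q expression shift in real tumors is not
established; the 2× default is a free parameter and is documented as
such.

The bulk generator adds the two program effects (defaults: 30 genes at
+1.0 log units for the LGR5 program; 8 genes at +1.5 for the LAPTM4B
program, the larger effect reflecting amplification-driven expression)
to Gaussian baseline log expression (noise σ = 0.6) in the four subtype
patterns, draws exponential survival with per-subtype log hazard ratios
(defaults 0.35, log 2.31, 0.45, 0 for CSS1–4, i.e. the LAPTM4B-dominant
subtype at HR 2.31 against the LGR5-dominant reference), uniform
censoring over (0, 36 months) for 25% of samples plus administrative
censoring at 36 months (≈ 44% events at the defaults), and Bernoulli
mutation indicators with subtype-specific frequencies (APC 0.84/0.78 in
the LGR5-enriched subtypes, TP53 0.75 in the LAPTM4B-dominant subtype,
with a hypermutated MSI-enriched CSS1 via per-subtype Poisson TMB means
45/10/10/10). All randomness flows from a single seed through
`SeedSequence` spawns, one stream per component, so editing one part of
a config does not perturb unrelated draws and identical configs are
bit-reproducible.

Not simulated: doublets, ambient RNA, batch effects, patient-level
expression correlation, read-level noise, copy-number heterogeneity
within a cluster, or informative censoring. Passing tests therefore
demonstrate correctness of the algorithms under their stated models, not
robustness to those real-data artifacts.

## Problem sizes and calibration checks

The test suite and the acceptance script use 20 seeded single-cell
simulations (3,000 × 2,000) for marker and arm-gain recovery, one
400-sample bulk cohort for CSS recovery, 50 seeds of a 600-sample
two-group cohort for Cox recovery of a planted HR 2.3, and 1,000
100-sample null replicates for log-rank type-I error — sizes at which
each check is statistically informative while the full suite stays fast.
One caveat worth stating: at n = 600 with ~44% events the sampling sd of
the Cox log-HR is ≈ 0.14, so the probability that any single estimate
falls in [1.8, 2.9] is ≈ 0.91; a 50-seed tally of that event is itself a
binomial draw and will occasionally dip below 45/50 even though the
estimator is unbiased (mean log HR 0.843 vs planted 0.833 over 200
replicates).

## Known limitations

- The arm scorer reports relative expression shifts; it cannot
  distinguish a copy-number gain from a coordinated transcriptional
  program on the same arm.
- CSS assignment depends on cohort composition through the medians: a
  cohort enriched for one subtype shifts the thresholds. This mirrors
  the cohort-relative definition of the classification itself.
- The packaged LGR5/LAPTM4B signature constants carry only the named
  published member genes; real analyses should derive or supply full
  lists.
- Cox fits use Breslow ties and Wald intervals; heavily tied or tiny
  cohorts deserve exact or Efron handling, which lifelines offers but
  this wrapper does not expose.
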