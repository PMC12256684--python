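# stemcss

Stem-like-cell signature scoring and CSS subtype stratification for
colorectal cancer (CRC) transcriptomics.

CRC tumors carry more than one stem-like cell population. Alongside the
canonical LGR5+ intestinal stem-cell compartment (WNT-driven), a second
stem-like population marked by *LAPTM4B* — MYC-associated, carrying a
chromosome-8q expression gain, and largely restricted to
microsatellite-stable (MSS) tumors — shapes prognosis in the opposite
direction. `stemcss` implements the analysis chain that identifies this
population's marker from single-cell data and turns both programs into a
clinically oriented four-way tumor classification:

1. **Ro/e enrichment** — for a cluster-by-group contingency table `N`,
   `Ro/e(i,j) = N_ij / E_ij` with `E_ij = N_i. N_.j / N_..`; values above 1
   mark enrichment beyond the marginal expectation.
2. **Differential expression** — per-gene two-sided Wilcoxon rank-sum on
   log-normalized expression (counts-per-10k, `log1p`), fold change on the
   de-logged scale, Benjamini–Hochberg FDR.
3. **Expression-inferred arm CNV** — reference-centered, clamped, moving-
   average-smoothed log2 expression averaged per chromosome arm; a
   simplified inferCNV sufficient to flag the 8q gain.
4. **Marker discovery** — the intersection
   `{up vs all other tumor clusters} ∩ {up vs the sibling stem-like
   cluster} ∩ {genes on 8q}` at `log2FC > 2`, `FDR < 0.01`.
5. **Stemness scoring** — an AUCell-style rank-based gene-set score: the
   normalized area under the recovery curve of signature genes within the
   top 5% of each cell's expression ranking.
6. **Signatures and CSS** — each stem-like signature is the intersection
   of two upregulation contrasts; samples are scored by the **median**
   log expression of signature genes, and the CRC stem-like subtype (CSS)
   is the quadrant relative to the cohort medians:
   CSS1 = low/low, CSS2 = LAPTM4B-dominant, CSS3 = high/high,
   CSS4 = LGR5-dominant.
7. **Outcome statistics** — Kaplan–Meier, log-rank, Cox proportional
   hazards (Breslow ties), per-gene Fisher mutation enrichment with BH,
   Welch t-tests of mutation burden, and the ROC/AUC of the combined
   predictor `log LAPTM4B − log LGR5` (the log of the expression ratio;
   higher predicts recurrence).

A seeded synthetic-data module generates single-cell, bulk, clinical, and
mutation datasets with planted ground truth for every stage, so the whole
chain is testable end to end without patient data.

## Worked example

Run the full pipeline on the default simulated conditions (3,000 cells /
2,000 genes single-cell layer; 400-sample bulk cohort):

```sh
$ stemcss --quiet run-all --seed 1 --outdir out/
subtype
CSS1     97
CSS2    103
CSS3     97
CSS4    103
Cox CSS2 vs CSS4: HR=2.677
                  predictor      auc positive_class
combined_laptm4b_minus_lgr5 0.589920     recurrence
                    laptm4b 0.597022     recurrence
              lgr5_inverted 0.519633     recurrence
```

The four subtype counts are near-balanced by construction (median
thresholds split each axis in half). The Cox hazard ratio contrasts the
LAPTM4B-dominant subtype (CSS2) against the LGR5-dominant subtype (CSS4)
on the simulated disease-free survival times, whose planted value is
2.31; the estimate at this seed and cohort size is 2.68. The AUC table is
descriptive output on the same 400-sample cohort, where recurrence is
only weakly coupled to single-gene expression; the controlled evaluation
of the combined predictor lives in the acceptance script below.
`out/markers.tsv` lists the recovered 8q markers (here the five planted
ones, led by `LAPTM4B`), and `out/provenance.yaml` records every
parameter needed to reproduce the run bit-for-bit.

The same stages are available as library calls (`simulate_sc`,
`diff_expr`, `call_cluster_marker`, `build_signature`, `score_samples`,
`assign_css`, `cox_fit`, ...) and as scikit-learn-style estimators
(`GeneSetAUCScorer`, `ArmGainScorer`, `SignatureScorer`,
`CSSClassifier`) that compose with sklearn pipelines.

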