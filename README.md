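# myelometh

DNA-methylation analysis of myeloid malignancies: differential
methylation with dual thresholds, cell-type deconvolution and
stable-CpG filtering, CpG-signature scoring, and bisulfite-amplicon
read-pattern statistics — with a ground-truthed synthetic cohort
generator that reproduces the central methodological problem of blood
methylomics: **cell-composition shifts masquerade as disease-intrinsic
methylation changes**.

## The problem

Illumina array methylomes of whole blood report, per CpG probe, a beta
value β ∈ [0, 1] (fraction of methylated alleles). A bulk blood sample
is a convex mixture of leukocyte-subset methylomes, so when a disease
such as primary myelofibrosis (PMF) expands granulocytes, thousands of
CpGs shift in bulk without any cell-intrinsic change. This package
implements the analysis toolkit for separating the two signals and for
deriving small diagnostic CpG signatures, aimed at computational
epigenetics researchers working on myeloproliferative neoplasms and
related malignancies (MDS, JMML, AML).

## Core methods

- **Differential methylation.** Per CpG, Δβ = mean β(disease) − mean
  β(control); a CpG is called hyper-/hypomethylated when |Δβ| > 0.20
  *and* the Benjamini–Hochberg adjusted two-sided Welch-t p-value is
  < 0.05 (both strict).
- **Stable-CpG filter.** From sorted leukocyte reference profiles, keep
  CpGs whose mean β differs by at most 0.10 between every pair of cell
  types ("did not exceed 0.10": inclusive). Composition-driven calls
  concentrate on the excluded probes.
- **Deconvolution.** Cell-type fractions f solve
  min‖β − S f‖² s.t. f ≥ 0, Σf = 1 (NNLS + simplex renormalization;
  exact constrained solve available), with S a marker-probe signature
  matrix.
- **Signature derivation and score.** Intersect significant CpGs of
  target-vs-each-other-disease with target-vs-healthy (per direction),
  drop CpGs that also differ between independent control sets, and score
  samples with the k hypomethylated survivors as **S = k − Σβ**; S > 1
  calls the target disease.
- **Amplicon patterns.** For bisulfite-amplicon reads over neighboring
  CpGs, exact epiallele tabulation, dominance/Shannon entropy, and a
  column-permutation Monte-Carlo test of CpG independence (clonality
  shows up as a dominant pattern the product-of-marginals null cannot
  produce).
- Plus: hypergeometric annotation enrichment, ±500 bp neighborhood Δβ
  profiles, linear epigenetic-clock application (delta-age), per-CpG
  allele-burden correlation.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on the
default synthetic cohort (7 groups × 20 samples, 2,000 CpGs, seed 7) and
write their tables under `results/`. For example:

```bash
cd analysis
python 01_simulate_cohort.py
python 05_signature_score.py
```

prints (abridged):

```
derived signature (5 CpGs): ['cg00000331', 'cg00000393', 'cg00000831', 'cg00001546', 'cg00001585']
planted target-specific hypo CpGs recovered: Jaccard = 1.00

score by group (threshold > 1 calls disease):
   group  n  mean   min   max  frac_positive
     AML 20 0.747 0.706 0.779            0.0
    JMML 20 0.749 0.731 0.779            0.0
     MDS 20 0.751 0.729 0.772            0.0
PMF-CALR 20 2.494 2.428 2.546            1.0
PMF-JAK2 20 2.504 2.469 2.546            1.0
 PMF-MPL 20 2.505 2.471 2.589            1.0
 control 40 0.751 0.729 0.781            0.0
AUC (PMF vs rest): 1.000
```

The cascade recovered exactly the five planted PMF-specific CpGs
(control-level β 0.85, planted effect −0.35): PMF samples score ≈ 2.5,
everything else ≈ 0.75, so the > 1 cutoff separates them perfectly.
`02` shows that driver-mutation subgroups (JAK2/CALR/MPL) are
indistinguishable pairwise while all differ from controls; `04` shows
the stable-CpG filter removing exactly the 200 cell-type-variable
probes driven by the granulocyte shift (0.50 → 0.80, recovered by
deconvolution to RMSE 0.003); `07` contrasts polyclonal
(independence p = 1.0, entropy ≈ 9 bits) with clonal amplicon reads
(dominance 0.34, p = 0.005).

A `mepipe` CLI mirrors the library (`mepipe simulate cohort`,
`mepipe dm run`, `mepipe ref filter`, `mepipe run --config pipeline.yaml`,
...).

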