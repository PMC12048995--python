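# Methods

## Data model

Beta values β ∈ [0, 1] are the fraction of methylated alleles at a CpG
probe; matrices are probes × samples with explicit `NA` missingness.
Probe IDs from newer array versions carry replicate suffixes
(`cg04470072_TC11`); harmonization strips the suffix when everything
after the first underscore matches `<2 letters><digits>`, which makes
the rule idempotent. If two replicates collapse onto one root, the
replicate with fewer missing values is kept (ties: lexicographically
first suffix). A probe is dropped from a dataset when more than 20% of
its samples are missing; otherwise comparisons use pairwise deletion.
Betas are clipped to [1e-6, 1 − 1e-6] before any logit transform.
Genomic positions are 1-based; windows are closed at both ends.

## Differential methylation

Per CpG, a two-sided Welch t-test on beta values between two groups,
with Benjamini–Hochberg adjustment across all testable probes (≥ 2
non-missing values per group). A CpG is classified hyper/hypo only if
|Δβ| > 0.20 **and** adjusted p < 0.05, both strict, matching how such
dual thresholds are normally printed ("> 20 %", "< 0.05"). Probes with
zero variance in both groups get p = 1 (never significant) to avoid
0/0. Welch + BH was chosen because the underlying study names only
"adjusted p-values"; both pieces are deliberately plain and
swappable (a moderated t or Bonferroni could be slotted in without
touching the thresholds). Δβ is mean(group2) − mean(group1); disease is
passed as group2 so hyper = higher in disease. `passes_delta_only`
records CpGs beyond the magnitude threshold irrespective of
significance (the "gray numbers" convention of scatter plots).

The transfer analysis re-evaluates a significant-CpG set in a second
dataset: per-CpG Δβ restricted to the set, per-direction stratum means,
and a one-way ANOVA across strata. The ANOVA factor is not defined in
the source material, so this package constructs it as
hyper-set vs hypo-set vs a random background stratum of matched size
(seeded draw from the remaining target probes) — an interpretation, and
flagged as such.

## Cell types: stable filter and deconvolution

The stable-CpG filter keeps probes whose per-type mean betas differ by
at most 0.10 between every pair of cell types. The boundary is
inclusive ("did not exceed 0.1"), and per-type *mean* profiles are used
(not per-profile extremes), following the description of pairwise
comparisons of mean values; the max-minus-min spread equals the maximum
pairwise difference, which is what the implementation computes. Probes
with a missing mean in any cell type cannot be certified stable and are
excluded.

Deconvolution solves min‖β − S f‖² on the probability simplex. The
default is non-negative least squares followed by renormalization to
Σf = 1 — transparent, fast, and exact on noiseless mixtures; an
equality-constrained SLSQP solve is available behind `solver="qp"`.
The marker ("signature") matrix takes, per cell type, the n probes
maximizing |mean(type) − mean of other types' means| (ties by probe
ID). Rank-deficient signatures raise an error naming the most collinear
pair of cell types.

## Regions

Neighborhood profiles resolve the "1 kb window" vs "500 bp window"
wording as a total window of 1 kb = ±500 bp around each seed CpG
(window and bin width are parameters). Signed distance is
neighbor − seed; a neighbor near several seeds counts once, at the
nearest seed (ties to the lower-position seed). Bins are closed toward
zero ([−w, −w+b), …, (w−b, w]), so a neighbor at exactly ±window is
included. Hyper and hypo seeds can be profiled pooled or separately.

Category enrichment is a one-sided hypergeometric over-representation
test (P[X ≥ k]) per annotation category with BH across categories;
depletion is available behind `direction="under"`.

## Clocks and covariates

A clock is a linear model over CpG betas: age = g⁻¹(Σ wⱼ βⱼ + b). The
Horvath-style transform g⁻¹(y) = (1+A)·e^y − 1 for y ≤ 0, (1+A)·y + A
otherwise, ships with configurable adult age A = 20. Published
coefficient sets are external works and are **not** redistributed; the
file format is defined and a synthetic demonstration clock is fit in
`analysis/06`. Per-sample missing clock probes are imputed with the
probe's cohort mean (common practice; the source is silent); probes
absent from the matrix entirely have no cohort mean and are imputed at
β = 0.5 with a warning, erroring above 50% absence. Allele-burden
correlation is per-CpG Pearson on complete pairs, with BH across
defined probes; probes with < 3 pairs or zero variance are flagged
undefined and excluded from adjustment.

## Signature

The cascade: per direction, intersect significant CpGs across every
target-vs-other-disease comparison; intersect with the same-direction
significant CpGs of target-vs-healthy (the *filtered*, cell-type-stable
comparison — the variant consistent with deriving disease-specific
CpGs); if a control-vs-control comparison is supplied, drop any CpG
significant in it (a mechanical encoding of the batch/array-version
exclusion rule). Hypo survivors form the signature; hyper survivors are
reported for inspection. The pipeline's control check splits the
control group in half deterministically.

The score is S = k − Σβ over the k signature CpGs; higher = less
methylated = more disease-like. Calls use strict S > 1 (the threshold
is treated as a given constant; how it was originally chosen is not
stated). A hyper-direction score would be the mirror image and is out
of the default path. Missing signature values are imputed at the
probe's cohort mean so scores stay comparable across array versions.
Evaluation reports per-group distributions, the exact rank-based
(Mann–Whitney, midranks for ties) AUC of target-vs-rest, and the
confusion table at the threshold.

## Amplicon patterns

Reads over an amplicon's CpGs are binary epialleles. Instead of an
unspecified heatmap clustering, the package tabulates exact pattern
frequencies (counts over reads; they sum to 1 exactly) and summarizes
dominance (top-pattern frequency), Shannon entropy in bits, and the
distinct-pattern count. The independence test asks whether CpG states
co-occur beyond their marginals: the statistic is the top-pattern
frequency, the null resamples by permuting each CpG column
independently (preserving marginals exactly), and the p-value is
(1 + #{null ≥ observed})/(B + 1) with B = 199 by default. The p-value
is valid by exchangeability and mildly conservative under ties;
constant read sets give p = 1 by construction.

## Synthetic cohort generator

The generator encodes the study conditions; its defaults are fixed and
are not tuning knobs.

* **Mixture.** Each sample's pre-noise profile is R·f with R the
  cell-type reference (probes × 6 leukocyte types) and f a per-sample
  Dirichlet composition. Controls center on a typical blood composition
  (granulocytes 0.50, monocytes 0.10, B 0.12, NK 0.06, CD4 0.14,
  CD8 0.08; concentration 100); disease groups are granulocyte-expanded
  (0.80), creating the composition confound the filter must remove.
* **Reference.** Baseline betas are bimodal (Beta(0.35, 0.35), clipped
  to [0.03, 0.97]). At cell-type-variable CpGs one randomly chosen type
  deviates from the shared baseline by a contrast drawn
  Uniform(0.4, 0.9) (a fixed contrast is used when no upper bound is
  configured) — marker-like structure with a graded spread, so the
  number of confounded delta-passing CpGs grows smoothly with the
  composition shift.
* **Planted effects.** Disease-intrinsic effects are additive on the
  beta scale (Δβ = 0.35 by default, matching how magnitude thresholds
  are stated) and applied per disease *entity*: pan-myeloid effects
  (30 hyper + 30 hypo) hit every disease sample; entity-specific
  effects (PMF 10 hyper + 5 hypo; MDS/JMML/AML 8 + 8) hit only their
  samples, with PMF effects shared across the JAK2/CALR/MPL subgroups.
  Planted baselines leave 0.1 headroom so effects are not clipped. The
  five PMF-specific hypo CpGs are the built-in signature: control-level
  β fixed at 0.85 with effect −0.35, so disease samples score ≈ 2.5 and
  everything else ≈ 0.75 against the > 1 cutoff.
* **Burden.** Mutation carriers draw an allele burden Uniform(26, 93) %
  (the reported clinical range); burden-linked CpGs gain
  0.4 × burden/100.
* **Noise.** Logit-normal: Gaussian sd 0.05 on the logit scale, keeping
  values in (0, 1) and mimicking array heteroskedasticity near the
  boundaries.
* **Metadata.** MDS samples are bone marrow, everything else peripheral
  blood; controls are generated for every tissue present. JMML ages are
  pediatric (1–15), other groups adult. Fixed seeds reproduce every
  output bit-exactly.

What the generator does *not* emulate: probe-level technical artifacts
(type I/II chemistry, cross-reactivity), correlated neighborhoods of
real DMRs, age- or sex-dependent drift, copy-number effects, and
realistic annotation–methylation coupling (region/island classes are
assigned independently of effects, so enrichment on synthetic data is
flat by design). Passing tests therefore certify the statistical
machinery and its behavior under composition confounding — not
performance on real arrays.

## Pipeline and problem sizes

The orchestrated run compares each disease entity against controls of
the same tissue (aborting with guidance when no tissue-matched controls
exist), filters on stable CpGs, builds overlap (Venn) tables per
direction, derives and scores the target signature, and runs the
covariate analyses. Identical config + seed gives byte-identical
outputs.

Default problem sizes — 2,000 CpGs, 20 samples per group, and test
replicate counts of 20–200 — were chosen so every statistical claim is
testable with comfortable margins at interactive runtimes; all
operations are vectorized and scale linearly in probes × samples, and
the thresholds (0.20/0.05/0.10/±500 bp/score 1.0) are the field's
printed values, exposed in one config object.

## Known limitations

No covariate-adjusted differential models (age/sex regression,
surrogate variables); no IDAT/raw-intensity preprocessing; no formal
DMR calling; the deconvolution is the transparent NNLS variant, not a
reimplementation of any specific published algorithm; the score is a
demonstration statistic, not a clinically validated classifier.
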