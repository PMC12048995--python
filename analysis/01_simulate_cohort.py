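#!/usr/bin/env python
"""Simulate the default study-condition cohort.

Seven groups (healthy controls in both tissues, PMF split by driver
mutation, MDS, JMML, AML), 20 samples each, 2,000 CpGs: cell-type
mixtures with a granulocyte-shifted composition in disease, planted
pan-myeloid and disease-specific effects (including the five PMF
signature CpGs at control beta 0.85), burden-linked CpGs, and
logit-normal noise.  Writes beta/samples/reference/truth/annotation TSVs
under results/cohort/.
"""

from common import COHORT_DIR, ensure_cohort

cfg, ref, beta, sheet, truth, annot = ensure_cohort()

print(f"cohort written to {COHORT_DIR}")
print(f"  {beta.shape[0]} CpGs x {beta.shape[1]} samples")
print(sheet.table.groupby(["group", "tissue"]).size().to_string())
print("\nplanted CpG roles:")
print(truth.labels.value_counts().to_string())
print(f"\nsignature CpGs (control beta {cfg.signature_base_beta}): "
      + ", ".join(sorted(truth.signature_probes)))
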