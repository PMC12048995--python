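#!/usr/bin/env python
"""Genomic context of the significant CpGs.

Hypergeometric over-representation of CpG-island and genomic-region
classes among the significant hyper-/hypomethylated CpGs (against the
full tested probe universe), plus the neighborhood delta-beta profile in
a 1 kb window (+/-500 bp) around the significant CpGs.  On synthetic
annotation the enrichment is expected to be flat (classes are assigned
independently of the planted effects) — the script demonstrates the
machinery and writes the tables.
"""

import myelometh as mm
from myelometh.differential import significant_set
from common import RESULTS, ensure_cohort, pooled_pmf_sheet

cfg, ref, beta, sheet, truth, annot = ensure_cohort()
out = RESULTS / "regions"
out.mkdir(parents=True, exist_ok=True)

res = mm.differential(beta, pooled_pmf_sheet(sheet), "control", "PMF")
bg = mm.CpGSet("background", frozenset(res.index[res["testable"]]))

for direction in ("hyper", "hypo"):
    fg = significant_set(res, direction)
    if not len(fg):
        print(f"no {direction} CpGs to test")
        continue
    for field in ("island_class", "region_class"):
        table = mm.hypergeometric_enrichment(fg, bg, annot, field)
        table.to_csv(out / f"enrichment_{direction}_{field}.tsv",
                     sep="\t", index=False, float_format="%.4g")
        top = table.sort_values("p_hyper").iloc[0]
        print(f"{direction}/{field}: most enriched category "
              f"{top['category']!r} (k={top['n_foreground_in_cat']}/"
              f"{top['n_foreground']}, p={top['p_hyper']:.3g})")

seeds = mm.CpGSet(
    "seeds",
    significant_set(res, "hyper").probe_ids | significant_set(res, "hypo").probe_ids,
)
prof = mm.neighborhood_profile(seeds, res, annot, window_bp=500, bin_bp=100)
prof.bins.to_csv(out / "neighborhood_profile.tsv", sep="\t", index=False,
                 na_rep="NA", float_format="%.5g")
print(f"\nneighborhood profile around {prof.n_seeds} seeds "
      f"({int(prof.bins['n_cpgs'].sum())} neighboring CpGs in the 1 kb window):")
print(prof.bins.to_string(index=False))
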