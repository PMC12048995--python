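#!/usr/bin/env python
"""Amplicon read-pattern statistics: polyclonal blood vs clonal colonies.

Simulates bisulfite-amplicon read sets over 26 neighboring CpGs: a
polyclonal sample (independent CpG states at intermediate rates, as in
patient blood) and a clonal sample (two dominant epialleles with a small
error rate, as in single-colony derived cells).  Pattern tabulation,
dominance/entropy, and the column-permutation independence test separate
the two regimes.
"""

import numpy as np
import pandas as pd

import myelometh as mm
from common import RESULTS

out = RESULTS / "amplicon"
out.mkdir(parents=True, exist_ok=True)

N_CPGS = 26
N_READS = 500
rng = np.random.default_rng(23)

poly = mm.generate_amplicon_reads(
    N_READS, N_CPGS, "independent", p=rng.uniform(0.3, 0.7, N_CPGS), seed=23
)
clones = rng.integers(0, 2, size=(2, N_CPGS))
clonal = mm.generate_amplicon_reads(
    N_READS, N_CPGS, "clonal", clones=clones, proportions=[0.6, 0.4],
    flip_rate=0.02, seed=24,
)

rows = []
for name, reads in (("polyclonal_blood", poly), ("clonal_colony", clonal)):
    table = mm.tabulate_patterns(reads)
    table.head(50).to_csv(out / f"patterns_{name}.tsv", sep="\t", index=False,
                          float_format="%.5g")
    stats = mm.pattern_statistics(table)
    p_indep = mm.independence_test(reads, n_permutations=199, seed=25)
    rows.append({
        "sample": name,
        "n_distinct_patterns": stats.n_distinct,
        "dominance": round(stats.dominance, 4),
        "entropy_bits": round(stats.shannon_entropy, 3),
        "independence_p": p_indep,
    })
    print(f"{name}: {stats.n_distinct} distinct patterns, "
          f"dominance {stats.dominance:.3f}, entropy {stats.shannon_entropy:.2f} "
          f"bits, independence p = {p_indep:.4f}")

pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
print("\nclonal samples show few dominant patterns (low entropy, tiny "
      "independence p); polyclonal samples look independent (p well above "
      "0.05, near-maximal diversity).")
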