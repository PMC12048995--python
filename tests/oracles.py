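"""Independent brute-force reference implementations used only by tests.

Each function here is deliberately naive (loops, enumeration, textbook
formulas) and shares no code with the package, so agreement is evidence
of correctness rather than repetition.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up, via sort + cumulative min."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def hypergeom_tail_enumerated(N, K, n, k):
    """P[X >= k] for X ~ Hypergeom(N, K, n) by counting draws."""
    total = comb(N, n)
    favorable = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return favorable / total


def stable_probes_double_loop(mean_beta, threshold):
    """Probe indices whose max pairwise cell-type difference <= threshold,
    via an explicit double loop over cell-type pairs."""
    n_probes, n_types = mean_beta.shape
    keep = []
    for i in range(n_probes):
        ok = True
        for a in range(n_types):
            for b in range(a + 1, n_types):
                va, vb = mean_beta[i, a], mean_beta[i, b]
                if np.isnan(va) or np.isnan(vb) or abs(va - vb) > threshold:
                    ok = False
        if ok:
            keep.append(i)
    return keep


def venn_counts(sets):
    """Membership-pattern -> count by scanning every element."""
    universe = set().union(*sets)
    out = {}
    for x in universe:
        key = tuple(x in s for s in sets)
        out[key] = out.get(key, 0) + 1
    return out


def welch_per_probe(x1, x2):
    """Per-probe two-sided Welch t-test via scipy, one probe at a time."""
    deltas, ps = [], []
    for row1, row2 in zip(x1, x2):
        a = row1[~np.isnan(row1)]
        b = row2[~np.isnan(row2)]
        deltas.append(b.mean() - a.mean())
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            ps.append(1.0)
        else:
            ps.append(float(stats.ttest_ind(b, a, equal_var=False).pvalue))
    return np.array(deltas), np.array(ps)


def pearson_naive(x, y):
    """Pearson r from the covariance formula, pure python."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / sqrt(vx * vy)


def mean_per_bin_bruteforce(seeds, neighbors, deltas, window, bin_bp):
    """Count in-window non-seed probes per signed-distance bin by scanning
    every (neighbor, seed) pair; bins closed toward zero."""
    n_half = window // bin_bp
    counts = [0] * (2 * n_half)
    sums = [0.0] * (2 * n_half)
    for pos, db in zip(neighbors, deltas):
        best = None
        for s in sorted(seeds):
            d = pos - s
            if best is None or abs(d) < abs(best):
                best = d
        if best is None or abs(best) > window:
            continue
        if best < 0:
            k = int(np.ceil(-best / bin_bp))
            idx = n_half - k
        else:
            k = max(1, int(np.ceil(best / bin_bp)))
            idx = n_half + k - 1
        counts[idx] += 1
        sums[idx] += db
    return counts, sums
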