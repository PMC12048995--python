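"""Neighborhood methylation profiles and hypergeometric category enrichment.

``neighborhood_profile`` asks whether differential methylation at a CpG
extends to its genomic neighbors: every non-seed probe within a window
(default +/-500 bp, i.e. a 1 kb total window) of a significant seed CpG is
binned by signed distance to its nearest seed and the mean delta-beta per
bin is reported.

``hypergeometric_enrichment`` tests over-representation of annotation
categories (genomic-region class, CpG-island class) among significant
CpGs against a background probe universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import CpGSet, bh_adjust
from .io import CpGAnnotation

__all__ = ["NeighborhoodProfile", "neighborhood_profile", "hypergeometric_enrichment"]


@dataclass
class NeighborhoodProfile:
    """Mean delta-beta of neighboring CpGs by signed distance to the
    nearest seed; ``bins`` has columns bin_lo, bin_hi, n_cpgs, mean_delta."""

    bins: pd.DataFrame
    window_bp: int
    bin_bp: int
    n_seeds: int


def _bin_index(d: float, window: int, bin_bp: int) -> int:
    """Map signed distance to a bin, bins closed toward zero.

    Negative side: [lo, hi) so that -window lands in the first bin;
    positive side: (lo, hi] so that +window lands in the last bin; d == 0
    goes to the first positive bin.
    """
    half = window // bin_bp
    if d < 0:
        k = int(np.ceil(-d / bin_bp))
        return half - k
    k = max(1, int(np.ceil(d / bin_bp)))
    return half + k - 1


def neighborhood_profile(
    seed_cpgs: CpGSet,
    results: pd.DataFrame,
    annotation: CpGAnnotation,
    window_bp: int = 500,
    bin_bp: int = 100,
) -> NeighborhoodProfile:
    """Profile delta-beta around seed CpGs.

    Every annotated non-seed probe in ``results`` lying on the same
    chromosome within +/-``window_bp`` (closed) of a seed is assigned the
    signed distance (neighbor - seed) to its *nearest* seed (ties to the
    lower-position seed) and its delta_beta accumulates into the covering
    bin.  Bins with no probes report a missing mean.
    """
    if not seed_cpgs.probe_ids:
        raise ValueError("no seed CpGs supplied")
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be a multiple of bin_bp")
    annot = annotation.table
    seeds = annot.loc[annot.index.intersection(list(seed_cpgs.probe_ids))]
    if seeds.empty:
        raise ValueError("no seed CpGs found in the annotation")

    n_bins = 2 * (window_bp // bin_bp)
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    others = results.index.difference(seeds.index)
    neighbors = annot.loc[annot.index.intersection(others)]
    for chrom, seed_chr in seeds.groupby("chromosome"):
        spos = np.sort(seed_chr["position"].to_numpy())
        nb = neighbors[neighbors["chromosome"] == chrom]
        if nb.empty:
            continue
        npos = nb["position"].to_numpy()
        idx = np.searchsorted(spos, npos)
        left = np.clip(idx - 1, 0, len(spos) - 1)
        right = np.clip(idx, 0, len(spos) - 1)
        dl = npos - spos[left]
        dr = npos - spos[right]
        # nearest seed; tie -> lower-position seed (the left one)
        use_left = np.abs(dl) <= np.abs(dr)
        d = np.where(use_left, dl, dr)
        within = np.abs(d) <= window_bp
        deltas = results.loc[nb.index, "delta_beta"].to_numpy()
        for dist, db in zip(d[within], deltas[within]):
            if np.isnan(db):
                continue
            b = _bin_index(float(dist), window_bp, bin_bp)
            sums[b] += db
            counts[b] += 1

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_cpgs": counts,
            "mean_delta": means,
        }
    )
    return NeighborhoodProfile(
        bins=bins, window_bp=window_bp, bin_bp=bin_bp, n_seeds=len(seeds)
    )


def hypergeometric_enrichment(
    foreground: CpGSet,
    background: CpGSet,
    annotation: CpGAnnotation,
    category_field: str,
    direction: str = "over",
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation categories.

    For each category with K background probes, the probability of drawing
    at least k of them in a foreground of size n from a universe of size N
    is P[X >= k] with X ~ Hypergeom(N, K, n); BH adjustment across
    categories.  ``direction='under'`` tests depletion (P[X <= k]) instead.
    """
    fg = foreground.probe_ids
    bg = background.probe_ids
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    annot = annotation.table
    cats = annot.loc[annot.index.intersection(list(bg)), category_field]
    N = len(bg)
    n = len(fg)
    rows = []
    for cat in sorted(cats.dropna().unique()):
        members = set(cats.index[cats == cat])
        K = len(members)
        k = len(fg & members)
        if direction == "over":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append(
            {
                "category": cat,
                "n_foreground_in_cat": k,
                "n_foreground": n,
                "n_background_in_cat": K,
                "n_background": N,
                "p_hyper": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category", "n_foreground_in_cat", "n_foreground",
            "n_background_in_cat", "n_background", "p_hyper",
        ],
    )
    out["p_adj"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    return out
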