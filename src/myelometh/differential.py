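"""Per-CpG two-group differential methylation with dual thresholds.

A CpG is called hyper- or hypomethylated only when both conditions hold:
the group-mean beta difference exceeds a magnitude threshold (default
|dbeta| > 0.20) *and* the Benjamini-Hochberg adjusted p-value of a
two-sided Welch t-test falls below alpha (default 0.05).  Probes crossing
only the magnitude threshold are flagged separately
(``passes_delta_only``), mirroring how such CpGs are usually reported
alongside the significant ones.

Results are returned as a DataFrame with one row per probe (columns
``delta_beta, p_raw, p_adj, n1, n2, class, passes_delta_only, testable``),
where ``delta_beta = mean(group2) - mean(group1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleSheet

__all__ = [
    "CpGSet",
    "differential",
    "bh_adjust",
    "pairwise_comparisons",
    "set_overlap",
    "significant_set",
    "transfer_set_analysis",
    "TransferResult",
]

RESULT_COLUMNS = [
    "delta_beta", "p_raw", "p_adj", "n1", "n2",
    "class", "passes_delta_only", "testable",
]


@dataclass(frozen=True)
class CpGSet:
    """A named set of probes with a direction label (hyper/hypo/mixed)."""

    name: str
    probe_ids: frozenset
    direction: str = "mixed"

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo", "mixed"):
            raise ValueError(f"bad direction {self.direction!r}")
        object.__setattr__(self, "probe_ids", frozenset(self.probe_ids))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _welch(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized two-sided Welch t-test over rows; NaNs dropped pairwise.

    Rows where both groups have zero variance get p = 1 (never significant).
    Returns (delta, p, n1, n2, testable).
    """
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        n1 = np.sum(~np.isnan(x1), axis=1)
        n2 = np.sum(~np.isnan(x2), axis=1)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
    testable = (n1 >= 2) & (n2 >= 2)
    delta = m2 - m1
    se2 = np.where(testable, v1 / np.maximum(n1, 1) + v2 / np.maximum(n2, 1), np.nan)
    p = np.full(x1.shape[0], np.nan)
    degenerate = testable & (se2 == 0)
    ok = testable & (se2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta[ok] / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1[ok]) ** 2 / (n1[ok] - 1) + (v2[ok] / n2[ok]) ** 2 / (n2[ok] - 1)
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 1.0
    return delta, p, n1, n2, testable


def differential(
    beta: BetaMatrix,
    sheet: SampleSheet,
    group1: str,
    group2: str,
    delta_threshold: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG Welch t-test + BH between two sample groups.

    ``delta_beta = mean(group2) - mean(group1)``; with controls as group1
    and disease as group2, hyper means higher in disease.  Strict
    inequalities at both thresholds.
    """
    if not (0 < delta_threshold < 1 and 0 < alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    s1 = sheet.samples_in_group(group1)
    s2 = sheet.samples_in_group(group2)
    s1 = [s for s in s1 if s in beta.values.columns]
    s2 = [s for s in s2 if s in beta.values.columns]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(s1)} in {group1!r} "
            f"and {len(s2)} in {group2!r}"
        )
    x1 = beta.values[s1].to_numpy(dtype=float)
    x2 = beta.values[s2].to_numpy(dtype=float)
    delta, p, n1, n2, testable = _welch(x1, x2)

    p_adj = np.full_like(p, np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(p[testable])

    klass = np.full(len(delta), "ns", dtype=object)
    sig = testable & (p_adj < alpha)
    klass[sig & (delta > delta_threshold)] = "hyper"
    klass[sig & (delta < -delta_threshold)] = "hypo"
    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "p_raw": p,
            "p_adj": p_adj,
            "n1": n1,
            "n2": n2,
            "class": klass,
            "passes_delta_only": np.abs(delta) > delta_threshold,
            "testable": testable,
        },
        index=beta.values.index,
    )
    out.index.name = "probe_id"
    return out


def significant_set(results: pd.DataFrame, direction: str, name: str = "") -> CpGSet:
    """Extract the hyper or hypo significant probes as a CpGSet."""
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    probes = frozenset(results.index[results["class"] == direction])
    return CpGSet(name or direction, probes, direction)


def pairwise_comparisons(
    beta: BetaMatrix,
    sheet: SampleSheet,
    groups: Sequence[str],
    delta_threshold: float = 0.20,
    alpha: float = 0.05,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Differential results for every unordered group pair.

    Keys are alphabetically ordered tuples; delta_beta is oriented as
    mean(second) - mean(first) of the sorted pair, so the sign convention
    is deterministic.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for g1, g2 in combinations(sorted(groups), 2):
        out[(g1, g2)] = differential(beta, sheet, g1, g2, delta_threshold, alpha)
    return out


def set_overlap(sets: Sequence[CpGSet]) -> tuple[pd.DataFrame, CpGSet]:
    """Venn partition of >=2 CpG sets.

    Returns a table with one row per non-empty membership pattern
    (boolean column per set, plus ``count``) and the full intersection.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        names = [f"{s.name}_{i}" for i, s in enumerate(sets)]
    universe = set().union(*(s.probe_ids for s in sets))
    patterns: dict[tuple[bool, ...], int] = {}
    for probe in universe:
        key = tuple(probe in s.probe_ids for s in sets)
        patterns[key] = patterns.get(key, 0) + 1
    rows = []
    for key in sorted(patterns, reverse=True):
        rows.append({**dict(zip(names, key)), "count": patterns[key]})
    table = pd.DataFrame(rows, columns=[*names, "count"])
    inter = frozenset.intersection(*(s.probe_ids for s in sets))
    directions = {s.direction for s in sets}
    direction = directions.pop() if len(directions) == 1 else "mixed"
    return table, CpGSet("intersection", inter, direction)


@dataclass
class TransferResult:
    """CpG-set transfer analysis: a significant-CpG set from one comparison
    re-evaluated in another dataset."""

    per_cpg: pd.DataFrame          # probe_id, stratum, delta_beta
    stratum_means: dict            # stratum -> mean delta_beta
    anova_p: float


def transfer_set_analysis(
    source_sets: Sequence[CpGSet] | CpGSet,
    target_beta: BetaMatrix,
    target_sheet: SampleSheet,
    group_a: str,
    group_b: str,
    seed: int = 0,
) -> TransferResult:
    """Re-evaluate source CpG sets in a second dataset.

    Per-CpG delta_beta (mean(group_b) - mean(group_a)) is computed in the
    target for each source stratum (e.g. hyper-set and hypo-set) and for a
    random background stratum of matched size drawn from the remaining
    target probes; a one-way ANOVA compares the per-CpG delta distributions
    across strata.
    """
    if isinstance(source_sets, CpGSet):
        source_sets = [source_sets]
    target_probes = set(target_beta.probe_ids)
    strata: dict[str, list[str]] = {}
    for s in source_sets:
        common = sorted(s.probe_ids & target_probes)
        if not common:
            raise ValueError(f"source set {s.name!r} shares no probes with the target")
        strata[s.name] = common

    used = set().union(*(set(v) for v in strata.values()))
    pool = sorted(target_probes - used)
    bg_size = int(round(np.mean([len(v) for v in strata.values()])))
    rng = np.random.default_rng(seed)
    if pool and bg_size:
        bg = sorted(rng.choice(pool, size=min(bg_size, len(pool)), replace=False))
        strata["background"] = bg

    sa = target_sheet.samples_in_group(group_a)
    sb = target_sheet.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >=2 target samples per group")
    ma = target_beta.values[sa].mean(axis=1, skipna=True)
    mb = target_beta.values[sb].mean(axis=1, skipna=True)
    delta = mb - ma

    rows = []
    groups_for_anova = []
    means = {}
    for name, probes in strata.items():
        d = delta.loc[probes].dropna()
        rows.append(pd.DataFrame({"stratum": name, "delta_beta": d}))
        means[name] = float(d.mean()) if len(d) else float("nan")
        if len(d) >= 2:
            groups_for_anova.append(d.to_numpy())
    per_cpg = pd.concat(rows)
    per_cpg.index.name = "probe_id"
    if len(groups_for_anova) >= 2:
        anova_p = float(stats.f_oneway(*groups_for_anova).pvalue)
    else:
        anova_p = float("nan")
    return TransferResult(per_cpg=per_cpg, stratum_means=means, anova_p=anova_p)
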