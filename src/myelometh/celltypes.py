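"""Cell-type reference profiles, the stable-CpG filter, and deconvolution.

Bulk blood methylomes are convex mixtures of leukocyte-subset methylomes,
so group differences in cell composition masquerade as differential
methylation.  Two remedies are implemented here:

* the *stable-CpG filter*: keep only CpGs whose mean beta differs by at
  most a threshold (default 0.10, inclusive) between every pair of sorted
  leukocyte subsets, removing composition-driven signal;
* *reference-based deconvolution*: estimate each sample's cell-type
  fractions by non-negative least squares against subset mean profiles,
  renormalized onto the probability simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .differential import CpGSet
from .io import BetaMatrix, ParseError, _FLOAT_FMT, _sep_for

__all__ = [
    "CellTypeReference",
    "DeconvolutionResult",
    "read_reference",
    "write_reference",
    "stable_cpg_filter",
    "apply_stable_filter",
    "build_signature_matrix",
    "estimate_fractions",
    "estimate_fractions_matrix",
]


@dataclass
class CellTypeReference:
    """Mean beta profiles of sorted cell types.

    ``mean_beta``: DataFrame probes x cell types, values in [0, 1].
    ``n_profiles_per_type``: how many sorted-cell methylomes each column
    mean was computed from (informational).
    """

    mean_beta: pd.DataFrame
    n_profiles_per_type: dict | None = None

    def __post_init__(self) -> None:
        df = self.mean_beta
        if df.shape[1] < 2:
            raise ValueError("reference needs at least two cell types")
        arr = df.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ParseError("reference beta values must lie in [0, 1]")
        self.mean_beta = df.astype(float)

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_beta.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.mean_beta.index)


def read_reference(path: str | Path) -> CellTypeReference:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id'")
    return CellTypeReference(df.set_index("probe_id"))


def write_reference(ref: CellTypeReference, path: str | Path) -> None:
    ref.mean_beta.to_csv(
        path, sep=_sep_for(path), na_rep="NA", index_label="probe_id",
        float_format=_FLOAT_FMT,
    )


def stable_cpg_filter(reference: CellTypeReference, threshold: float = 0.10) -> CpGSet:
    """CpGs whose mean beta does not differ by more than ``threshold``
    between any pair of cell types (inclusive boundary: a maximum pairwise
    difference of exactly ``threshold`` is retained).

    Probes with a missing mean in any cell type cannot be certified stable
    and are excluded.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    df = reference.mean_beta
    spread = df.max(axis=1) - df.min(axis=1)  # == max pairwise |difference|
    ok = spread.notna() & (spread <= threshold) & df.notna().all(axis=1)
    return CpGSet("stable", frozenset(df.index[ok]), "mixed")


def apply_stable_filter(
    results: pd.DataFrame, stable: CpGSet
) -> tuple[pd.DataFrame, dict]:
    """Restrict a differential-result table to cell-type-stable probes.

    Returns the filtered table plus before/after counts of hyper and hypo
    calls (the quantity the filter is meant to shrink when composition,
    not disease, drives the signal).
    """
    keep = results.index.isin(stable.probe_ids)
    filtered = results.loc[keep]
    counts = {
        "n_before": int(len(results)),
        "n_after": int(len(filtered)),
        "hyper_before": int((results["class"] == "hyper").sum()),
        "hypo_before": int((results["class"] == "hypo").sum()),
        "hyper_after": int((filtered["class"] == "hyper").sum()),
        "hypo_after": int((filtered["class"] == "hypo").sum()),
    }
    return filtered, counts


def build_signature_matrix(
    reference: CellTypeReference, n_per_type: int
) -> CellTypeReference:
    """Reduce a reference to its most discriminative marker probes.

    For each cell type, the ``n_per_type`` probes maximizing
    |mean(type) - mean of the other types' means| are selected (ties broken
    by probe ID); the union over types forms the signature matrix.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    df = reference.mean_beta
    if n_per_type > len(df):
        warnings.warn(
            f"n_per_type={n_per_type} exceeds probe count {len(df)}; using all probes"
        )
        return CellTypeReference(df.copy(), reference.n_profiles_per_type)
    selected: set[str] = set()
    k = len(df.columns)
    for ct in df.columns:
        others = df.drop(columns=ct).mean(axis=1)
        contrast = (df[ct] - others).abs()
        ranked = contrast.sort_index().sort_values(ascending=False, kind="stable")
        selected.update(ranked.index[:n_per_type])
    probes = sorted(selected)
    return CellTypeReference(df.loc[probes].copy(), reference.n_profiles_per_type)


@dataclass
class DeconvolutionResult:
    """Estimated cell-type fractions for one sample (nonnegative, sum 1)."""

    sample_id: str
    fractions: pd.Series
    residual_rmse: float


def _check_rank(S: np.ndarray, cell_types: Sequence[str]) -> None:
    if np.linalg.matrix_rank(S) < S.shape[1]:
        # name the most collinear pair to make the error actionable
        C = np.corrcoef(S.T)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
        raise ValueError(
            "signature matrix is rank deficient; most collinear cell types: "
            f"{cell_types[i]!r} and {cell_types[j]!r}"
        )


def estimate_fractions(
    sample_beta: pd.Series,
    signature: CellTypeReference,
    solver: str = "nnls",
    sample_id: str = "",
) -> DeconvolutionResult:
    """Estimate cell-type fractions for one bulk methylome.

    Solves min ||beta - S f||^2 over the simplex (f >= 0, sum f = 1).
    ``solver='nnls'`` (default): non-negative least squares followed by
    renormalization onto the simplex.  ``solver='qp'``: exact
    equality-constrained solve via SLSQP.
    """
    shared = signature.mean_beta.index.intersection(sample_beta.index)
    y = sample_beta.loc[shared]
    S = signature.mean_beta.loc[shared]
    mask = y.notna() & S.notna().all(axis=1)
    y = y[mask].to_numpy(dtype=float)
    Sm = S[mask].to_numpy(dtype=float)
    k = Sm.shape[1]
    if len(y) < k:
        raise ValueError(
            f"only {len(y)} usable shared probes for {k} cell types"
        )
    _check_rank(Sm, signature.cell_types)
    if solver == "nnls":
        f, _ = optimize.nnls(Sm, y)
        total = f.sum()
        if total <= 0:
            raise ValueError("NNLS returned an all-zero fraction vector")
        f = f / total
    elif solver == "qp":
        x0 = np.full(k, 1.0 / k)
        res = optimize.minimize(
            lambda f: float(np.sum((Sm @ f - y) ** 2)),
            x0,
            jac=lambda f: 2.0 * Sm.T @ (Sm @ f - y),
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        f = np.clip(res.x, 0.0, None)
        f = f / f.sum()
    else:
        raise ValueError(f"unknown solver {solver!r}")
    rmse = float(np.sqrt(np.mean((Sm @ f - y) ** 2)))
    fractions = pd.Series(f, index=signature.cell_types, name=sample_id or None)
    return DeconvolutionResult(sample_id=sample_id, fractions=fractions, residual_rmse=rmse)


def estimate_fractions_matrix(
    beta: BetaMatrix, signature: CellTypeReference, solver: str = "nnls"
) -> pd.DataFrame:
    """Deconvolve every sample; rows = samples, columns = cell types plus
    ``residual_rmse``."""
    rows = {}
    for sid in beta.sample_ids:
        res = estimate_fractions(beta.values[sid], signature, solver=solver, sample_id=sid)
        rows[sid] = pd.concat([res.fractions, pd.Series({"residual_rmse": res.residual_rmse})])
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out
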