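"""Data containers and delimited-text IO for methylation analysis.

The central object is the :class:`BetaMatrix`: CpG probes x samples with
methylation beta values in [0, 1] (fraction methylated).  Sample metadata
travels in a :class:`SampleSheet`, probe genomic context in a
:class:`CpGAnnotation`.  All files are plain TSV/CSV with ``NA`` as the
missing marker; see the module-level readers/writers.

Probe identifiers from newer array versions carry replicate suffixes
(e.g. ``cg04470072_TC11``); :func:`normalize_probe_id` strips them so
probe sets can be intersected across array versions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "ParseError",
    "normalize_probe_id",
    "normalize_probes",
    "intersect_probes",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
]

#: replicate suffix on EPIC v2-style probe IDs: underscore + 2 letters + digits
_REPLICATE_SUFFIX = re.compile(r"^[A-Za-z]{2}\d+$")

#: beta values are clipped into this open interval before logit transforms
BETA_EPS = 1e-6

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def normalize_probe_id(raw_id: str) -> str:
    """Return the probe root, stripping an array-replicate suffix if present.

    ``cg04470072_TC11`` -> ``cg04470072``: when everything after the first
    underscore matches ``<2 letters><digits>``, the prefix is returned;
    otherwise the ID is returned unchanged.  Idempotent.
    """
    if not raw_id:
        raise ValueError("probe ID must be non-empty")
    root, sep, rest = raw_id.partition("_")
    if sep and root and _REPLICATE_SUFFIX.match(rest):
        return root
    return raw_id


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values.

    ``values`` is a DataFrame indexed by probe ID with sample-ID columns;
    entries are floats in [0, 1] or NaN (missing).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate probe IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ParseError("duplicate sample IDs in beta matrix")
        arr = df.to_numpy(dtype=float)
        bad = np.where((arr < 0) | (arr > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ParseError(
                f"beta value out of [0,1] at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {arr[i, j]}"
            )
        self.values = df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)])

    def clipped(self, eps: float = BETA_EPS) -> pd.DataFrame:
        """Values clipped into [eps, 1-eps], for logit transforms."""
        return self.values.clip(lower=eps, upper=1.0 - eps)


_SHEET_COLUMNS = ["group", "mutation", "allele_burden", "age_years", "tissue", "batch"]


@dataclass
class SampleSheet:
    """Per-sample metadata: group, driver mutation, allele burden (%),
    age (years), tissue (PB/BM), batch.  Indexed by sample ID."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"sample sheet missing columns: {missing}")
        if df.index.has_duplicates:
            raise ParseError("duplicate sample IDs in sample sheet")
        burden = pd.to_numeric(df["allele_burden"], errors="coerce")
        if ((burden < 0) | (burden > 100)).any():
            bad = df.index[(burden < 0) | (burden > 100)][0]
            raise ParseError(f"allele_burden outside [0,100] for sample {bad!r}")
        age = pd.to_numeric(df["age_years"], errors="coerce")
        if (age < 0).any():
            raise ParseError("negative age_years in sample sheet")
        df = df.copy()
        df["allele_burden"] = burden.astype(float)
        df["age_years"] = age.astype(float)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def validate_against(self, beta: BetaMatrix) -> None:
        """Every matrix sample must have a metadata row."""
        missing = sorted(set(beta.sample_ids) - set(self.sample_ids))
        if missing:
            raise ParseError(f"samples absent from sample sheet: {missing}")


_ANNOT_COLUMNS = ["chromosome", "position", "region_class", "island_class", "gene"]


@dataclass
class CpGAnnotation:
    """Genomic context per probe: chromosome, 1-based position, genomic-region
    class (promoter/gene body/intergenic...), CpG-island class, gene."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"annotation missing columns: {missing}")
        if df.index.has_duplicates:
            raise ParseError("duplicate probe IDs in annotation")
        pos = pd.to_numeric(df["position"], errors="raise")
        if (pos <= 0).any():
            raise ParseError("annotation positions must be positive (1-based)")
        df = df.copy()
        df["position"] = pos.astype(int)
        self.table = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)


def normalize_probes(beta: BetaMatrix) -> BetaMatrix:
    """Strip replicate suffixes from all probe IDs.

    If two replicates collapse onto one root, the replicate with fewer
    missing values wins; ties go to the lexicographically first suffix.
    """
    df = beta.values
    roots = pd.Index([normalize_probe_id(p) for p in df.index])
    if not roots.has_duplicates:
        out = df.copy()
        out.index = roots
        return BetaMatrix(out)
    n_missing = df.isna().sum(axis=1).to_numpy()
    order = pd.DataFrame(
        {"root": roots, "n_missing": n_missing, "raw": df.index},
    ).sort_values(["root", "n_missing", "raw"], kind="stable")
    keep_raw = order.drop_duplicates("root", keep="first")["raw"]
    out = df.loc[keep_raw].copy()
    out.index = [normalize_probe_id(p) for p in out.index]
    return BetaMatrix(out.sort_index())


def intersect_probes(
    matrices: Sequence[BetaMatrix], max_missing_frac: float = 0.20
) -> list[BetaMatrix]:
    """Restrict every matrix to the common probe set, in canonical order.

    A probe is first dropped from a dataset when more than
    ``max_missing_frac`` of its samples are missing there; the intersection
    is taken over the surviving per-dataset probe sets and returned sorted.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    kept_sets = []
    for bm in matrices:
        frac_missing = bm.values.isna().mean(axis=1)
        kept_sets.append(set(bm.values.index[frac_missing <= max_missing_frac]))
    common = set.intersection(*kept_sets)
    if not common:
        raise ValueError("probe intersection across datasets is empty")
    order = sorted(common)
    return [bm.subset_probes(order) for bm in matrices]


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric beta value in sample column {col!r}") from exc
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.values.to_csv(
        path, sep=_sep_for(path), na_rep="NA", index_label="probe_id",
        float_format=_FLOAT_FMT,
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs a 'sample_id' column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(
        path, sep=_sep_for(path), na_rep="NA", index_label="sample_id",
        float_format=_FLOAT_FMT,
    )


def read_annotation(path: str | Path) -> CpGAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: annotation needs a 'probe_id' column")
    return CpGAnnotation(df.set_index("probe_id"))


def write_annotation(annot: CpGAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="probe_id")
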