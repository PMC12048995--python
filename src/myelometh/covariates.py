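"""Epigenetic-clock application and allele-burden correlation.

An epigenetic clock is a linear model over CpG beta values predicting
chronological age; the difference between predicted and chronological age
is the *delta-age*.  Clock coefficient files are user-supplied (published
coefficient sets are external works and are not shipped); the file format
and a Horvath-style piecewise log/linear age transform are provided.

``correlate_with_burden`` relates per-CpG methylation to the driver-
mutation allele burden (variant allele frequency, a proxy for malignant
clone size) by Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import BetaMatrix, ParseError, SampleSheet, _sep_for

__all__ = [
    "ClockModel",
    "read_clock",
    "write_clock",
    "apply_linear_clock",
    "correlate_with_burden",
]


@dataclass
class ClockModel:
    """Linear age predictor: age_transform^{-1}(intercept + sum w_j beta_j).

    ``transform='identity'`` predicts age directly; ``'log-linear'`` is the
    Horvath-style piecewise form, where the linear predictor y maps to
    (1 + adult_age) * exp(y) - 1 for y <= 0 and
    (1 + adult_age) * y + adult_age for y > 0.
    """

    name: str
    coefficients: pd.Series  # probe_id -> weight
    intercept: float = 0.0
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("clock needs at least one coefficient")
        if self.transform not in ("identity", "log-linear"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        if self.transform == "identity":
            return np.asarray(y, dtype=float)
        y = np.asarray(y, dtype=float)
        a = self.adult_age
        return np.where(y <= 0, (1 + a) * np.exp(y) - 1, (1 + a) * y + a)


def read_clock(path: str | Path) -> ClockModel:
    """Clock TSV: '#key<TAB>value' header lines (name, intercept, transform,
    adult_age) followed by a probe_id/weight table."""
    meta = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("\t")
            meta[key] = value
            header_lines += 1
    df = pd.read_csv(path, sep=_sep_for(path), skiprows=header_lines)
    if list(df.columns[:2]) != ["probe_id", "weight"]:
        raise ParseError(f"{path}: clock table needs columns probe_id, weight")
    coef = pd.Series(df["weight"].to_numpy(dtype=float), index=df["probe_id"])
    return ClockModel(
        name=meta.get("name", Path(path).stem),
        coefficients=coef,
        intercept=float(meta.get("intercept", 0.0)),
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


def write_clock(clock: ClockModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{clock.name}\n")
        fh.write(f"#intercept\t{clock.intercept!r}\n")
        fh.write(f"#transform\t{clock.transform}\n")
        fh.write(f"#adult_age\t{clock.adult_age!r}\n")
        fh.write("probe_id\tweight\n")
        for pid, w in clock.coefficients.items():
            fh.write(f"{pid}\t{w!r}\n")


def apply_linear_clock(
    beta: BetaMatrix, clock: ClockModel, sheet: SampleSheet | None = None
) -> pd.DataFrame:
    """Predict epigenetic age per sample; delta_age where chronological age
    is available in the sample sheet.

    Per-sample missing values at clock probes are imputed with the probe's
    cohort mean.  Probes absent from the matrix entirely are imputed at
    beta 0.5 with a warning; more than 50% absent is an error.
    """
    probes = clock.coefficients.index
    present = probes.intersection(beta.values.index)
    absent = probes.difference(beta.values.index)
    if len(absent) * 2 > len(probes):
        raise ValueError(
            f"{len(absent)}/{len(probes)} clock probes absent from the matrix: "
            f"{sorted(absent)[:10]}..."
        )
    X = beta.values.reindex(probes)
    if len(absent):
        warnings.warn(
            f"{len(absent)} clock probes absent from the matrix; imputed at beta 0.5"
        )
        X.loc[absent] = 0.5
    cohort_mean = X.mean(axis=1, skipna=True).fillna(0.5)
    X = X.apply(lambda col: col.fillna(cohort_mean))
    y = clock.coefficients.reindex(probes).to_numpy() @ X.to_numpy() + clock.intercept
    predicted = clock.inverse_transform(y)
    out = pd.DataFrame({"predicted_age": predicted}, index=beta.sample_ids)
    out.index.name = "sample_id"
    if sheet is not None:
        chrono = sheet.table["age_years"].reindex(out.index)
        out["chronological_age"] = chrono
        out["delta_age"] = out["predicted_age"] - chrono
    return out


def correlate_with_burden(
    beta: BetaMatrix, sheet: SampleSheet, value_field: str = "allele_burden"
) -> pd.DataFrame:
    """Per-CpG Pearson correlation of beta with a numeric sample covariate.

    Complete pairs only; probes with fewer than 3 complete pairs or zero
    variance are flagged undefined and excluded from the BH adjustment.
    Columns: r, p_raw, p_adj, n, defined.
    """
    x = pd.to_numeric(sheet.table[value_field], errors="coerce").reindex(
        beta.sample_ids
    ).to_numpy(dtype=float)
    if np.sum(~np.isnan(x)) < 3:
        warnings.warn("fewer than 3 samples with a non-missing covariate")
    B = beta.values.to_numpy(dtype=float)
    M = ~np.isnan(B) & ~np.isnan(x)[None, :]
    n = M.sum(axis=1)

    Bm = np.where(M, B, 0.0)
    Xm = np.where(M, x[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nb = np.maximum(n, 1)
        mb = Bm.sum(axis=1) / nb
        mx = Xm.sum(axis=1) / nb
        cov = (Bm * Xm).sum(axis=1) / nb - mb * mx
        vb = (Bm**2).sum(axis=1) / nb - mb**2
        vx = (Xm**2).sum(axis=1) / nb - mx**2
        r = cov / np.sqrt(vb * vx)
    defined = (n >= 3) & np.isfinite(r)
    r = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)
    p = np.full(len(r), np.nan)
    ok = defined & (np.abs(r) < 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r[ok] * np.sqrt((n[ok] - 2) / (1.0 - r[ok] ** 2))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), n[ok] - 2)
    p[defined & (np.abs(r) >= 1.0)] = 0.0
    p_adj = np.full(len(r), np.nan)
    if defined.any():
        p_adj[defined] = bh_adjust(p[defined])
    out = pd.DataFrame(
        {"r": r, "p_raw": p, "p_adj": p_adj, "n": n, "defined": defined},
        index=beta.values.index,
    )
    out.index.name = "probe_id"
    return out
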