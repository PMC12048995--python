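"""Disease-specific CpG signature derivation and scoring.

The signature is derived by an intersection cascade: CpGs significantly
hypo-/hypermethylated in the target disease versus *every* other disease
are intersected with the same-direction significant CpGs of the
target-versus-healthy comparison; CpGs that are also significant in an
independent control-versus-control comparison (a batch/array-version
red flag) are excluded.

The resulting k-CpG score for a sample is ``S = k - sum of the k beta
values`` (hypomethylation raises the score); samples with S strictly
above a decision threshold (default 1.0) are called positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import BetaMatrix, SampleSheet

__all__ = [
    "SignatureDefinition",
    "DerivedSignature",
    "EmptySignatureError",
    "derive_signature",
    "compute_score",
    "evaluate_score",
    "ScoreEvaluation",
    "read_signature",
    "write_signature",
]


class EmptySignatureError(ValueError):
    """The intersection cascade left no CpGs."""


def read_signature(path) -> "SignatureDefinition":
    """Signature TSV: '#key<TAB>value' header (name, direction, threshold)
    followed by one probe ID per line."""
    meta = {}
    probes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
            elif line != "probe_id":
                probes.append(line)
    return SignatureDefinition(
        name=meta.get("name", "signature"),
        probe_ids=tuple(probes),
        direction=meta.get("direction", "hypo"),
        score_threshold=float(meta.get("threshold", 1.0)),
    )


def write_signature(sig: "SignatureDefinition", path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{sig.name}\n")
        fh.write(f"#direction\t{sig.direction}\n")
        fh.write(f"#threshold\t{sig.score_threshold!r}\n")
        fh.write("probe_id\n")
        for p in sig.probe_ids:
            fh.write(p + "\n")


@dataclass(frozen=True)
class SignatureDefinition:
    """An ordered k-CpG signature with its decision threshold."""

    name: str
    probe_ids: tuple
    direction: str = "hypo"
    score_threshold: float = 1.0

    def __post_init__(self):
        if len(self.probe_ids) < 1:
            raise ValueError("signature needs at least one probe")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("signature probes must be unique")

    @property
    def k(self) -> int:
        return len(self.probe_ids)


@dataclass
class DerivedSignature:
    """Cascade output: the hypo-direction signature plus the hyper-direction
    survivors (reported for inspection) and per-step set sizes."""

    signature: SignatureDefinition
    hyper_probes: tuple
    steps: dict


def _sig_probes(results: pd.DataFrame, direction: str) -> set:
    return set(results.index[results["class"] == direction])


def derive_signature(
    target_vs_others: Mapping[str, pd.DataFrame],
    target_vs_healthy: pd.DataFrame,
    control_check: pd.DataFrame | None = None,
    name: str = "signature",
    score_threshold: float = 1.0,
) -> DerivedSignature:
    """Run the intersection cascade.

    All differential tables must be oriented with the target disease as
    group2 (delta_beta = target - other), so "hypo" means lower in the
    target.  Steps: (1) per direction, intersect significant CpGs across
    every target-vs-other-disease comparison; (2) intersect with the
    same-direction significant CpGs of target-vs-healthy; (3) drop CpGs
    significant in the control-vs-control comparison, if given.  Returns
    the hypo survivors as the signature (ordered by probe ID); raises
    :class:`EmptySignatureError` if none survive.
    """
    if not target_vs_others:
        raise ValueError("need at least one target-vs-other-disease comparison")
    steps: dict = {}
    survivors = {}
    for direction in ("hyper", "hypo"):
        sets = [_sig_probes(t, direction) for t in target_vs_others.values()]
        step1 = set.intersection(*sets)
        step2 = step1 & _sig_probes(target_vs_healthy, direction)
        steps[f"{direction}_step1"] = len(step1)
        steps[f"{direction}_step2"] = len(step2)
        if control_check is not None:
            flagged = set(control_check.index[control_check["class"] != "ns"])
            dropped = step2 & flagged
            step2 = step2 - flagged
            steps[f"{direction}_dropped_control_check"] = len(dropped)
        survivors[direction] = step2
    hypo = tuple(sorted(survivors["hypo"]))
    hyper = tuple(sorted(survivors["hyper"]))
    if not hypo:
        raise EmptySignatureError(
            "no hypomethylated CpGs survived the intersection cascade "
            f"({len(hyper)} hypermethylated survivors)"
        )
    sig = SignatureDefinition(
        name=name, probe_ids=hypo, direction="hypo", score_threshold=score_threshold
    )
    return DerivedSignature(signature=sig, hyper_probes=hyper, steps=steps)


def compute_score(beta: BetaMatrix, signature: SignatureDefinition) -> pd.DataFrame:
    """Per-sample signature score S = k - sum of signature beta values.

    Per-sample missing values are imputed with the probe's cohort mean;
    probes absent from the matrix entirely are imputed at beta 0.5 with a
    warning.  Columns: score, n_missing_probes, call.
    """
    probes = pd.Index(signature.probe_ids)
    present = probes.intersection(beta.values.index)
    if len(present) == 0:
        raise ValueError("no signature probes present in the matrix")
    absent = probes.difference(beta.values.index)
    X = beta.values.reindex(probes)
    if len(absent):
        warnings.warn(
            f"{len(absent)} signature probes absent from the matrix; imputed at 0.5"
        )
        X.loc[absent] = 0.5
    n_missing = X.isna().sum(axis=0).astype(int) + len(absent)
    cohort_mean = X.mean(axis=1, skipna=True).fillna(0.5)
    X = X.apply(lambda col: col.fillna(cohort_mean))
    score = signature.k - X.sum(axis=0)
    out = pd.DataFrame(
        {
            "score": score,
            "n_missing_probes": n_missing,
            "call": np.where(score > signature.score_threshold, "positive", "negative"),
        }
    )
    out.index.name = "sample_id"
    return out


@dataclass
class ScoreEvaluation:
    """Separation of the target group from the rest by the score."""

    per_group: pd.DataFrame       # group, n, mean, min, max, frac_positive
    auc: float                    # rank-based (Mann-Whitney) target vs rest
    confusion: dict               # tp, fp, tn, fn at the threshold


def evaluate_score(
    scores: pd.DataFrame,
    sheet: SampleSheet,
    target_group: str | Sequence[str],
    threshold: float = 1.0,
) -> ScoreEvaluation:
    """Summarize score separation: per-group distributions, exact rank-based
    AUC of target-vs-rest, and the confusion table at the threshold."""
    targets = (target_group,) if isinstance(target_group, str) else tuple(target_group)
    groups = sheet.table["group"].reindex(scores.index)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups to evaluate")
    s = scores["score"].to_numpy(dtype=float)
    is_target = groups.isin(targets).to_numpy()

    per_group = (
        pd.DataFrame({"group": groups, "score": s, "positive": s > threshold})
        .groupby("group")
        .agg(
            n=("score", "size"),
            mean=("score", "mean"),
            min=("score", "min"),
            max=("score", "max"),
            frac_positive=("positive", "mean"),
        )
        .reset_index()
    )

    n1 = int(is_target.sum())
    n0 = int((~is_target).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("target group absent or no comparison samples")
    ranks = rankdata(s)  # midranks: ties contribute 0.5
    auc = (ranks[is_target].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    pos = s > threshold
    confusion = {
        "tp": int((pos & is_target).sum()),
        "fp": int((pos & ~is_target).sum()),
        "tn": int((~pos & ~is_target).sum()),
        "fn": int((~pos & is_target).sum()),
    }
    return ScoreEvaluation(per_group=per_group, auc=float(auc), confusion=confusion)
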