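"""End-to-end orchestration of the study-shaped workflow.

Sequence: load/validate -> per-disease differential versus tissue-matched
controls -> cell-type-stable CpG filtering -> cross-disease overlap
tables -> signature derivation for the target disease -> per-sample
scoring and evaluation -> covariate analyses (allele-burden correlation,
optional clock).  Each stage logs its input/output dimensions; any stage
error aborts with the stage name and cause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltypes import CellTypeReference, apply_stable_filter, stable_cpg_filter
from .covariates import ClockModel, apply_linear_clock, correlate_with_burden
from .differential import CpGSet, differential, set_overlap, significant_set
from .io import BetaMatrix, CpGAnnotation, SampleSheet
from .regions import hypergeometric_enrichment
from .signature import (
    DerivedSignature,
    compute_score,
    derive_signature,
    evaluate_score,
)
from .simulate import _entity

logger = logging.getLogger("myelometh.pipeline")

__all__ = ["PipelineParams", "PipelineReport", "PipelineStageError", "run_full", "write_report"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the workflow, in one place."""

    delta: float = 0.20
    alpha: float = 0.05
    stable_threshold: float = 0.10
    window_bp: int = 500
    bin_bp: int = 100
    score_threshold: float = 1.0
    target_entity: str = "PMF"
    seed: int = 0


@dataclass
class PipelineReport:
    params: PipelineParams
    filter_counts: dict                  # entity -> before/after call counts
    differential: dict                   # entity -> filtered result table
    overlap_tables: dict                 # direction -> Venn partition table
    derived: DerivedSignature | None
    scores: pd.DataFrame | None
    evaluation: object | None
    burden_correlation: pd.DataFrame | None
    clock_results: pd.DataFrame | None
    enrichment: pd.DataFrame | None


def _entity_sheet(sheet: SampleSheet, entity: str, tissues: set,
                  other: str | None = None) -> SampleSheet:
    """Relabel groups so one disease entity (and optionally a second) can be
    compared directly; controls are restricted to matching tissues."""
    df = sheet.table.copy()
    ent = df["group"].map(lambda g: _entity(g) or "control")
    keep = pd.Series(False, index=df.index)
    keep |= ent == entity
    if other is not None:
        keep |= ent == other
    keep |= (ent == "control") & df["tissue"].isin(tissues)
    df = df.loc[keep].copy()
    df["group"] = ent.loc[keep].to_numpy()
    return SampleSheet(df)


def run_full(
    beta: BetaMatrix,
    sheet: SampleSheet,
    reference: CellTypeReference,
    annotation: CpGAnnotation | None = None,
    params: PipelineParams = PipelineParams(),
    clock: ClockModel | None = None,
) -> PipelineReport:
    """Run the full workflow on in-memory inputs."""

    def stage(name):
        logger.info("stage %s", name)
        return name

    current = stage("validate")
    try:
        sheet.validate_against(beta)
        ent = sheet.table["group"].map(lambda g: _entity(g) or "control")
        entities = sorted(set(ent) - {"control"})
        if not entities:
            raise ValueError("no disease groups in the sample sheet")
        tissues_of = {
            e: set(sheet.table.loc[ent == e, "tissue"]) for e in entities
        }
        control_tissues = set(sheet.table.loc[ent == "control", "tissue"])
        for e, ts in tissues_of.items():
            if not ts & control_tissues:
                raise ValueError(
                    f"no controls share a tissue with entity {e!r} (tissues {sorted(ts)}); "
                    "add tissue-matched control samples"
                )
        logger.info("entities=%s, matrix=%s", entities, beta.shape)

        current = stage("stable_filter")
        stable = stable_cpg_filter(reference, params.stable_threshold)
        logger.info("stable probes: %d / %d", len(stable), len(reference.probe_ids))

        current = stage("differential")
        unfiltered, filtered, counts = {}, {}, {}
        for e in entities:
            ts = tissues_of[e] & control_tissues
            esheet = _entity_sheet(sheet, e, ts)
            res = differential(beta, esheet, "control", e, params.delta, params.alpha)
            unfiltered[e] = res
            filtered[e], counts[e] = apply_stable_filter(res, stable)
            logger.info(
                "%s vs control: hyper %d->%d, hypo %d->%d after stable filter",
                e, counts[e]["hyper_before"], counts[e]["hyper_after"],
                counts[e]["hypo_before"], counts[e]["hypo_after"],
            )

        current = stage("overlap")
        overlap_tables = {}
        if len(entities) >= 2:
            for direction in ("hyper", "hypo"):
                sets = [significant_set(filtered[e], direction, name=e) for e in entities]
                if all(len(s) == 0 for s in sets):
                    continue
                table, _ = set_overlap(sets)
                overlap_tables[direction] = table

        current = stage("signature")
        derived = None
        scores = None
        evaluation = None
        target = params.target_entity
        if target in entities:
            others = [e for e in entities if e != target]
            tvo = {}
            for o in others:
                osheet = _entity_sheet(sheet, target, set(), other=o)
                res = differential(beta, osheet, o, target, params.delta, params.alpha)
                tvo[o] = res.loc[res.index.isin(stable.probe_ids)]
            tvh = filtered[target]
            control_ids = list(sheet.table.index[ent == "control"])
            control_check = None
            if len(control_ids) >= 4:
                half = len(control_ids) // 2
                cc = sheet.table.loc[control_ids].copy()
                cc["group"] = ["ctrlA"] * half + ["ctrlB"] * (len(control_ids) - half)
                ccres = differential(
                    beta, SampleSheet(cc), "ctrlA", "ctrlB", params.delta, params.alpha
                )
                control_check = ccres.loc[ccres.index.isin(stable.probe_ids)]
            if others:
                derived = derive_signature(
                    tvo, tvh, control_check,
                    name=f"{target}_signature",
                    score_threshold=params.score_threshold,
                )
                logger.info(
                    "signature: %d hypo CpGs (%d hyper survivors)",
                    derived.signature.k, len(derived.hyper_probes),
                )
                current = stage("score")
                scores = compute_score(beta, derived.signature)
                target_groups = [
                    g for g in sheet.table["group"].unique() if _entity(g) == target
                ]
                evaluation = evaluate_score(
                    scores, sheet, target_groups, params.score_threshold
                )
                logger.info("score AUC (target vs rest): %.3f", evaluation.auc)

        current = stage("covariates")
        burden_corr = None
        if sheet.table["allele_burden"].notna().sum() >= 3:
            burden_corr = correlate_with_burden(beta, sheet)
        clock_results = None
        if clock is not None:
            clock_results = apply_linear_clock(beta, clock, sheet)

        current = stage("enrichment")
        enrichment = None
        if annotation is not None and target in entities:
            fg = significant_set(unfiltered[target], "hypo", "fg")
            bg = CpGSet("bg", frozenset(unfiltered[target].index), "mixed")
            if len(fg):
                enrichment = hypergeometric_enrichment(
                    fg, bg, annotation, "island_class"
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError(current, exc) from exc

    return PipelineReport(
        params=params,
        filter_counts=counts,
        differential=filtered,
        overlap_tables=overlap_tables,
        derived=derived,
        scores=scores,
        evaluation=evaluation,
        burden_correlation=burden_corr,
        clock_results=clock_results,
        enrichment=enrichment,
    )


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    """Write every report table as TSV plus a plain-text run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for e, table in report.differential.items():
        table.to_csv(out / f"dm_{e}_filtered.tsv", sep="\t", na_rep="NA",
                     float_format="%.10g")
    for direction, table in report.overlap_tables.items():
        table.to_csv(out / f"overlap_{direction}.tsv", sep="\t", index=False)
    if report.scores is not None:
        report.scores.to_csv(out / "scores.tsv", sep="\t", float_format="%.10g")
    if report.burden_correlation is not None:
        report.burden_correlation.to_csv(
            out / "burden_correlation.tsv", sep="\t", na_rep="NA", float_format="%.10g"
        )
    if report.clock_results is not None:
        report.clock_results.to_csv(
            out / "clock.tsv", sep="\t", na_rep="NA", float_format="%.10g"
        )
    if report.enrichment is not None:
        report.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"myelometh {__version__}\n")
        for k, v in asdict(report.params).items():
            fh.write(f"param\t{k}\t{v}\n")
        for e, c in report.filter_counts.items():
            for k, v in c.items():
                fh.write(f"counts\t{e}\t{k}\t{v}\n")
        if report.derived is not None:
            fh.write("signature\t" + ",".join(report.derived.signature.probe_ids) + "\n")
            for k, v in report.derived.steps.items():
                fh.write(f"cascade\t{k}\t{v}\n")
        if report.evaluation is not None:
            fh.write(f"auc\t{report.evaluation.auc!r}\n")
            for k, v in report.evaluation.confusion.items():
                fh.write(f"confusion\t{k}\t{v}\n")
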