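"""Shared paths and cohort access for the numbered analysis scripts.

The default study-condition cohort (seed 7) is written once by
``01_simulate_cohort.py``; later scripts load it from disk, or regenerate
it transparently if the files are not there yet.
"""

from pathlib import Path

import myelometh as mm

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"

COHORT_SEED = 7


def cohort_config() -> mm.SimulationConfig:
    return mm.SimulationConfig(seed=COHORT_SEED)


def ensure_cohort():
    """Return (config, reference, beta, sheet, truth, annotation), writing
    the cohort files on first use."""
    cfg = cohort_config()
    if not (COHORT_DIR / "beta.tsv").exists():
        from myelometh.celltypes import write_reference
        from myelometh.io import (
            write_annotation,
            write_beta_matrix,
            write_sample_sheet,
        )

        COHORT_DIR.mkdir(parents=True, exist_ok=True)
        ref = mm.generate_reference(cfg)
        beta, sheet, truth = mm.generate_cohort(cfg, ref)
        annot = mm.generate_annotation(beta.probe_ids, seed=cfg.seed)
        write_beta_matrix(beta, COHORT_DIR / "beta.tsv")
        write_sample_sheet(sheet, COHORT_DIR / "samples.tsv")
        write_reference(ref, COHORT_DIR / "reference.tsv")
        truth.to_frame().to_csv(COHORT_DIR / "truth.tsv", sep="\t")
        write_annotation(annot, COHORT_DIR / "annotation.tsv")
        return cfg, ref, beta, sheet, truth, annot

    from myelometh.celltypes import read_reference

    ref = read_reference(COHORT_DIR / "reference.tsv")
    beta = mm.read_beta_matrix(COHORT_DIR / "beta.tsv")
    sheet = mm.read_sample_sheet(COHORT_DIR / "samples.tsv")
    annot = mm.read_annotation(COHORT_DIR / "annotation.tsv")
    # ground truth is regenerated (bit-identical for the fixed seed)
    _, _, truth = mm.generate_cohort(cfg, mm.generate_reference(cfg))
    return cfg, ref, beta, sheet, truth, annot


def pooled_pmf_sheet(sheet: mm.SampleSheet) -> mm.SampleSheet:
    """Relabel the mutation subgroups as one PMF group."""
    df = sheet.table.copy()
    df["group"] = df["group"].map(lambda g: "PMF" if g.startswith("PMF") else g)
    return mm.SampleSheet(df)
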