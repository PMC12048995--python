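"""Ground-truthed synthetic methylation cohorts.

The generator emulates the statistical structure that bulk blood
methylomes are assumed to have:

* each sample's pre-noise beta profile is a convex mixture of cell-type
  methylomes, with per-sample compositions drawn from a group-specific
  Dirichlet (disease groups are granulocyte-shifted, creating the
  cell-composition confound);
* a subset of CpGs is *cell-type variable* (one cell type deviates from
  the common baseline by a planted contrast), so composition shifts alone
  produce apparent group differences there;
* *disease-intrinsic* effects are planted additively on the beta scale at
  dedicated CpGs — shared pan-myeloid effects plus effects specific to a
  disease entity (PMF effects are shared across its driver-mutation
  subgroups), including a small set of target-specific hypomethylated
  "signature" CpGs with a fixed control-level beta;
* *burden-linked* CpGs gain methylation proportionally to the sample's
  driver-mutation allele burden (effect x burden/100);
* measurement noise is logit-normal (additive Gaussian on the logit
  scale), mimicking array heteroskedasticity while keeping values in
  (0, 1).

Every CpG's role is recorded in a :class:`GroundTruth` object so that
sensitivity, false-discovery and recovery properties can be scored
exactly.  Fixing ``seed`` reproduces all outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .amplicon import AmpliconReadSet
from .celltypes import CellTypeReference
from .io import BETA_EPS, BetaMatrix, CpGAnnotation, SampleSheet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_reference",
    "generate_cohort",
    "generate_annotation",
    "generate_amplicon_reads",
]

_DEFAULT_CELL_TYPES = ("granulocytes", "monocytes", "B_cells", "NK_cells", "CD4_T", "CD8_T")
_DEFAULT_GROUPS = ("control", "PMF-JAK2", "PMF-CALR", "PMF-MPL", "MDS", "JMML", "AML")

# typical leukocyte proportions in healthy blood vs a granulocyte-expanded
# disease state; scaled by a concentration of 100 for the Dirichlet draw
_CONTROL_PROPS = np.array([0.50, 0.10, 0.12, 0.06, 0.14, 0.08])
_DISEASE_PROPS = np.array([0.80, 0.04, 0.048, 0.024, 0.056, 0.032])
_DIRICHLET_CONCENTRATION = 100.0


def _entity(group: str) -> str | None:
    """Disease entity of a sample-sheet group ('PMF-JAK2' -> 'PMF')."""
    if group == "control":
        return None
    return group.split("-")[0]


def _mutation(group: str) -> str:
    if "-" in group:
        return group.split("-", 1)[1]
    return "none"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modeled study: ten-to-twenty samples per group,
    driver-mutation subgroups of PMF plus MDS/JMML/AML and healthy
    controls, allele burdens uniform on the reported 26-93% range, a
    strong granulocyte-composition confound, and planted effect sizes of
    0.35 beta (comfortably above the 0.20 calling threshold).
    """

    n_cpgs: int = 2000
    cell_types: tuple = _DEFAULT_CELL_TYPES
    groups: tuple = _DEFAULT_GROUPS
    n_samples_per_group: int | Mapping = 20
    dirichlet_alpha_per_group: Mapping | None = None
    #: entity -> (n_hyper, n_hypo); the pseudo-entity "shared" is planted
    #: in every disease sample (pan-myeloid effects)
    n_intrinsic_cpgs_per_group: Mapping | None = None
    effect_size: float = 0.35
    n_celltype_variable_cpgs: int = 200
    celltype_contrast: float = 0.4
    #: when set, per-CpG contrasts are drawn Uniform(contrast, contrast_max)
    #: instead of being exactly celltype_contrast
    celltype_contrast_max: float | None = 0.9
    noise_sd_logit: float = 0.05
    burden_linked_cpgs: int = 20
    burden_effect: float = 0.4
    burden_range: tuple = (26.0, 93.0)
    n_signature_cpgs: int = 5
    signature_base_beta: float = 0.85
    signature_effect: float = 0.35
    signature_entity: str = "PMF"
    tissue_per_group: Mapping | None = None
    seed: int = 0

    def intrinsic_map(self) -> dict:
        if self.n_intrinsic_cpgs_per_group is not None:
            return dict(self.n_intrinsic_cpgs_per_group)
        return {"shared": (30, 30), "PMF": (10, 5), "MDS": (8, 8),
                "JMML": (8, 8), "AML": (8, 8)}

    def alphas(self) -> dict:
        if self.dirichlet_alpha_per_group is not None:
            return {g: np.asarray(a, dtype=float) for g, a in self.dirichlet_alpha_per_group.items()}
        k = len(self.cell_types)
        if k == len(_CONTROL_PROPS):
            ctrl, dis = _CONTROL_PROPS, _DISEASE_PROPS
        else:  # non-default panel: mild granulocyte-style shift on type 0
            ctrl = np.full(k, 1.0 / k)
            dis = np.full(k, 0.5 / (k - 1))
            dis[0] = 0.5
        out = {}
        for g in self.groups:
            props = ctrl if g == "control" else dis
            out[g] = props * _DIRICHLET_CONCENTRATION
        return out

    def tissues(self) -> dict:
        if self.tissue_per_group is not None:
            return dict(self.tissue_per_group)
        return {g: ("BM" if _entity(g) == "MDS" else "PB") for g in self.groups}

    def n_samples(self, group: str) -> int:
        if isinstance(self.n_samples_per_group, Mapping):
            return int(self.n_samples_per_group[group])
        return int(self.n_samples_per_group)

    def __post_init__(self) -> None:
        planted = self.n_celltype_variable_cpgs + self.burden_linked_cpgs
        for n_hyper, n_hypo in self.intrinsic_map().values():
            planted += n_hyper + n_hypo
        if planted > self.n_cpgs:
            raise ValueError(
                f"planted CpGs ({planted}) exceed n_cpgs ({self.n_cpgs})"
            )
        for name, eff in (("effect_size", self.effect_size),
                          ("signature_effect", self.signature_effect),
                          ("burden_effect", self.burden_effect)):
            if not 0 < eff < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for g, a in self.alphas().items():
            if np.any(np.asarray(a) <= 0):
                raise ValueError(f"Dirichlet alpha for {g!r} must be strictly positive")
            if len(a) != len(self.cell_types):
                raise ValueError(f"alpha length mismatch for group {g!r}")
        hypo_target = self.intrinsic_map().get(self.signature_entity, (0, 0))[1]
        if self.n_signature_cpgs > hypo_target:
            raise ValueError(
                "n_signature_cpgs exceeds the target entity's hypo allotment"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``labels`` holds one of: 'null', 'celltype-variable', 'burden-linked',
    'intrinsic-hyper:<entity>', 'intrinsic-hypo:<entity>' per probe
    ('shared' = pan-myeloid).  ``signature_probes`` are the target-entity
    hypo CpGs planted with the fixed control-level beta.
    """

    labels: pd.Series
    compositions: pd.DataFrame      # samples x cell types, rows sum to 1
    burdens: pd.Series              # allele burden %, NaN for controls
    signature_probes: tuple
    clip_warnings: int = 0

    def probes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def intrinsic_probes(self, entity: str, direction: str) -> list[str]:
        return self.probes(f"intrinsic-{direction}:{entity}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels})
        df["is_signature"] = df.index.isin(self.signature_probes)
        df.index.name = "probe_id"
        return df


@dataclass
class _Plan:
    probe_ids: list
    labels: pd.Series
    base_beta: np.ndarray           # common baseline per CpG
    reference: CellTypeReference
    signature_probes: tuple


def _build_plan(config: SimulationConfig) -> _Plan:
    """Deterministic CpG role assignment and cell-type reference."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_cpgs
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    order = rng.permutation(n)
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        block = order[cursor:cursor + count]
        cursor += count
        return block

    labels = np.full(n, "null", dtype=object)
    var_idx = take(config.n_celltype_variable_cpgs)
    labels[var_idx] = "celltype-variable"
    burden_idx = take(config.burden_linked_cpgs)
    labels[burden_idx] = "burden-linked"
    intrinsic_idx: dict[tuple[str, str], np.ndarray] = {}
    for entity, (n_hyper, n_hypo) in config.intrinsic_map().items():
        intrinsic_idx[(entity, "hyper")] = take(n_hyper)
        intrinsic_idx[(entity, "hypo")] = take(n_hypo)
        labels[intrinsic_idx[(entity, "hyper")]] = f"intrinsic-hyper:{entity}"
        labels[intrinsic_idx[(entity, "hypo")]] = f"intrinsic-hypo:{entity}"

    # baseline betas: bimodal like real array data, kept off the boundaries
    base = np.clip(rng.beta(0.35, 0.35, size=n), 0.03, 0.97)
    # planted CpGs need headroom so additive effects are not clipped
    eff = config.effect_size
    for (entity, direction), idx in intrinsic_idx.items():
        if direction == "hyper":
            base[idx] = rng.uniform(0.05, 1.0 - eff - 0.1, size=len(idx))
        else:
            base[idx] = rng.uniform(eff + 0.1, 0.95, size=len(idx))
    base[burden_idx] = rng.uniform(0.05, 1.0 - config.burden_effect - 0.05,
                                   size=len(burden_idx))
    sig_idx = intrinsic_idx.get(
        (config.signature_entity, "hypo"), np.empty(0, dtype=int)
    )[: config.n_signature_cpgs]
    base[sig_idx] = config.signature_base_beta

    # reference: all cell types share the baseline except at variable CpGs,
    # where one randomly chosen type deviates by the planted contrast
    k = len(config.cell_types)
    R = np.tile(base[:, None], (1, k))
    if config.celltype_contrast_max is None:
        contrasts = np.full(len(var_idx), config.celltype_contrast)
    else:
        contrasts = rng.uniform(config.celltype_contrast,
                                config.celltype_contrast_max, size=len(var_idx))
    marker_type = rng.integers(0, k, size=len(var_idx))
    sign = rng.choice([-1.0, 1.0], size=len(var_idx))
    for j, (i, c, t, s) in enumerate(zip(var_idx, contrasts, marker_type, sign)):
        lo, hi = 0.02, 0.98
        b = base[i]
        # flip the deviation direction if it would leave [lo, hi]
        if s > 0 and b + c > hi:
            s = -1.0
        if s < 0 and b - c < lo:
            s = 1.0
            if b + c > hi:  # no room either way: re-center the baseline
                b = rng.uniform(lo, hi - c)
                R[i, :] = b
                base[i] = b
        R[i, t] = b + s * c

    labels = pd.Series(labels, index=probe_ids, name="label")
    ref = CellTypeReference(
        pd.DataFrame(R, index=probe_ids, columns=list(config.cell_types))
    )
    return _Plan(
        probe_ids=probe_ids,
        labels=labels,
        base_beta=base,
        reference=ref,
        signature_probes=tuple(np.array(probe_ids, dtype=object)[sig_idx]),
    )


def generate_reference(config: SimulationConfig) -> CellTypeReference:
    """Cell-type mean-beta profiles implied by the config (deterministic
    given the seed)."""
    return _build_plan(config).reference


def generate_cohort(
    config: SimulationConfig, reference: CellTypeReference | None = None
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Simulate a beta matrix, sample sheet and ground truth.

    Samples are convex mixtures of the reference profiles (compositions ~
    group Dirichlet), plus planted disease-intrinsic effects, plus
    burden-scaled effects, then logit-normal noise.  ``reference``
    defaults to :func:`generate_reference` of the same config.
    """
    plan = _build_plan(config)
    if reference is None:
        reference = plan.reference
    if list(reference.probe_ids) != plan.probe_ids:
        raise ValueError("reference probes do not match the configured cohort")
    rng = np.random.default_rng([config.seed, 202])
    alphas = config.alphas()
    tissues = config.tissues()

    sample_ids: list[str] = []
    rows = []
    comps = []
    control_tissues = sorted({tissues[g] for g in config.groups if g != "control"}) or ["PB"]
    for group in config.groups:
        group_tissues = control_tissues if group == "control" else [tissues[group]]
        for tissue in group_tissues:
            n = config.n_samples(group)
            mut = _mutation(group) if group != "control" else "none"
            entity = _entity(group)
            if entity == "JMML":
                ages = rng.uniform(1.0, 15.0, size=n)
            elif group == "control" or entity in ("PMF", "MDS"):
                ages = rng.uniform(45.0, 80.0, size=n)
            else:
                ages = rng.uniform(30.0, 80.0, size=n)
            for i in range(n):
                sid = f"{group}.{tissue}.{i:02d}"
                sample_ids.append(sid)
                burden = (
                    rng.uniform(*config.burden_range)
                    if mut in ("JAK2", "CALR", "MPL")
                    else np.nan
                )
                rows.append(
                    {
                        "sample_id": sid, "group": group, "mutation": mut,
                        "allele_burden": burden, "age_years": round(float(ages[i]), 1),
                        "tissue": tissue, "batch": "sim",
                    }
                )
            comps.append(rng.dirichlet(alphas[group], size=n))
    sheet_df = pd.DataFrame(rows).set_index("sample_id")
    F = np.vstack(comps)                                  # samples x types
    R = reference.mean_beta.to_numpy()                    # probes x types
    B = R @ F.T                                           # probes x samples

    labels = plan.labels
    col_group = sheet_df["group"].to_numpy()
    col_entity = np.array([_entity(g) or "control" for g in col_group], dtype=object)
    is_disease = col_entity != "control"

    eff = config.effect_size
    for entity, _counts in config.intrinsic_map().items():
        cols = is_disease if entity == "shared" else (col_entity == entity)
        if not cols.any():
            continue
        for direction, s in (("hyper", +1.0), ("hypo", -1.0)):
            probes = labels.index[labels == f"intrinsic-{direction}:{entity}"]
            idx = labels.index.get_indexer(probes)
            per_probe = np.full(len(idx), s * eff)
            if entity == config.signature_entity and direction == "hypo":
                sig_mask = np.isin(np.asarray(probes), plan.signature_probes)
                per_probe[sig_mask] = -config.signature_effect
            B[np.ix_(idx, np.flatnonzero(cols))] += per_probe[:, None]

    burden = sheet_df["allele_burden"].to_numpy(dtype=float)
    has_burden = ~np.isnan(burden)
    if has_burden.any() and config.burden_linked_cpgs:
        bidx = labels.index.get_indexer(labels.index[labels == "burden-linked"])
        B[np.ix_(bidx, np.flatnonzero(has_burden))] += (
            config.burden_effect * burden[has_burden][None, :] / 100.0
        )

    n_clipped = int(np.sum((B < 0) | (B > 1)))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} pre-noise beta values fell outside (0, 1) and were clipped"
        )
    B = np.clip(B, 0.0, 1.0)
    if config.noise_sd_logit > 0:
        Z = logit(np.clip(B, BETA_EPS, 1 - BETA_EPS))
        Z += rng.normal(0.0, config.noise_sd_logit, size=B.shape)
        B = expit(Z)
    B = np.clip(B, 0.0, 1.0)

    beta = BetaMatrix(pd.DataFrame(B, index=plan.probe_ids, columns=sample_ids))
    sheet = SampleSheet(sheet_df)
    truth = GroundTruth(
        labels=labels,
        compositions=pd.DataFrame(F, index=sample_ids, columns=list(config.cell_types)),
        burdens=sheet_df["allele_burden"].copy(),
        signature_probes=plan.signature_probes,
        clip_warnings=n_clipped,
    )
    return beta, sheet, truth


_REGION_CLASSES = (("intergenic", 0.45), ("gene body", 0.30), ("promoter", 0.25))
_ISLAND_CLASSES = (("open sea", 0.40), ("island", 0.30), ("shore", 0.20), ("shelf", 0.10))


def generate_annotation(probe_ids: Sequence[str], seed: int = 0,
                        n_chromosomes: int = 4) -> CpGAnnotation:
    """Synthetic probe annotation: probes are laid out along chromosomes
    with 50-2000 bp gaps (so neighborhood windows contain probes), and
    region/island classes are drawn with array-like proportions."""
    rng = np.random.default_rng([seed, 303])
    n = len(probe_ids)
    chrom = np.sort(rng.integers(1, n_chromosomes + 1, size=n))
    pos = np.empty(n, dtype=int)
    for c in range(1, n_chromosomes + 1):
        m = chrom == c
        gaps = rng.integers(50, 2000, size=m.sum())
        pos[m] = 10_000 + np.cumsum(gaps)
    region = rng.choice([c for c, _ in _REGION_CLASSES], size=n,
                        p=[p for _, p in _REGION_CLASSES])
    island = rng.choice([c for c, _ in _ISLAND_CLASSES], size=n,
                        p=[p for _, p in _ISLAND_CLASSES])
    gene = np.where(region == "intergenic", np.nan,
                    np.array([f"GENE{i // 10}" for i in range(n)], dtype=object))
    df = pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "position": pos,
            "region_class": region,
            "island_class": island,
            "gene": gene,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return CpGAnnotation(df)


def generate_amplicon_reads(
    n_reads: int,
    n_cpgs: int,
    model: str = "independent",
    p: float | Sequence[float] = 0.5,
    clones: Sequence[Sequence[int]] | None = None,
    proportions: Sequence[float] | None = None,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> AmpliconReadSet:
    """Simulate binary amplicon reads.

    ``model='independent'``: each CpG is i.i.d. Bernoulli(p_j) across
    reads (polyclonal-like).  ``model='clonal'``: each read copies a clone
    pattern drawn with the given proportions, then every bit flips with
    probability ``flip_rate`` (bisulfite-conversion/PCR error).
    """
    rng = np.random.default_rng([seed, 404])
    if model == "independent":
        pj = np.broadcast_to(np.asarray(p, dtype=float), (n_cpgs,))
        if np.any((pj < 0) | (pj > 1)):
            raise ValueError("p must lie in [0, 1]")
        reads = (rng.random((n_reads, n_cpgs)) < pj[None, :]).astype(np.int8)
    elif model == "clonal":
        if clones is None or proportions is None:
            raise ValueError("clonal model needs clones and proportions")
        C = np.asarray(clones, dtype=np.int8)
        props = np.asarray(proportions, dtype=float)
        if C.shape[1] != n_cpgs:
            raise ValueError("clone patterns must have n_cpgs columns")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("clone proportions must sum to 1")
        if not 0 <= flip_rate <= 1:
            raise ValueError("flip_rate must lie in [0, 1]")
        which = rng.choice(len(C), size=n_reads, p=props)
        reads = C[which].copy()
        if flip_rate > 0:
            flips = rng.random(reads.shape) < flip_rate
            reads = np.where(flips, 1 - reads, reads).astype(np.int8)
    else:
        raise ValueError(f"unknown model {model!r}")
    return AmpliconReadSet(reads)
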