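import numpy as np
import pandas as pd
import pytest

import myelometh as mm


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort shared across tests (read-only)."""
    cfg = mm.SimulationConfig(seed=7)
    ref = mm.generate_reference(cfg)
    beta, sheet, truth = mm.generate_cohort(cfg, ref)
    return cfg, ref, beta, sheet, truth


@pytest.fixture(scope="session")
def small_two_group():
    """Compact control-vs-PMF cohort without composition confound."""
    cfg = mm.SimulationConfig(
        n_cpgs=500,
        groups=("control", "PMF-JAK2"),
        n_samples_per_group=10,
        n_celltype_variable_cpgs=0,
        n_intrinsic_cpgs_per_group={"PMF": (20, 20)},
        n_signature_cpgs=5,
        burden_linked_cpgs=0,
        seed=11,
    )
    ref = mm.generate_reference(cfg)
    beta, sheet, truth = mm.generate_cohort(cfg, ref)
    return cfg, ref, beta, sheet, truth


def make_beta(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return mm.BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))


def make_sheet(groups, **overrides):
    """Minimal sample sheet: groups is a mapping sample_id -> group."""
    df = pd.DataFrame(
        {
            "group": pd.Series(groups),
            "mutation": "none",
            "allele_burden": np.nan,
            "age_years": 60.0,
            "tissue": "PB",
            "batch": "t",
        }
    )
    for k, v in overrides.items():
        df[k] = v
    df.index.name = "sample_id"
    return mm.SampleSheet(df)
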