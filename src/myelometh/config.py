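"""YAML configuration for simulations and pipeline runs.

A config file may carry a ``simulate:`` block (fields of
:class:`~myelometh.simulate.SimulationConfig`), a ``params:`` block
(fields of :class:`~myelometh.pipeline.PipelineParams`), and an
``inputs:`` block with file paths (beta, samples, reference, annotation,
clock).  A top-level ``seed`` overrides both sub-seeds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .pipeline import PipelineParams
from .simulate import SimulationConfig

__all__ = ["load_config", "simulation_config_from_dict", "pipeline_params_from_dict"]


def _restrict(d: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("cell_types", "groups", "burden_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**_restrict(d, SimulationConfig))


def pipeline_params_from_dict(d: dict) -> PipelineParams:
    return PipelineParams(**_restrict(dict(d), PipelineParams))


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into {'simulate': SimulationConfig | None,
    'params': PipelineParams, 'inputs': dict, 'outdir': str | None}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = raw.get("seed")
    sim_d = raw.get("simulate")
    if sim_d is not None and seed is not None:
        sim_d = {**sim_d, "seed": int(seed)}
    par_d = raw.get("params", {})
    if seed is not None:
        par_d = {**par_d, "seed": int(seed)}
    return {
        "simulate": simulation_config_from_dict(sim_d) if sim_d is not None else None,
        "params": pipeline_params_from_dict(par_d),
        "inputs": raw.get("inputs", {}),
        "outdir": raw.get("outdir"),
    }
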