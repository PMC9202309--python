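"""YAML run configuration: blocks system / energy / de / pull / engine / pathfinder.

The ``de:`` block exposes the published parameter names
(population_size, max_vector_length, iterations, crossover_prob, diff_weight,
alpha, seed); ``pull:`` carries k, v, tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .desearch import DEConfig, ScoreConfig
from .dynamics import EngineConfig
from .energy import EnergyConfig
from .pathfind import PathfinderConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    system: dict
    energy: EnergyConfig
    de: DEConfig
    score: ScoreConfig
    pull: dict           # k, v, tau
    engine: EngineConfig
    pathfinder: PathfinderConfig


def _take(block: dict, cls, **extra):
    fields = {f for f in cls.__dataclass_fields__}
    kwargs = {k: v for k, v in block.items() if k in fields}
    kwargs.update(extra)
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    de_block = dict(raw.get("de", {}))
    alpha = de_block.pop("alpha", 2.0)
    pf_block = dict(raw.get("pathfinder", {}))
    if "fixed_direction" in pf_block and pf_block["fixed_direction"] is not None:
        pf_block["fixed_direction"] = np.asarray(pf_block["fixed_direction"], float)
    pull = {"k": 600.0, "v": 5.0, "tau": 20.0}
    pull.update(raw.get("pull", {}))
    return RunConfig(
        system=dict(raw.get("system", {})),
        energy=_take(raw.get("energy", {}), EnergyConfig),
        de=_take(de_block, DEConfig),
        score=ScoreConfig(alpha=alpha),
        pull=pull,
        engine=_take(raw.get("engine", {}), EngineConfig),
        pathfinder=_take(pf_block, PathfinderConfig),
    )
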