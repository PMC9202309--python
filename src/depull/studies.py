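"""Canonical desk-scale protocol studies on the standard fixtures.

These functions define the package's reference study conditions: the
pulling parameters are the published defaults (k = 600 kJ/mol/nm^2,
v = 5 nm/ns, tau = 20 ps, alpha = 2, CR = 0.9, F = 0.5), while the search
population/iterations, integrator step and temperatures are desk-scale
choices sized to the synthetic fixtures (see docs/methods.md).  Both the
acceptance script and the protocol-level tests run these.
"""

from __future__ import annotations

import numpy as np

from .analysis import (classify_pathways, compute_work, has_secondary_peak,
                       spearman, success_rate)
from .desearch import DEConfig, ScoreConfig
from .dynamics import EngineConfig
from .energy import EnergyConfig
from .pathfind import PathfinderConfig, run_ensemble
from .structures import select_pulled_atom
from .synth import channel_gates, make_ligand_series, make_system, standard_fixtures

__all__ = ["desk_de_config", "desk_engine", "straight_study", "bent_study",
           "two_channel_study", "cage_study", "affinity_study"]

#: temperature (K) for the pathway-splitting study; the others run athermal
TWO_CHANNEL_TEMPERATURE = 20.0


def desk_de_config() -> DEConfig:
    return DEConfig(population_size=48, iterations=30)


def desk_engine(temperature: float = 0.0) -> EngineConfig:
    return EngineConfig(timestep=0.01, temperature=temperature)


def _prepare(name: str):
    system, channels = make_system(standard_fixtures()[name])
    system.pulled_atom_id = select_pulled_atom(system)
    return system, channels


def _works(results, exited_only: bool = True):
    """Pulling work per trajectory; by default only trajectories that
    reached the unbound state (W_pull is the work at the end of egress)."""
    kept = [r for r in results if r.status == "exited"] if exited_only else results
    return [compute_work(r.profile).w_pull for r in kept]


def straight_study(base_seed: int = 0, n: int = 20) -> dict:
    """Single open channel: every trajectory should find it and leave."""
    system, channels = _prepare("STRAIGHT")
    results = run_ensemble(
        system, n_trajectories=n, base_seed=base_seed,
        pathfinder_cfg=PathfinderConfig(max_intervals=50),
        de_cfg=desk_de_config(), engine_cfg=desk_engine())
    labels = classify_pathways(
        [r for r in results if r.status == "exited"],
        gates=channel_gates(channels))
    return {
        "results": results,
        "success_rate": success_rate(results),
        "works": _works(results),
        "labels": labels,
    }


def bent_study(base_seed: int = 0, n: int = 20) -> dict:
    """L-shaped channel: adaptive pulling turns the elbow; a straight pull
    must squeeze through the tight vent at much higher work, showing the
    collision signature (secondary force peak)."""
    system, channels = _prepare("BENT")
    pf_multi = PathfinderConfig(max_intervals=60)
    multi = run_ensemble(system, n_trajectories=n, base_seed=base_seed,
                         pathfinder_cfg=pf_multi, de_cfg=desk_de_config(),
                         engine_cfg=desk_engine())
    pf_uni = PathfinderConfig(max_intervals=60, mode="unidirectional",
                              fixed_direction=np.array([0.0, 0.0, 1.0]))
    uni = run_ensemble(system, n_trajectories=n, base_seed=base_seed + 500,
                       pathfinder_cfg=pf_uni, de_cfg=desk_de_config(),
                       engine_cfg=desk_engine())
    return {
        "multi_results": multi,
        "uni_results": uni,
        "multi_success_rate": success_rate(multi),
        "multi_works": _works(multi),
        "uni_works": _works(uni),
        "uni_secondary_peak_fraction": float(np.mean(
            [has_secondary_peak(r.profile) for r in uni])),
    }


def two_channel_study(base_seed: int = 0, n: int = 30) -> dict:
    """Wide/easy vs narrow/tapered channel: mild thermal noise lets the
    ensemble discover both, with the easier one dominating."""
    system, channels = _prepare("TWO_CHANNEL")
    results = run_ensemble(
        system, n_trajectories=n, base_seed=base_seed,
        pathfinder_cfg=PathfinderConfig(max_intervals=70),
        de_cfg=desk_de_config(),
        engine_cfg=desk_engine(TWO_CHANNEL_TEMPERATURE))
    exited = [r for r in results if r.status == "exited"]
    labels = classify_pathways(exited, gates=channel_gates(channels))
    counts = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    return {
        "results": results,
        "success_rate": success_rate(results),
        "label_counts": counts,
        "works_by_label": {
            lab: [compute_work(r.profile).w_pull
                  for r, l in zip(exited, labels) if l == lab]
            for lab in counts},
    }


def cage_study(base_seed: int = 0, n: int = 12) -> dict:
    """Closed shell: nothing may ever leave."""
    system, _ = _prepare("CAGE")
    results = run_ensemble(
        system, n_trajectories=n, base_seed=base_seed,
        pathfinder_cfg=PathfinderConfig(max_intervals=25),
        de_cfg=desk_de_config(), engine_cfg=desk_engine())
    return {
        "results": results,
        "exit_count": sum(1 for r in results if r.status == "exited"),
    }


def affinity_study(base_seed: int = 0, depths=(2, 4, 6, 8, 10),
                   n_per_depth: int = 10) -> dict:
    """Binding-well depth series on the open channel: mean pulling work must
    rank the depths (the desk-scale analogue of ranking ligand affinities)."""
    base = standard_fixtures()["STRAIGHT"]
    systems = make_ligand_series(base, list(depths))
    mean_works, all_works = [], {}
    for i, (depth, system) in enumerate(zip(depths, systems)):
        system.pulled_atom_id = select_pulled_atom(system)
        results = run_ensemble(
            system, n_trajectories=n_per_depth,
            base_seed=base_seed + 100 * i,
            pathfinder_cfg=PathfinderConfig(max_intervals=50),
            de_cfg=desk_de_config(), engine_cfg=desk_engine())
        works = [compute_work(r.profile).w_pull for r in results
                 if r.status == "exited"]
        all_works[float(depth)] = works
        mean_works.append(float(np.mean(works)))
    rho = spearman(list(depths), mean_works)
    return {"depths": list(depths), "mean_works": mean_works,
            "works": all_works, "spearman_rho": rho}
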