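"""Orchestrate the N-interval egress loop: direction search -> pull -> checks.

Each interval either re-optimises the pulling direction with differential
evolution (multidirectional mode) or reuses a user-supplied fixed direction
(unidirectional mode), then integrates one spring-pulling interval and tests
for exit or arrest:

* exit  — the minimum ligand-receptor atom distance exceeds
  ``exit_min_distance`` at ``exit_consecutive`` consecutive interval ends
  (equivalently both truncated nonbonded components are exactly zero);
  once the threshold is first crossed the direction is frozen for the
  confirmation intervals.
* stuck — the ligand centre of mass moves less than
  ``stuck_min_displacement`` per interval for ``stuck_consecutive``
  consecutive intervals.
* max_intervals — the interval budget N (simulation time / tau) runs out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .desearch import (DEConfig, DegenerateDirectionError, ScoreConfig,
                       find_direction)
from .dynamics import EngineConfig, ForceProfile, PullSpec, run_interval
from .energy import EnergyConfig, EnergyPair, NonbondedWorkspace

__all__ = ["PathfinderConfig", "PathResult", "exit_check", "find_path",
           "run_ensemble"]


@dataclass(frozen=True)
class PathfinderConfig:
    max_intervals: int = 100
    exit_min_distance: float | None = None   # nm; default energy cutoff + 0.2
    exit_consecutive: int = 2
    stuck_min_displacement: float = 0.01     # nm per interval
    stuck_consecutive: int = 5
    mode: str = "multidirectional"           # or "unidirectional"
    fixed_direction: np.ndarray | None = None
    spring_reset: bool = False               # relax the spring at every interval

    def __post_init__(self) -> None:
        if self.max_intervals < 1:
            raise ValueError("max_intervals must be >= 1")
        if self.exit_min_distance is not None and self.exit_min_distance <= 0:
            raise ValueError("exit_min_distance must be > 0")
        if self.mode not in ("multidirectional", "unidirectional"):
            raise ValueError("mode must be multidirectional|unidirectional")
        if self.mode == "unidirectional":
            if self.fixed_direction is None:
                raise ValueError("unidirectional mode requires fixed_direction")
            d = np.asarray(self.fixed_direction, float)
            n = float(np.linalg.norm(d))
            if n == 0:
                raise ValueError("fixed_direction must be nonzero")
            object.__setattr__(self, "fixed_direction", d / n)

    def resolved_exit_distance(self, energy_cfg: EnergyConfig) -> float:
        if self.exit_min_distance is not None:
            return self.exit_min_distance
        return energy_cfg.cutoff + 0.2


@dataclass
class PathResult:
    """One egress attempt: waypoints, directions, profile, termination status."""

    waypoints: np.ndarray            # (intervals_used + 1, 3) ligand CoM, nm
    pulled_positions: np.ndarray     # (intervals_used + 1, 3) pulled atom, nm
    directions: np.ndarray           # (intervals_used, 3) unit vectors
    profile: ForceProfile            # concatenated across intervals
    energies: list[EnergyPair]       # per-interval end energies
    status: str                      # exited | stuck | max_intervals
    intervals_used: int
    seed: int | None
    tau: float
    ligand_snapshots: np.ndarray     # (intervals_used + 1, n_ligand, 3) nm
    error: str | None = None

    def exit_direction(self) -> np.ndarray:
        """Unit vector from the first to the last CoM waypoint."""
        v = self.waypoints[-1] - self.waypoints[0]
        n = float(np.linalg.norm(v))
        if n == 0:
            raise ValueError("path has zero net displacement")
        return v / n


def exit_check(min_distances: list[float], cfg: PathfinderConfig,
               energy_cfg: EnergyConfig = EnergyConfig()) -> bool:
    """True when the last exit_consecutive interval-end distances all clear
    the exit threshold."""
    thr = cfg.resolved_exit_distance(energy_cfg)
    if len(min_distances) < cfg.exit_consecutive:
        return False
    return all(d > thr for d in min_distances[-cfg.exit_consecutive:])


def _radial_fallback_direction(system) -> np.ndarray:
    """Direction away from the receptor centroid; used when the ligand starts
    outside the interaction field and no previous direction exists."""
    v = system.ligand_com() - system.receptor_positions().mean(axis=0)
    n = float(np.linalg.norm(v))
    if n == 0:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def find_path(system, pathfinder_cfg: PathfinderConfig = PathfinderConfig(),
              de_cfg: DEConfig = DEConfig(), score_cfg: ScoreConfig = ScoreConfig(),
              pull_k: float = 600.0, pull_v: float = 5.0, tau: float = 20.0,
              engine_cfg: EngineConfig = EngineConfig(),
              energy_cfg: EnergyConfig = EnergyConfig(),
              seed: int | None = None) -> PathResult:
    """Run the full egress loop for one trajectory.

    Returns a PathResult; engine aborts are recorded with the interval index
    (status "stuck", error message attached) rather than raised, so ensemble
    runs are never fatal.
    """
    if system.pulled_atom_id is None:
        raise ValueError("select a pulled atom before pathfinding")
    rng = np.random.default_rng(seed)
    base_ws = NonbondedWorkspace(system, energy_cfg)
    thr = pathfinder_cfg.resolved_exit_distance(energy_cfg)

    state = system.with_ligand_positions(system.ligand_positions())
    waypoints = [state.ligand_com()]
    pulled_positions = [state.ligand_positions()[state.pulled_index()]]
    snapshots = [state.ligand_positions()]
    directions: list[np.ndarray] = []
    energies: list[EnergyPair] = []
    segments: list[ForceProfile] = []
    min_dists: list[float] = []
    status = "max_intervals"
    error = None
    t_off, x_off = 0.0, 0.0
    anchor: np.ndarray | None = None
    last_direction: np.ndarray | None = None
    exit_streak = 0
    stuck_streak = 0

    # neighbour-pruned workspace around the current pose, margin generous
    def local_ws(st):
        com = st.ligand_com()
        ext = float(np.max(np.linalg.norm(st.ligand_positions() - com, axis=1)))
        return base_ws.subset(com, de_cfg.max_vector_length + ext + 0.3)

    n_done = 0
    for interval in range(pathfinder_cfg.max_intervals):
        lig = state.ligand_positions()
        ws = local_ws(state)
        prev_energy = ws.energies(lig)
        currently_out = ws.min_distance(lig) > thr

        if exit_streak > 0 and last_direction is not None:
            # past the exit threshold: keep the direction unchanged (confirmation)
            direction = last_direction
        elif pathfinder_cfg.mode == "unidirectional":
            direction = pathfinder_cfg.fixed_direction
        else:
            try:
                res = find_direction(state, prev_energy, de_cfg, score_cfg,
                                     energy_cfg, rng,
                                     previous_direction=last_direction,
                                     workspace=base_ws)
                direction = res.direction
            except DegenerateDirectionError:
                if currently_out:
                    direction = _radial_fallback_direction(state)
                else:
                    raise
        spec = PullSpec(direction=direction, k=pull_k, v=pull_v, tau=tau)
        try:
            result = run_interval(state, spec, engine_cfg, energy_cfg,
                                  (t_off, x_off), rng, workspace=base_ws,
                                  anchor=anchor)
        except RuntimeError as exc:
            status, error = "stuck", f"interval {interval}: {exc}"
            break
        state = state.with_ligand_positions(result.final_positions)
        n_done += 1
        directions.append(np.asarray(direction, float))
        energies.append(result.energies_end)
        segments.append(result.profile_segment)
        waypoints.append(state.ligand_com())
        pulled_positions.append(result.final_positions[state.pulled_index()])
        snapshots.append(result.final_positions)
        last_direction = np.asarray(direction, float)
        anchor = None if pathfinder_cfg.spring_reset else result.anchor_end
        t_off = result.profile_segment.times[-1]
        x_off = result.profile_segment.displacements[-1]

        d_min = local_ws(state).min_distance(state.ligand_positions())
        min_dists.append(d_min)
        exit_streak = exit_streak + 1 if d_min > thr else 0
        if exit_streak >= pathfinder_cfg.exit_consecutive:
            status = "exited"
            break
        stuck_streak = (stuck_streak + 1
                        if result.net_displacement < pathfinder_cfg.stuck_min_displacement
                        else 0)
        if stuck_streak >= pathfinder_cfg.stuck_consecutive:
            status = "stuck"
            break

    if n_done == 0 and error is None:
        raise RuntimeError("no interval completed")
    profile = ForceProfile.concatenate(segments) if segments else ForceProfile(
        np.array([0.0]), np.array([0.0]), np.array([0.0]))
    return PathResult(
        waypoints=np.array(waypoints), pulled_positions=np.array(pulled_positions),
        directions=np.array(directions), profile=profile, energies=energies,
        status=status, intervals_used=n_done, seed=seed, tau=tau,
        ligand_snapshots=np.array(snapshots), error=error,
    )


def run_ensemble(system, n_trajectories: int, base_seed: int = 0,
                 **kwargs) -> list[PathResult]:
    """Independent trajectories with seeds base_seed .. base_seed + n - 1.

    Results are order-stable and independent of execution order; individual
    failures are recorded on the PathResult, not raised.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    results = []
    for i in range(n_trajectories):
        results.append(find_path(system, seed=base_seed + i, **kwargs))
    return results
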