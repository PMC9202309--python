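"""Desk-scale steered pulling engine (overdamped Langevin / Brownian dynamics).

A dummy atom advances at constant speed v along the interval's pulling
direction; a harmonic spring of stiffness k ties it to the pulled ligand
atom.  With a freshly relaxed anchor the force along the direction is
k (v t - x), x being the pulled atom's displacement projected on the
direction since the interval start.  Across intervals the anchor is carried
over by default (vector spring, continuous through direction changes), so
extension can accumulate until receptor-ligand contacts rupture — without
accumulation the force would be bounded by ~k v tau and no bound ligand
could ever be pulled free.

Per-atom overdamped update:  dx = F/gamma dt + sqrt(2 kB T dt / gamma) N(0,1).
By default the ligand moves as a rigid body (net force over summed friction
translates all atoms; no rotation), which keeps a multi-atom ligand intact
under a single-atom pull; ``rigid_ligand=False`` integrates every ligand atom
independently (spring force on the pulled atom only, nonbonded forces on all).
Receptor atoms are held fixed.  Production-scale dynamics is delegated to an
external engine through the adapter file contract (see ``adapter``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyConfig, EnergyPair, NonbondedWorkspace

__all__ = ["PullSpec", "EngineConfig", "ForceProfile", "IntervalResult",
           "spring_force", "run_interval", "BOLTZMANN_KJ_PER_MOL_K"]

#: kB in kJ mol^-1 K^-1
BOLTZMANN_KJ_PER_MOL_K = 0.00831446261815324


@dataclass(frozen=True)
class PullSpec:
    """Moving-spring pulling parameters.

    k in kJ/mol/nm^2 (AFM-typical 600), v in nm/ns, tau (interval length) in
    ps, direction a unit 3-vector.  v = 0 is allowed for diagnostics
    (stationary spring anchor).
    """

    direction: np.ndarray
    k: float = 600.0
    v: float = 5.0
    tau: float = 20.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("direction must be unit-norm within 1e-9")
        object.__setattr__(self, "direction", d)
        if self.k <= 0 or self.v < 0 or self.tau <= 0:
            raise ValueError("require k > 0, v >= 0, tau > 0")

    @property
    def v_nm_per_ps(self) -> float:
        return self.v * 1e-3


@dataclass(frozen=True)
class EngineConfig:
    timestep: float = 0.002       # ps
    friction: float = 50.0        # kJ mol^-1 ps nm^-2 per atom
    temperature: float = 300.0    # K; 0 allowed (deterministic)
    seed: int | None = None
    rigid_ligand: bool = True
    prune_margin: float = 0.5     # nm beyond cutoff for the neighbour prune
    max_step: float = 0.03        # nm; per-step displacement cap (overlap taming)

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.friction <= 0 or self.temperature < 0:
            raise ValueError("require timestep > 0, friction > 0, temperature >= 0")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")


@dataclass
class ForceProfile:
    """Spring force / displacement time series, one sample per integrator step.

    forces: signed spring force along the instantaneous direction, kJ/mol/nm.
    displacements: cumulative pulled-atom displacement projected on the
    instantaneous direction, accumulated across intervals (backsliding makes
    it non-monotone; that is allowed).
    """

    times: np.ndarray
    forces: np.ndarray
    displacements: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        f = np.asarray(self.forces, float)
        x = np.asarray(self.displacements, float)
        if not (len(t) == len(f) == len(x)):
            raise ValueError("times, forces, displacements must have equal lengths")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times, self.forces, self.displacements = t, f, x

    def __len__(self) -> int:
        return len(self.times)

    @staticmethod
    def concatenate(profiles: list["ForceProfile"]) -> "ForceProfile":
        return ForceProfile(
            np.concatenate([p.times for p in profiles]),
            np.concatenate([p.forces for p in profiles]),
            np.concatenate([p.displacements for p in profiles]),
        )


@dataclass
class IntervalResult:
    final_positions: np.ndarray     # ligand coordinates, nm
    profile_segment: ForceProfile
    energies_end: EnergyPair
    net_displacement: float         # |CoM shift| over the interval, nm
    anchor_end: np.ndarray | None = None   # dummy-atom position at interval end


class EngineAbort(RuntimeError):
    """Non-finite force encountered (overlap deeper than the clamp guard)."""


def spring_force(t: float, x: float, spec: PullSpec) -> float:
    """Signed spring force k (v t - x): positive while the dummy leads the atom."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return spec.k * (spec.v_nm_per_ps * t - x)


def run_interval(system, spec: PullSpec, engine: EngineConfig,
                 energy_cfg: EnergyConfig, profile_offset: tuple[float, float],
                 rng: np.random.Generator,
                 workspace: NonbondedWorkspace | None = None,
                 anchor: np.ndarray | None = None) -> IntervalResult:
    """Integrate one pulling interval of length tau.

    profile_offset = (t0, x0) continues the global time/displacement
    bookkeeping across intervals so the pulling work integrates over the
    whole trajectory.  The spring force is the vector k (dummy - pulled
    atom), applied wholly to the pulled atom; the dummy advances at v along
    spec.direction from ``anchor`` (default: the pulled atom's position at
    interval start, i.e. a freshly relaxed spring).  Passing the previous
    interval's anchor_end lets spring extension accumulate across intervals,
    continuously through direction changes.  The profile is sampled every
    integrator step.
    """
    from ._kernels import integrate_interval

    t0, x0 = profile_offset
    pulled = system.pulled_index()
    pos0 = system.ligand_positions()
    com0 = system.ligand_com(pos0)
    n_lig = pos0.shape[0]
    dt = engine.timestep
    n_steps = int(round(spec.tau / dt))
    if abs(n_steps * dt - spec.tau) > 1e-9:
        raise ValueError("tau must be an integer multiple of the timestep")

    base_ws = workspace if workspace is not None else NonbondedWorkspace(system, energy_cfg)
    lig_extent = float(np.max(np.linalg.norm(pos0 - com0, axis=1)))

    gamma = engine.friction
    kBT = BOLTZMANN_KJ_PER_MOL_K * engine.temperature
    if engine.temperature > 0:
        if engine.rigid_ligand:
            scale = np.sqrt(2.0 * kBT * dt / (gamma * n_lig))
            noise = scale * rng.standard_normal((n_steps, 3))
        else:
            scale = np.sqrt(2.0 * kBT * dt / gamma)
            noise = scale * rng.standard_normal((n_steps, n_lig * 3))
    else:
        noise = np.zeros((n_steps, 3 if engine.rigid_ligand else n_lig * 3))

    anchor0 = (pos0[pulled].copy() if anchor is None
               else np.asarray(anchor, dtype=float))
    # neighbour prune with retry: the margin must cover the worst CoM drift
    margin = engine.prune_margin + lig_extent + spec.v_nm_per_ps * spec.tau
    for _attempt in range(6):
        ws = base_ws.subset(com0, margin)
        pos = pos0.copy()
        times, forces, disps, pos, max_drift, ok = integrate_interval(
            pos, ws.rec_pos, ws.qq, ws.sigma, ws.eps4,
            energy_cfg.cutoff, energy_cfg.min_distance_clamp,
            spec.k, spec.v_nm_per_ps, dt, n_steps,
            np.asarray(spec.direction, float), pulled,
            gamma, engine.rigid_ligand, noise, engine.max_step, t0, x0, anchor0)
        if not ok:
            raise EngineAbort(
                "non-finite force/displacement during the interval "
                "(ligand-receptor overlap beyond the clamp guard)")
        if max_drift + lig_extent <= margin:
            break
        margin *= 2.0
    else:
        raise EngineAbort("ligand drift exceeded every neighbour-prune margin")

    end_ws = base_ws.subset(system.ligand_com(pos), engine.prune_margin + lig_extent)
    e_elec, e_vdw = end_ws.energies_batch(pos[None])
    return IntervalResult(
        final_positions=pos,
        profile_segment=ForceProfile(times, forces, disps),
        energies_end=EnergyPair(float(e_elec[0]), float(e_vdw[0])),
        net_displacement=float(np.linalg.norm(system.ligand_com(pos) - com0)),
        anchor_end=anchor0 + spec.v_nm_per_ps * spec.tau * np.asarray(spec.direction),
    )
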