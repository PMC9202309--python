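"""Ligand-receptor Coulomb and Lennard-Jones interaction energies and forces.

Plain truncation at the cutoff (no shift, no switching): the energies feed a
score that only ranks candidate ligand translations, so absolute long-range
accuracy is immaterial.  Lorentz-Berthelot combination rules
(sigma_ij = (sigma_i + sigma_j)/2, eps_ij = sqrt(eps_i * eps_j)) match the
AMBER-family conventions.  A small distance clamp guards the floating-point
range for overlapping probe poses; physically the score's alpha-term is the
overlap guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyPair", "EnergyConfig", "pair_energy", "compute_nonbonded",
           "NonbondedWorkspace"]

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458


@dataclass(frozen=True)
class EnergyPair:
    """Electrostatic and van der Waals ligand-receptor energies, kJ/mol."""

    e_elec: float
    e_vdw: float

    @property
    def total(self) -> float:
        return self.e_elec + self.e_vdw

    def __add__(self, other: "EnergyPair") -> "EnergyPair":
        return EnergyPair(self.e_elec + other.e_elec, self.e_vdw + other.e_vdw)


@dataclass(frozen=True)
class EnergyConfig:
    cutoff: float = 1.0                     # nm
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    min_distance_clamp: float = 0.01        # nm

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.dielectric <= 0 or self.min_distance_clamp <= 0:
            raise ValueError("cutoff, dielectric and min_distance_clamp must be > 0")


def pair_energy(r: float, qi: float, qj: float, sigma_ij: float, eps_ij: float,
                config: EnergyConfig = EnergyConfig()) -> EnergyPair:
    """Energy of a single atom pair at separation r (nm).

    e_elec = f qi qj / (dielectric * max(r, clamp));
    e_vdw  = 4 eps [(sigma/r_eff)^12 - (sigma/r_eff)^6], r_eff = max(r, clamp).
    Both components are exactly 0 beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    if r > config.cutoff:
        return EnergyPair(0.0, 0.0)
    r_eff = max(r, config.min_distance_clamp)
    e_elec = config.coulomb_constant * qi * qj / (config.dielectric * r_eff)
    if eps_ij > 0 and sigma_ij > 0:
        a6 = (sigma_ij / r_eff) ** 6
        e_vdw = 4.0 * eps_ij * (a6 * a6 - a6)
    else:
        e_vdw = 0.0
    return EnergyPair(e_elec, e_vdw)


class NonbondedWorkspace:
    """Precomputed combined pair parameters for one receptor/ligand pairing.

    Caches the Lorentz-Berthelot sigma_ij, eps_ij and charge products so the
    differential-evolution search and the dynamics engine can evaluate many
    ligand poses cheaply.  ``subset`` restricts the receptor to atoms near a
    point (a plain distance prune; with a margin covering the cutoff the
    result is identical to the full sum).
    """

    def __init__(self, system, config: EnergyConfig = EnergyConfig(),
                 receptor_indices: np.ndarray | None = None) -> None:
        self.system = system
        self.config = config
        rec = system.receptor
        if receptor_indices is None:
            receptor_indices = np.arange(len(rec))
        self.receptor_indices = np.asarray(receptor_indices, dtype=int)
        sel = [rec[i] for i in self.receptor_indices]
        self.rec_pos = np.array([a.position for a in sel], dtype=float).reshape(-1, 3)
        rq = np.array([a.charge for a in sel], dtype=float)
        rs = np.array([a.sigma for a in sel], dtype=float)
        re = np.array([a.epsilon for a in sel], dtype=float)
        lq = np.array([a.charge for a in system.ligand], dtype=float)
        ls = np.array([a.sigma for a in system.ligand], dtype=float)
        le = np.array([a.epsilon for a in system.ligand], dtype=float)
        # (n_ligand, n_receptor) combined parameters
        self.qq = lq[:, None] * rq[None, :] * config.coulomb_constant / config.dielectric
        self.sigma = 0.5 * (ls[:, None] + rs[None, :])
        self.eps4 = 4.0 * np.sqrt(le[:, None] * re[None, :])

    def subset(self, center: np.ndarray, margin: float) -> "NonbondedWorkspace":
        """Workspace restricted to receptor atoms within cutoff+margin of center."""
        if self.rec_pos.shape[0] == 0:
            return self
        d = np.linalg.norm(self.rec_pos - np.asarray(center, float), axis=1)
        keep = self.receptor_indices[d <= self.config.cutoff + margin]
        return NonbondedWorkspace(self.system, self.config, keep)

    # -- energies ----------------------------------------------------------------
    def energies(self, ligand_positions: np.ndarray) -> EnergyPair:
        e_elec, e_vdw = self.energies_batch(ligand_positions[None, :, :])
        return EnergyPair(float(e_elec[0]), float(e_vdw[0]))

    def energies_batch(self, poses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Energies for a batch of ligand poses, shape (n_poses, n_ligand, 3)."""
        poses = np.asarray(poses, dtype=float)
        n, nl = poses.shape[0], poses.shape[1]
        m = self.rec_pos.shape[0]
        if m == 0:
            return np.zeros(n), np.zeros(n)
        flat = poses.reshape(n * nl, 3)
        # r^2 via |a|^2 + |b|^2 - 2 a.b (BLAS-friendly)
        r2 = ((flat * flat).sum(axis=1)[:, None]
              + (self.rec_pos * self.rec_pos).sum(axis=1)[None, :]
              - 2.0 * flat @ self.rec_pos.T)
        np.maximum(r2, 0.0, out=r2)
        r = np.sqrt(r2).reshape(n, nl, m)
        within = r <= self.config.cutoff
        r_eff = np.maximum(r, self.config.min_distance_clamp)
        e_elec = np.where(within, self.qq[None] / r_eff, 0.0).sum(axis=(1, 2))
        a6 = (self.sigma[None] / r_eff) ** 6
        e_vdw = np.where(within, self.eps4[None] * (a6 * a6 - a6), 0.0).sum(axis=(1, 2))
        return e_elec, e_vdw

    # -- forces ------------------------------------------------------------------
    def forces(self, ligand_positions: np.ndarray) -> np.ndarray:
        """Analytic nonbonded force on each ligand atom, kJ/mol/nm.

        Gradient of the truncated pair potentials; the discontinuity at the
        cutoff is accepted.  Inside the clamp radius the force is evaluated
        at the clamp distance (bounded, radially outward).
        """
        pos = np.asarray(ligand_positions, dtype=float)
        if self.rec_pos.shape[0] == 0:
            return np.zeros_like(pos)
        diff = pos[:, None, :] - self.rec_pos[None, :, :]          # (nl, nr, 3)
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        within = r <= self.config.cutoff
        r_eff = np.maximum(r, self.config.min_distance_clamp)
        a6 = (self.sigma / r_eff) ** 6
        # dE/dr terms give magnitude/r_eff along the unit separation vector
        coul = self.qq / (r_eff * r_eff)
        lj = (6.0 * self.eps4 / r_eff) * (2.0 * a6 * a6 - a6)
        mag = np.where(within, coul + lj, 0.0) / r_eff
        # guard r ~ 0: direction undefined; treat as zero contribution
        mag = np.where(r > 1e-12, mag, 0.0)
        return np.einsum("ij,ijk->ik", mag, diff)

    def min_distance(self, ligand_positions: np.ndarray) -> float:
        """Minimum ligand-receptor atom distance (inf for an empty receptor set)."""
        if self.rec_pos.shape[0] == 0:
            return float("inf")
        pos = np.asarray(ligand_positions, dtype=float)
        diff = pos[:, None, :] - self.rec_pos[None, :, :]
        return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min())


def compute_nonbonded(system, ligand_positions: np.ndarray,
                      config: EnergyConfig = EnergyConfig()) -> EnergyPair:
    """Total ligand-receptor interaction energies for an arbitrary ligand pose.

    Sums pair_energy over all ligand-receptor pairs within the cutoff;
    intra-ligand and intra-receptor pairs are excluded by construction.
    """
    pos = np.asarray(ligand_positions, dtype=float)
    if pos.shape != (len(system.ligand), 3):
        raise ValueError("ligand_positions length must equal the ligand atom count")
    return NonbondedWorkspace(system, config).energies(pos)
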