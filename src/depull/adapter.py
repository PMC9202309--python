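"""File contract for driving one pulling interval on an external MD engine.

Per interval the pathfinder writes a plain-text direction file

    # direction_x direction_y direction_z k_kJ_per_mol_nm2 v_nm_per_ns tau_ps
    0.0 0.0 1.0 600 5 20

plus the current ligand coordinates (PDB), and expects back a coordinate
file (PDB or GRO) with the ligand pose at the interval end and a force
profile in the package's 3-column text format (time ps, displacement nm,
force kJ/mol/nm).  ``ExternalEngineAdapter`` satisfies the same operation
contract as the built-in toy engine's ``run_interval``, so the pathfinder
is agnostic about which one executes the dynamics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np

from .dynamics import ForceProfile, IntervalResult, PullSpec
from .energy import EnergyConfig, NonbondedWorkspace
from .structures import read_profile, write_system_pdb, _read_structure

__all__ = ["write_direction_file", "read_direction_file", "ExternalEngineAdapter"]


def write_direction_file(path: str | Path, spec: PullSpec) -> None:
    d = spec.direction
    Path(path).write_text(
        "# direction_x direction_y direction_z k_kJ_per_mol_nm2 v_nm_per_ns tau_ps\n"
        f"{d[0]:.12g} {d[1]:.12g} {d[2]:.12g} {spec.k:.12g} {spec.v:.12g} {spec.tau:.12g}\n"
    )


def read_direction_file(path: str | Path) -> PullSpec:
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        vals = [float(v) for v in line.split()]
        if len(vals) != 6:
            raise ValueError(f"{path}: expected 6 values (direction, k, v, tau)")
        return PullSpec(direction=np.array(vals[:3]), k=vals[3], v=vals[4], tau=vals[5])
    raise ValueError(f"{path}: no direction record found")


class ExternalEngineAdapter:
    """Run intervals by file exchange with an external engine.

    ``runner(workdir)`` is invoked after the direction and coordinate files
    are written; it must leave ``ligand_out.pdb`` (or ``.gro``) and
    ``profile_out.dat`` in the directory.  In production the runner shells
    out to the MD engine; in tests the toy engine can stand on the far side
    of the same contract.
    """

    DIRECTION_FILE = "direction.dat"
    LIGAND_IN = "ligand_in.pdb"
    LIGAND_OUT_CANDIDATES = ("ligand_out.pdb", "ligand_out.gro")
    PROFILE_OUT = "profile_out.dat"

    def __init__(self, workdir: str | Path, runner: Callable[[Path], None]) -> None:
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.runner = runner

    def run_interval(self, system, spec: PullSpec, engine, energy_cfg: EnergyConfig,
                     profile_offset: tuple[float, float], rng) -> IntervalResult:
        write_direction_file(self.workdir / self.DIRECTION_FILE, spec)
        write_system_pdb(system, self.workdir / "receptor_in.pdb",
                         self.workdir / self.LIGAND_IN)
        self.runner(self.workdir)
        out = None
        for cand in self.LIGAND_OUT_CANDIDATES:
            if (self.workdir / cand).exists():
                out = self.workdir / cand
                break
        if out is None:
            raise FileNotFoundError("external engine produced no ligand_out coordinate file")
        _, _, pos = _read_structure(out)
        if pos.shape[0] != len(system.ligand):
            raise ValueError("external engine returned a different ligand atom count")
        profile = read_profile(self.workdir / self.PROFILE_OUT)
        com0 = system.ligand_com()
        new_sys = system.with_ligand_positions(pos)
        ws = NonbondedWorkspace(new_sys, energy_cfg)
        energies = ws.energies(pos)
        return IntervalResult(
            final_positions=pos,
            profile_segment=profile,
            energies_end=energies,
            net_displacement=float(np.linalg.norm(new_sys.ligand_com() - com0)),
        )
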