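"""Molecular structures, nonbonded parameter tables and on-disk formats.

Internal units throughout the package: nm (length), ps (time), kJ/mol
(energy), elementary charge (e).  PDB files carry Angstrom and are
converted at the boundary; GRO files already carry nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.gro as _gro

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "ParameterTable",
    "ParameterLookupError",
    "load_parameter_table",
    "load_system",
    "select_pulled_atom",
    "write_system_pdb",
    "write_path",
    "read_waypoints",
    "write_profile",
    "read_profile",
]

_ANGSTROM_PER_NM = 10.0


class ParameterLookupError(KeyError):
    """Raised when atoms in a structure have no entry in the parameter table."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates (nm) and nonbonded parameters.

    charge in elementary charge units, sigma in nm, epsilon in kJ/mol.
    role is "receptor" or "ligand".
    """

    atom_id: int
    name: str
    position: np.ndarray
    charge: float
    sigma: float
    epsilon: float
    role: str
    mass: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError(f"atom {self.atom_id}: sigma and epsilon must be >= 0")
        if self.role not in ("receptor", "ligand"):
            raise ValueError(f"atom {self.atom_id}: role must be receptor|ligand")


@dataclass
class MolecularSystem:
    """Receptor + ligand atom lists; the state the whole protocol acts on."""

    receptor: list[AtomRecord]
    ligand: list[AtomRecord]
    pulled_atom_id: int | None = None

    def __post_init__(self) -> None:
        if not self.receptor or not self.ligand:
            raise ValueError("receptor and ligand atom lists must both be non-empty")
        ids = [a.atom_id for a in self.receptor] + [a.atom_id for a in self.ligand]
        if len(ids) != len(set(ids)):
            raise ValueError("atom_ids must be unique within the system")
        if self.pulled_atom_id is not None:
            if self.pulled_atom_id not in {a.atom_id for a in self.ligand}:
                raise ValueError("pulled_atom_id must refer to a ligand atom")

    # --- convenient array views -------------------------------------------------
    def receptor_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.receptor], dtype=float)

    def ligand_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand], dtype=float)

    def ligand_masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.ligand], dtype=float)

    def ligand_com(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted ligand centre of mass (unit masses by default)."""
        pos = self.ligand_positions() if positions is None else np.asarray(positions)
        m = self.ligand_masses()
        return (m[:, None] * pos).sum(axis=0) / m.sum()

    def pulled_index(self) -> int:
        """Index of the pulled atom within the ligand list."""
        if self.pulled_atom_id is None:
            raise ValueError("no pulled atom selected")
        for i, a in enumerate(self.ligand):
            if a.atom_id == self.pulled_atom_id:
                return i
        raise AssertionError("pulled_atom_id not in ligand")  # unreachable

    def with_ligand_positions(self, positions: np.ndarray) -> "MolecularSystem":
        pos = np.asarray(positions, dtype=float)
        if pos.shape != (len(self.ligand), 3):
            raise ValueError("positions shape must match ligand atom count")
        new_lig = [replace(a, position=p) for a, p in zip(self.ligand, pos)]
        return MolecularSystem(self.receptor, new_lig, self.pulled_atom_id)


@dataclass
class ParameterTable:
    """Maps atom name (optionally qualified by residue name) to (charge, sigma, epsilon).

    Residue-qualified entries ("RES:NAME") take precedence over bare names.
    """

    entries: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def add(self, name: str, charge: float, sigma: float, epsilon: float,
            resname: str | None = None) -> None:
        key = f"{resname}:{name}" if resname else name
        if key in self.entries and self.entries[key] != (charge, sigma, epsilon):
            raise ValueError(f"conflicting parameter entry for {key!r}")
        self.entries[key] = (float(charge), float(sigma), float(epsilon))

    def lookup(self, name: str, resname: str | None = None) -> tuple[float, float, float]:
        if resname is not None and f"{resname}:{name}" in self.entries:
            return self.entries[f"{resname}:{name}"]
        if name in self.entries:
            return self.entries[name]
        raise ParameterLookupError(name)


def load_parameter_table(path: str | Path) -> ParameterTable:
    """Read a delimited text table: name[, resname], charge, sigma, epsilon.

    Lines starting with '#' are comments.  3 trailing numeric columns are
    required; one or two leading string columns give the atom name and the
    optional residue qualifier.
    """
    table = ParameterTable()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            if len(parts) == 4:
                name, charge, sigma, eps = parts
                table.add(name, float(charge), float(sigma), float(eps))
            elif len(parts) == 5:
                name, resname, charge, sigma, eps = parts
                table.add(name, float(charge), float(sigma), float(eps), resname=resname)
            else:
                raise ValueError("expected 4 or 5 columns")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed parameter line: {raw!r} ({exc})")
    return table


def _read_structure(path: str | Path):
    """Read a single-frame structure; returns (names, resnames, positions_nm)."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".gro":
            arr = _gro.GROFile.read(str(path)).get_structure(model=1)
            # biotite converts GRO nm -> Angstrom internally; undo at the boundary
            pos_nm = arr.coord / _ANGSTROM_PER_NM
        elif suffix in (".pdb", ".ent"):
            arr = _pdb.PDBFile.read(str(path)).get_structure(model=1)
            pos_nm = arr.coord / _ANGSTROM_PER_NM
        else:
            raise ValueError(f"unsupported structure format: {path.name!r} "
                             "(expected .pdb or .gro)")
    except ValueError:
        raise
    except Exception as exc:  # biotite raises format-specific errors
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    names = [n.strip() for n in arr.atom_name]
    resnames = [r.strip() for r in arr.res_name]
    return names, resnames, np.asarray(pos_nm, dtype=float)


def load_system(receptor_path: str | Path, ligand_path: str | Path,
                params: ParameterTable) -> MolecularSystem:
    """Load receptor and ligand structures and assign nonbonded parameters.

    Formats detected by extension (.pdb / .gro).  Coordinates are converted
    to nm.  Atoms whose names are missing from the table raise a
    ParameterLookupError listing every offending atom.
    """
    atoms: list[AtomRecord] = []
    missing: list[str] = []
    next_id = 1
    for path, role in ((receptor_path, "receptor"), (ligand_path, "ligand")):
        names, resnames, pos = _read_structure(path)
        for name, resname, p in zip(names, resnames, pos):
            try:
                charge, sigma, eps = params.lookup(name, resname)
            except ParameterLookupError:
                missing.append(f"{resname}/{name}")
                charge = sigma = eps = 0.0
            atoms.append(AtomRecord(next_id, name, p, charge, sigma, eps, role))
            next_id += 1
    if missing:
        raise ParameterLookupError(
            "no parameters for atoms: " + ", ".join(sorted(set(missing))))
    receptor = [a for a in atoms if a.role == "receptor"]
    ligand = [a for a in atoms if a.role == "ligand"]
    return MolecularSystem(receptor, ligand)


def select_pulled_atom(system: MolecularSystem, heavy_only: bool = False) -> int:
    """Return the id of the ligand atom closest to the ligand centre of mass.

    The harmonic spring of the pulling stage attaches to this atom.  Ties are
    broken by lowest atom_id.  With heavy_only, atoms named like hydrogens
    (name starting with H) are excluded from the scan.
    """
    candidates = [a for a in system.ligand
                  if not (heavy_only and a.name.upper().startswith("H"))]
    if not candidates:
        raise ValueError("no candidate ligand atoms for pulled-atom selection")
    com = system.ligand_com()
    best = min(candidates,
               key=lambda a: (float(np.linalg.norm(a.position - com)), a.atom_id))
    return best.atom_id


# --- writing ---------------------------------------------------------------------

def _atom_array(atoms: Sequence[AtomRecord], positions_nm: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.asarray(positions_nm, dtype=float) * _ANGSTROM_PER_NM
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_name = np.array(["REC" if a.role == "receptor" else "LIG" for a in atoms])
    arr.res_id = np.array([1 if a.role == "receptor" else 2 for a in atoms])
    arr.chain_id = np.array(["A" if a.role == "receptor" else "B" for a in atoms])
    arr.element = np.array([(a.name[:1] or "X").upper() for a in atoms])
    arr.hetero = np.array([a.role == "ligand" for a in atoms])
    return arr


def write_system_pdb(system: MolecularSystem, receptor_path: str | Path,
                     ligand_path: str | Path) -> None:
    """Write receptor and ligand as separate single-model PDB files (Angstrom)."""
    for atoms, path in ((system.receptor, receptor_path), (system.ligand, ligand_path)):
        f = _pdb.PDBFile()
        f.set_structure(_atom_array(atoms, np.array([a.position for a in atoms])))
        f.write(str(path))


def write_parameter_table(system: MolecularSystem, path: str | Path) -> None:
    """Write a parameter table covering every distinct atom name in the system."""
    lines = ["# name charge sigma epsilon"]
    seen: dict[str, tuple[float, float, float]] = {}
    for a in system.receptor + system.ligand:
        trip = (a.charge, a.sigma, a.epsilon)
        if a.name in seen and seen[a.name] != trip:
            raise ValueError(f"atom name {a.name!r} maps to conflicting parameters; "
                             "rename atoms before exporting a table")
        seen[a.name] = trip
    for name, (q, s, e) in seen.items():
        lines.append(f"{name} {q:.6g} {s:.6g} {e:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


_WAYPOINT_COLUMNS = ["interval", "time_ps", "com_x", "com_y", "com_z",
                     "dir_x", "dir_y", "dir_z", "e_elec", "e_vdw"]


def write_path(path_result, out_prefix: str | Path, system: MolecularSystem | None = None) -> tuple[Path, Path]:
    """Persist one egress attempt: waypoint CSV + multi-model PDB of ligand snapshots.

    Returns (csv_path, pdb_path).  Directions are written unit-norm; the CSV
    round-trips losslessly through read_waypoints.
    """
    out_prefix = Path(out_prefix)
    if path_result.intervals_used < 1:
        raise ValueError("path is empty")
    rows = []
    for i in range(path_result.intervals_used):
        d = path_result.directions[i]
        n = float(np.linalg.norm(d))
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            d = d / n
        com = path_result.waypoints[i + 1]
        e = path_result.energies[i]
        rows.append([i, (i + 1) * path_result.tau, *com, *d, e.e_elec, e.e_vdw])
    df = pd.DataFrame(rows, columns=_WAYPOINT_COLUMNS)
    csv_path = out_prefix.with_suffix(".waypoints.csv")
    df.to_csv(csv_path, index=False, float_format="%.12g")

    pdb_path = out_prefix.with_suffix(".snapshots.pdb")
    snaps = np.asarray(path_result.ligand_snapshots)  # (n_models, n_atoms, 3) nm
    if system is not None:
        template = system.ligand
    else:
        template = [AtomRecord(i + 1, f"L{i+1}", snaps[0, i], 0.0, 0.0, 0.0, "ligand")
                    for i in range(snaps.shape[1])]
    arrays = [_atom_array(template, frame) for frame in snaps]
    f = _pdb.PDBFile()
    f.set_structure(struc.stack(arrays))
    f.write(str(pdb_path))
    return csv_path, pdb_path


def read_waypoints(csv_path: str | Path) -> pd.DataFrame:
    """Read back a waypoint table written by write_path."""
    df = pd.read_csv(csv_path)
    missing = set(_WAYPOINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waypoint table missing columns: {sorted(missing)}")
    return df


def write_profile(profile, path: str | Path) -> None:
    """Write a force profile as 3-column text: time ps, displacement nm, force kJ/mol/nm."""
    data = np.column_stack([profile.times, profile.displacements, profile.forces])
    header = "time_ps displacement_nm force_kJ_per_mol_nm"
    np.savetxt(str(path), data, header=header, fmt="%.10g")


def read_profile(path: str | Path):
    """Read a 3-column force profile (xvg-style comment lines tolerated)."""
    from .dynamics import ForceProfile  # local import to avoid cycle

    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line[0] in "#@;":
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        rows.append([float(p) for p in parts[:3]])
    if not rows:
        raise ValueError(f"{path}: empty profile")
    data = np.array(rows)
    return ForceProfile(times=data[:, 0], displacements=data[:, 1], forces=data[:, 2])
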