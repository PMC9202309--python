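"""Toy receptor-ligand systems with known ground-truth egress channels.

The receptor is a thick spherical shell: concentric near-uniform
(Fibonacci-sphere) layers of neutral Lennard-Jones atoms between an inner
cavity radius and the outer shell radius.  Channels are carved by deleting
every receptor atom within a clearance radius of a centreline polyline that
runs from the binding site to the exterior; each channel carries a labelled
exterior gate sphere for ground-truth pathway classification.  A ring of
attractive "site" atoms around the cavity centre realises a binding well of
prescribed depth: the ring epsilon is calibrated so the ligand's bound-pose
interaction energy equals -epsilon_site.

The default ligand is a rigid 3-atom equilateral triangle, small enough
that the direction search's probe ball spans meaningful energy differences
at fixture scale.  In-layer spacing is kept below 2^(1/6) sigma so the
ligand cannot leak between shell atoms except through a channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structures import AtomRecord, MolecularSystem
from .energy import EnergyConfig, NonbondedWorkspace

__all__ = ["ChannelSpec", "SyntheticSystemSpec", "make_system",
           "make_ligand_series", "standard_fixtures", "channel_gates"]


@dataclass(frozen=True)
class ChannelSpec:
    label: str
    waypoints: np.ndarray        # (n, 3) polyline, nm, site -> exterior
    radius: float                # nm, atom-free clearance around the centreline
    gate_center: np.ndarray      # nm
    gate_radius: float           # nm
    segment_radii: tuple | None = None   # per-segment clearance (tapered channels)

    def __post_init__(self) -> None:
        wp = np.asarray(self.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 3:
            raise ValueError("waypoints must be an (n>=2, 3) polyline")
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "gate_center", np.asarray(self.gate_center, float))
        if self.radius <= 0 or self.gate_radius <= 0:
            raise ValueError("radius and gate_radius must be > 0")
        if self.segment_radii is not None:
            if len(self.segment_radii) != wp.shape[0] - 1:
                raise ValueError("segment_radii must have one entry per segment")
            if any(r <= 0 for r in self.segment_radii):
                raise ValueError("segment radii must be > 0")

    def _radii(self) -> list[float]:
        n_seg = self.waypoints.shape[0] - 1
        return (list(self.segment_radii) if self.segment_radii is not None
                else [self.radius] * n_seg)

    def distance_to_centerline(self, points: np.ndarray) -> np.ndarray:
        """Distance of each point to the polyline (segment-wise)."""
        pts = np.atleast_2d(np.asarray(points, float))
        best = np.full(len(pts), np.inf)
        for a, b in zip(self.waypoints[:-1], self.waypoints[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(pts))
            closest = a + t[:, None] * ab
            best = np.minimum(best, np.linalg.norm(pts - closest, axis=1))
        return best

    def in_clearance(self, points: np.ndarray) -> np.ndarray:
        """True for points inside the (possibly tapered) carve clearance."""
        pts = np.atleast_2d(np.asarray(points, float))
        inside = np.zeros(len(pts), dtype=bool)
        for (a, b), rad in zip(zip(self.waypoints[:-1], self.waypoints[1:]),
                               self._radii()):
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(pts))
            closest = a + t[:, None] * ab
            inside |= np.linalg.norm(pts - closest, axis=1) <= rad
        return inside


@dataclass(frozen=True)
class SyntheticSystemSpec:
    shell_radius: float = 1.08         # outer radius of the solid, nm
    cavity_radius: float = 0.45        # binding-pocket radius (innermost layer), nm
    shell_atom_spacing: float = 0.21   # in-layer and radial spacing, nm
    shell_sigma: float = 0.2           # nm
    shell_epsilon: float = 0.3         # kJ/mol
    shell_charge: float = 0.0          # e
    channels: tuple[ChannelSpec, ...] = ()
    site_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    epsilon_site: float = 6.0          # kJ/mol binding-well depth
    site_ring_radius: float = 0.30     # nm
    site_ring_sigma: float = 0.05      # nm; small sigma keeps the well short-ranged
    site_ring_atoms: int = 6
    ligand_atoms: int = 3
    ligand_side: float = 0.15          # nm, triangle edge
    ligand_sigma: float = 0.3
    ligand_epsilon: float = 1.0
    ligand_charge: float = 0.0         # per-atom charge on one atom if nonzero
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_center", np.asarray(self.site_center, float))
        if self.epsilon_site < 0:
            raise ValueError("epsilon_site must be >= 0")
        if self.shell_atom_spacing >= 2 ** (1 / 6) * self.shell_sigma:
            raise ValueError("shell_atom_spacing must stay below 2^(1/6) sigma "
                             "(leak-proof shell)")
        labels = [c.label for c in self.channels]
        if len(labels) != len(set(labels)):
            raise ValueError("channel labels must be unique")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _ligand_template(spec: SyntheticSystemSpec) -> np.ndarray:
    """Rigid ligand coordinates centred on the site (xy-plane triangle)."""
    if spec.ligand_atoms == 1:
        return spec.site_center[None, :].copy()
    if spec.ligand_atoms == 3:
        r = spec.ligand_side / math.sqrt(3.0)
        ang = np.array([0.0, 2 * math.pi / 3, 4 * math.pi / 3])
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)])
        return pts + spec.site_center
    raise ValueError("ligand_atoms must be 1 or 3")


def _site_ring(spec: SyntheticSystemSpec) -> np.ndarray:
    ang = 2 * math.pi * np.arange(spec.site_ring_atoms) / spec.site_ring_atoms
    ring = np.column_stack([spec.site_ring_radius * np.cos(ang),
                            spec.site_ring_radius * np.sin(ang),
                            np.zeros(len(ang))])
    return ring + spec.site_center


def _calibrate_site_epsilon(spec: SyntheticSystemSpec,
                            energy_cfg: EnergyConfig) -> float:
    """Per-ring-atom epsilon such that the bound-pose ligand-ring LJ energy
    equals -epsilon_site (linear in the combined pair epsilon)."""
    if spec.epsilon_site == 0:
        return 0.0
    lig = _ligand_template(spec)
    ring = _site_ring(spec)
    sigma_ij = 0.5 * (spec.ligand_sigma + spec.site_ring_sigma)
    total = 0.0
    for lp in lig:
        for rp in ring:
            r = float(np.linalg.norm(lp - rp))
            if r > energy_cfg.cutoff:
                continue
            a6 = (sigma_ij / max(r, energy_cfg.min_distance_clamp)) ** 6
            total += 4.0 * (a6 * a6 - a6)       # per unit pair-epsilon
    if total >= 0:
        raise ValueError("site ring is not attractive at the bound pose; "
                         "adjust site_ring_radius")
    eps_pair = spec.epsilon_site / (-total)
    # Lorentz-Berthelot: eps_pair = sqrt(eps_ring * eps_ligand)
    return eps_pair ** 2 / spec.ligand_epsilon


def make_system(spec: SyntheticSystemSpec,
                energy_cfg: EnergyConfig = EnergyConfig()
                ) -> tuple[MolecularSystem, list[ChannelSpec]]:
    """Build the synthetic receptor-ligand system; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    s = spec.shell_atom_spacing
    radii = np.arange(spec.cavity_radius, spec.shell_radius + 1e-9, s)
    if len(radii) == 0:
        raise ValueError("no room for shell layers between cavity and outer radius")
    shell_points = []
    for r in radii:
        n = max(8, int(round(4.0 * math.pi * r * r / (s * s))))
        pts = _fibonacci_sphere(n) * r
        pts = pts @ _random_rotation(rng).T   # decorrelate layer seams
        shell_points.append(pts + spec.site_center)
    shell = np.concatenate(shell_points, axis=0)

    keep = np.ones(len(shell), dtype=bool)
    for ch in spec.channels:
        if min(ch._radii()) <= 0.5 * spec.ligand_side + 0.05:
            raise ValueError(f"channel {ch.label!r}: radius too small for the ligand")
        keep &= ~ch.in_clearance(shell)
    shell = shell[keep]

    site_eps = _calibrate_site_epsilon(spec, energy_cfg)
    ring = _site_ring(spec)

    atoms: list[AtomRecord] = []
    next_id = 1
    for p in shell:
        atoms.append(AtomRecord(next_id, "SH", p, spec.shell_charge,
                                spec.shell_sigma, spec.shell_epsilon, "receptor"))
        next_id += 1
    for p in ring:
        atoms.append(AtomRecord(next_id, "SI", p, 0.0, spec.site_ring_sigma,
                                site_eps, "receptor"))
        next_id += 1
    ligand: list[AtomRecord] = []
    for j, p in enumerate(_ligand_template(spec)):
        q = spec.ligand_charge if j == 0 else 0.0
        ligand.append(AtomRecord(next_id, f"L{j+1}", p, q, spec.ligand_sigma,
                                 spec.ligand_epsilon, "ligand"))
        next_id += 1

    system = MolecularSystem(receptor=atoms, ligand=ligand)
    return system, list(spec.channels)


def make_ligand_series(base: SyntheticSystemSpec, well_depths,
                       energy_cfg: EnergyConfig = EnergyConfig()
                       ) -> list[MolecularSystem]:
    """Identical geometry, varying only the binding-well depth epsilon_site.

    The fixture for the work-vs-affinity rank-correlation property: deeper
    wells should require more pulling work.
    """
    systems = []
    for depth in well_depths:
        if depth < 0:
            raise ValueError("well depths must be >= 0")
        sys_d, _ = make_system(replace(base, epsilon_site=float(depth)), energy_cfg)
        systems.append(sys_d)
    return systems


def channel_gates(channels) -> list[tuple[str, np.ndarray, float]]:
    """Gate tuples (label, center, radius) for classify_pathways."""
    return [(c.label, c.gate_center, c.gate_radius) for c in channels]


def _channel(label: str, waypoints, radius: float, gate_center,
             gate_radius: float = 0.7) -> ChannelSpec:
    return ChannelSpec(label=label, waypoints=np.asarray(waypoints, float),
                       radius=radius, gate_center=np.asarray(gate_center, float),
                       gate_radius=gate_radius)


def standard_fixtures() -> dict[str, SyntheticSystemSpec]:
    """The four canonical fixtures used across the test suite.

    STRAIGHT — one axial channel along +z; the minimal open-tunnel system.
    BENT — one L-shaped channel (one 90 degree turn): straight pulling along
        the initial axis collides with the solid above the elbow, the
        multidirectional search has to turn; the demonstrator for
        unidirectional failure.
    TWO_CHANNEL — a wide low-barrier channel (+z) and a narrow tighter one
        (-z); exercises multi-pathway discovery and population ordering.
    CAGE — closed shell, no channel; nothing should ever exit.
    """
    straight = SyntheticSystemSpec(
        channels=(_channel("axial", [[0, 0, 0.25], [0, 0, 2.2]], 0.35, [0, 0, 2.4]),),
    )
    # BENT: the easy route turns 90 degrees at the elbow; straight ahead the
    # tunnel continues only as a tight vent that a straight pull must squeeze
    # through at high force (the obstructed-tunnel scenario for which
    # multidirectional pulling exists).
    bent = SyntheticSystemSpec(
        shell_radius=1.30,
        channels=(
            _channel("elbow",
                     [[0, 0, 0.25], [0, 0, 0.72], [2.2, 0, 0.72]], 0.35,
                     [2.3, 0, 0.9], gate_radius=1.0),
            _channel("vent", [[0, 0, 0.72], [0, 0, 2.0]], 0.26, [0, 0, 2.3],
                     gate_radius=0.6),
        ),
    )
    # TWO_CHANNEL: mouths of equal width so the first direction choice is a
    # genuine near-tie; the narrow route tapers deeper in, making it the
    # higher-work minority pathway.
    two_channel = SyntheticSystemSpec(
        channels=(
            _channel("wide", [[0, 0, 0.30], [0, 0, 2.2]], 0.42, [0, 0, 2.4]),
            ChannelSpec("narrow", np.array([[0, 0, -0.30], [0, 0, -0.95],
                                            [0, 0, -2.2]]),
                        0.40, np.array([0, 0, -2.4]), 0.7,
                        segment_radii=(0.40, 0.30)),
        ),
    )
    cage = SyntheticSystemSpec(shell_radius=0.87, channels=())
    return {"STRAIGHT": straight, "BENT": bent, "TWO_CHANNEL": two_channel,
            "CAGE": cage}
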