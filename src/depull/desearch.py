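"""Differential-evolution search for the next pulling direction.

For one pulling interval the ligand is rigidly translated by trial vectors
drawn from a ball of radius ``max_vector_length`` and each probe pose is
scored with

    E_score = (E_elec + E_vdw)_current - (E_elec + E_vdw)_previous
              + alpha * |(E_elec + E_vdw)_current|

The alpha-term penalises sitting in (or moving into) any strongly
interacting pose: it stops the search from being trapped in deep minima and
keeps probes from overlapping the receptor.  The translation that minimises
the score, normalised, becomes the next pulling direction.

The optimiser is classic DE/rand/1/bin (Storn-Price): mutant
``x_r1 + F * (x_r2 - x_r3)`` with three distinct partners, binomial
crossover with one guaranteed mutant coordinate, greedy selection with ties
keeping the incumbent.  Infeasible trials (norm beyond the ball) are
rescaled radially onto the ball boundary, which preserves the search
direction and keeps feasibility exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyConfig, EnergyPair, NonbondedWorkspace

__all__ = ["ScoreConfig", "DEConfig", "TranslationCandidate", "DirectionResult",
           "e_score", "sample_population", "de_minimize", "find_direction",
           "DegenerateDirectionError"]


class DegenerateDirectionError(RuntimeError):
    """First-interval search found no usable direction (zero interaction field)."""


@dataclass(frozen=True)
class ScoreConfig:
    """alpha weights the |current interaction| trap-escape/overlap term."""

    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class DEConfig:
    population_size: int = 3000
    max_vector_length: float = 0.7     # nm (7 A)
    iterations: int = 100
    crossover_prob: float = 0.9        # CR
    diff_weight: float = 0.5           # F
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("DE needs population_size >= 4 (3 partners + target)")
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.diff_weight <= 0 or self.max_vector_length <= 0:
            raise ValueError("diff_weight and max_vector_length must be > 0")


@dataclass(frozen=True)
class TranslationCandidate:
    vector: np.ndarray          # nm, norm <= max_vector_length
    score: float | None = None  # kJ/mol


@dataclass(frozen=True)
class DirectionResult:
    direction: np.ndarray       # unit vector
    best_vector: np.ndarray     # nm
    best_score: float           # kJ/mol
    best_energy: EnergyPair
    degenerate: bool = False


def e_score(current: EnergyPair, previous: EnergyPair,
            cfg: ScoreConfig = ScoreConfig()) -> float:
    """Score of a probe pose relative to the pose at the end of the last interval."""
    cur = current.e_elec + current.e_vdw
    prev = previous.e_elec + previous.e_vdw
    return cur - prev + cfg.alpha * abs(cur)


def _sample_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in the solid ball of the given radius."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = rng.random((n, 1))
    return v / norms * radius * np.cbrt(u)


def sample_population(cfg: DEConfig, rng: np.random.Generator) -> list[TranslationCandidate]:
    """Initial unscored population: vectors uniform in the feasible ball."""
    vecs = _sample_ball(cfg.population_size, cfg.max_vector_length, rng)
    return [TranslationCandidate(v) for v in vecs]


def _distinct_partners(n: int, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    """Three random indices per target, mutually distinct and != target."""
    idx = np.arange(n)
    partners = []
    taken = [idx]
    for _ in range(3):
        r = rng.integers(0, n, size=n)
        bad = np.zeros(n, dtype=bool)
        for t in taken + partners:
            bad |= r == t
        while bad.any():
            r = np.where(bad, rng.integers(0, n, size=n), r)
            bad = np.zeros(n, dtype=bool)
            for t in taken + partners:
                bad |= r == t
        partners.append(r)
    return tuple(partners)


def de_minimize(objective, cfg: DEConfig, rng: np.random.Generator,
                vectorized: bool = False) -> tuple[np.ndarray, float]:
    """Minimise objective over the ball of radius max_vector_length.

    objective maps a 3-vector to a number; with vectorized=True it must map
    an (n, 3) array to an (n,) array.  Non-finite objective values are
    treated as +inf (such candidates are never selected).  Runs exactly
    cfg.iterations generations and returns (best_vector, best_value); among
    equal-score finalists the lowest population index wins.
    """
    if not vectorized:
        scalar = objective
        objective = lambda vs: np.array([scalar(v) for v in vs], dtype=float)

    def evaluate(vs: np.ndarray) -> np.ndarray:
        vals = np.asarray(objective(vs), dtype=float)
        return np.where(np.isfinite(vals), vals, np.inf)

    n, radius = cfg.population_size, cfg.max_vector_length
    pop = _sample_ball(n, radius, rng)
    scores = evaluate(pop)

    for _ in range(cfg.iterations):
        r1, r2, r3 = _distinct_partners(n, rng)
        mutant = pop[r1] + cfg.diff_weight * (pop[r2] - pop[r3])
        cross = rng.random((n, 3)) < cfg.crossover_prob
        jrand = rng.integers(0, 3, size=n)
        cross[np.arange(n), jrand] = True
        trial = np.where(cross, mutant, pop)
        norms = np.linalg.norm(trial, axis=1)
        over = norms > radius
        if over.any():
            trial[over] *= (radius / norms[over])[:, None]
        trial_scores = evaluate(trial)
        better = trial_scores < scores          # strict: ties keep the target
        pop[better] = trial[better]
        scores[better] = trial_scores[better]

    best = int(np.argmin(scores))               # lowest index on ties
    return pop[best].copy(), float(scores[best])


def find_direction(system, previous_energy: EnergyPair,
                   de_cfg: DEConfig, score_cfg: ScoreConfig,
                   energy_cfg: EnergyConfig, rng: np.random.Generator,
                   previous_direction: np.ndarray | None = None,
                   workspace: NonbondedWorkspace | None = None) -> DirectionResult:
    """One interval's direction search over rigid ligand translations.

    previous_energy is the interaction energy of the ligand's current
    (untranslated) pose.  If the best translation is degenerate (zero-length
    vector, or the probe field is identically zero because no receptor atom
    is in reach), the previous interval's direction is reused and flagged;
    on the first interval that raises DegenerateDirectionError.
    """
    if system.pulled_atom_id is None:
        raise ValueError("select a pulled atom before searching directions")
    lig0 = system.ligand_positions()
    ws = workspace if workspace is not None else NonbondedWorkspace(system, energy_cfg)
    # prune to atoms reachable by any probe pose (exact: margin covers the probes)
    lig_extent = float(np.max(np.linalg.norm(lig0 - system.ligand_com(lig0), axis=1)))
    ws = ws.subset(system.ligand_com(lig0), de_cfg.max_vector_length + lig_extent + 1e-9)

    def objective(vs: np.ndarray) -> np.ndarray:
        poses = lig0[None, :, :] + vs[:, None, :]
        e_elec, e_vdw = ws.energies_batch(poses)
        cur = e_elec + e_vdw
        prev = previous_energy.e_elec + previous_energy.e_vdw
        return cur - prev + score_cfg.alpha * np.abs(cur)

    best_vec, best_score = de_minimize(objective, de_cfg, rng, vectorized=True)
    e_elec, e_vdw = ws.energies_batch(lig0[None] + best_vec[None, None, :])
    best_energy = EnergyPair(float(e_elec[0]), float(e_vdw[0]))

    zero_field = ws.rec_pos.shape[0] == 0 or (
        best_score == 0.0 and best_energy.total == 0.0 and previous_energy.total == 0.0)
    norm = float(np.linalg.norm(best_vec))
    if norm < 1e-6 or zero_field:
        if previous_direction is None:
            raise DegenerateDirectionError(
                "direction search degenerate on the first interval "
                "(no interaction field or zero best vector); reseed or move the ligand")
        d = np.asarray(previous_direction, float)
        return DirectionResult(d / np.linalg.norm(d), best_vec, best_score,
                               best_energy, degenerate=True)
    return DirectionResult(best_vec / norm, best_vec, best_score, best_energy)
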