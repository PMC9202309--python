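"""Observables of pulling ensembles: work, rupture force, correlations,
pathway classification, bootstrap populations and success rate.

The pulling work is the discretised path integral of the spring force over
the pulled-atom displacement, W = sum_i F_i (x_i - x_{i-1}); the rupture
force F_max is the largest spring-force sample.  W averaged over an ensemble
is the non-equilibrium proxy for relative binding affinity that is
correlated against ln(IC50) (IC50 in mol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dynamics import ForceProfile

__all__ = ["WorkResult", "AffinityRecord", "CorrelationResult", "PathwayPopulation",
           "compute_work", "pearson", "classify_pathways", "bootstrap_populations",
           "success_rate", "pathway_percentage", "has_secondary_peak",
           "KCAL_PER_KJ", "ensemble_work_table"]

KCAL_PER_KJ = 1.0 / 4.184


@dataclass(frozen=True)
class WorkResult:
    w_pull: float            # kJ/mol
    f_max: float             # kJ/mol/nm
    trajectory_id: int | str | None = None

    @property
    def w_pull_kcal(self) -> float:
        return self.w_pull * KCAL_PER_KJ


@dataclass(frozen=True)
class AffinityRecord:
    ligand_id: str
    ic50: float              # mol/L

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")

    @property
    def ln_ic50(self) -> float:
        return math.log(self.ic50)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r


@dataclass(frozen=True)
class PathwayPopulation:
    label: str
    count: int
    mean_percent: float
    sd_percent: float


def compute_work(profile: ForceProfile, trajectory_id=None,
                 trapezoid: bool = False) -> WorkResult:
    """Pulling work and rupture force from one force profile.

    Left-Riemann by default: W = sum_{i>=1} F_i (x_i - x_{i-1}) with x_0 the
    first displacement sample; ``trapezoid=True`` averages consecutive force
    samples instead.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    f = profile.forces
    x = profile.displacements
    dx = np.diff(x)
    if trapezoid:
        w = float(np.sum(0.5 * (f[1:] + f[:-1]) * dx))
    else:
        w = float(np.sum(f[1:] * dx))
    return WorkResult(w_pull=w, f_max=float(f.max()), trajectory_id=trajectory_id)


def pearson(work: np.ndarray, ln_ic50: np.ndarray) -> CorrelationResult:
    """Product-moment correlation r between pulling work and ln(IC50)."""
    x = np.asarray(work, float)
    y = np.asarray(ln_ic50, float)
    if x.shape != y.shape:
        raise ValueError("work and ln_ic50 must have equal lengths")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=n)


def _enters_sphere(track: np.ndarray, center: np.ndarray, radius: float,
                   start_index: int = 0) -> int | None:
    d = np.linalg.norm(track[start_index:] - center, axis=1)
    hits = np.nonzero(d <= radius)[0]
    return None if hits.size == 0 else int(hits[0]) + start_index


def classify_pathways(paths, gates=None, site_center: np.ndarray | None = None,
                      site_radius: float = 0.5,
                      angle_threshold_deg: float = 45.0) -> list[str]:
    """Label each path by the first gate sphere its CoM track enters.

    gates: list of (label, center, radius), pairwise disjoint.  The track is
    considered only after it leaves the binding-site sphere (default: a
    sphere of site_radius around each path's starting CoM).  Paths entering
    no gate are labelled "unassigned".

    With gates=None a heuristic fallback is used instead: complete-linkage
    clustering of the exit directions with an angular threshold; clusters
    are labelled "C1", "C2", ... in order of first appearance.
    """
    if gates is None:
        return _cluster_exit_directions(paths, angle_threshold_deg)
    for i, (la, ca, ra) in enumerate(gates):
        for lb, cb, rb in gates[i + 1:]:
            if np.linalg.norm(np.asarray(ca, float) - np.asarray(cb, float)) <= ra + rb:
                raise ValueError(f"gates {la!r} and {lb!r} overlap")
    labels = []
    for path in paths:
        track = np.asarray(path.waypoints, float)
        center = track[0] if site_center is None else np.asarray(site_center, float)
        d_site = np.linalg.norm(track - center, axis=1)
        outside = np.nonzero(d_site > site_radius)[0]
        start = int(outside[0]) if outside.size else len(track)
        best: tuple[int, str] | None = None
        for label, gc, gr in gates:
            hit = _enters_sphere(track, np.asarray(gc, float), gr, start)
            if hit is not None and (best is None or hit < best[0]):
                best = (hit, label)
        labels.append(best[1] if best else "unassigned")
    return labels


def _cluster_exit_directions(paths, angle_threshold_deg: float) -> list[str]:
    dirs = np.array([p.exit_direction() for p in paths])
    if len(dirs) == 1:
        return ["C1"]
    cosines = np.clip(dirs @ dirs.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosines))
    np.fill_diagonal(ang, 0.0)
    z = linkage(squareform(ang, checks=False), method="complete")
    flat = fcluster(z, t=angle_threshold_deg, criterion="distance")
    order: dict[int, str] = {}
    labels = []
    for c in flat:
        if c not in order:
            order[c] = f"C{len(order) + 1}"
        labels.append(order[c])
    return labels


def bootstrap_populations(labels, n_resamples: int = 20000,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> list[PathwayPopulation]:
    """Bootstrap the pathway label list: resample with replacement
    n_resamples times and report the mean and SD of each label's percentage."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    uniq = sorted(set(labels), key=labels.index)  # first-appearance order
    n = len(labels)
    codes = np.array([uniq.index(l) for l in labels])
    draws = rng.integers(0, n, size=(n_resamples, n))
    sampled = codes[draws]
    out = []
    for k, label in enumerate(uniq):
        pct = 100.0 * (sampled == k).mean(axis=1)
        out.append(PathwayPopulation(
            label=label, count=labels.count(label),
            mean_percent=float(pct.mean()), sd_percent=float(pct.std(ddof=0))))
    return out


def success_rate(results) -> float:
    """Percentage of trajectories that ended with the ligand fully outside."""
    results = list(results)
    if not results:
        raise ValueError("results must be non-empty")
    exited = sum(1 for r in results if r.status == "exited")
    return 100.0 * exited / len(results)


def pathway_percentage(counts) -> list[tuple[str, float, int]]:
    """Exact and integer-rounded percentage per (label, count) pair."""
    counts = list(counts)
    total = sum(c for _, c in counts)
    if total <= 0:
        raise ValueError("total count must be > 0")
    if any(c < 0 for _, c in counts):
        raise ValueError("counts must be >= 0")
    return [(label, 100.0 * c / total, round(100.0 * c / total))
            for label, c in counts]


def has_secondary_peak(profile: ForceProfile, drop_frac: float = 0.5,
                       height_frac: float = 0.5) -> bool:
    """Detect a secondary force peak after the first major rupture event.

    The first peak is the maximum force before the force first falls below
    drop_frac of its running maximum; a secondary peak is detected when the
    force later recovers to at least height_frac of the first peak.  A
    profile that ends while the force is still rising counts (the collision
    diagnostic for straight pulling into an obstructed tunnel).
    """
    f = np.asarray(profile.forces, float)
    if len(f) < 3 or f.max() <= 0:
        return False
    running_max = np.maximum.accumulate(f)
    dropped = np.nonzero(f < drop_frac * running_max)[0]
    if dropped.size == 0:
        return False
    i_drop = int(dropped[0])
    first_peak = float(running_max[i_drop])
    after = f[i_drop:]
    return bool(after.max() >= height_frac * first_peak)


def ensemble_work_table(results, ids=None, trapezoid: bool = False) -> pd.DataFrame:
    """Per-trajectory work/rupture table for an ensemble of PathResults.

    Emits a warning column context: the ensemble SD is reported by the
    caller; a RuntimeWarning is raised when SD > 10% of the mean, mirroring
    the trajectory-count rule used to size ensembles.
    """
    import warnings

    rows = []
    for i, res in enumerate(results):
        wid = ids[i] if ids is not None else i
        w = compute_work(res.profile, trajectory_id=wid, trapezoid=trapezoid)
        rows.append({"trajectory": wid, "status": res.status,
                     "w_pull_kJ": w.w_pull, "w_pull_kcal": w.w_pull_kcal,
                     "f_max": w.f_max, "intervals": res.intervals_used})
    df = pd.DataFrame(rows)
    mean, sd = df["w_pull_kJ"].mean(), df["w_pull_kJ"].std(ddof=1)
    if len(df) > 1 and mean != 0 and sd > 0.1 * abs(mean):
        warnings.warn(
            f"work SD ({sd:.3g}) exceeds 10% of the mean ({mean:.3g}); "
            "consider more trajectories", RuntimeWarning, stacklevel=2)
    return df


def spearman(x, y) -> float:
    """Spearman rank correlation (thin wrapper, kept here for discoverability)."""
    rho, _ = _stats.spearmanr(x, y)
    return float(rho)
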