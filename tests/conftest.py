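import numpy as np
import pytest

import depull as dp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_de():
    """Desk-scale DE settings used for fixture protocol runs."""
    return dp.DEConfig(population_size=48, iterations=30)


@pytest.fixture(scope="session")
def desk_engine():
    return dp.EngineConfig(timestep=0.01, temperature=0.0)


def make_free_ligand_system(n_lig: int = 1):
    """Ligand with the receptor parked far beyond any interaction range."""
    receptor = [dp.AtomRecord(1, "FAR", np.array([100.0, 100.0, 100.0]),
                              0.0, 0.2, 0.3, "receptor")]
    ligand = [dp.AtomRecord(10 + i, f"L{i+1}",
                            np.array([0.05 * i, 0.0, 0.0]), 0.0, 0.3, 1.0, "ligand")
              for i in range(n_lig)]
    system = dp.MolecularSystem(receptor, ligand)
    system.pulled_atom_id = ligand[0].atom_id
    return system


def random_system(rng, n_lig=10, n_rec=50, box=3.0, charged=True):
    """Random atoms in a box, for brute-force energy comparisons."""
    ligand = []
    for i in range(n_lig):
        ligand.append(dp.AtomRecord(
            1000 + i, f"L{i}", rng.uniform(0, box, 3),
            rng.uniform(-0.5, 0.5) if charged else 0.0,
            rng.uniform(0.15, 0.35), rng.uniform(0.1, 1.5), "ligand"))
    receptor = []
    for j in range(n_rec):
        receptor.append(dp.AtomRecord(
            j + 1, f"R{j}", rng.uniform(0, box, 3),
            rng.uniform(-0.5, 0.5) if charged else 0.0,
            rng.uniform(0.15, 0.35), rng.uniform(0.1, 1.5), "receptor"))
    return dp.MolecularSystem(receptor, ligand)


def brute_force_nonbonded(system, config=dp.EnergyConfig()):
    """Independent double-loop oracle over all ligand-receptor pairs."""
    e_elec = e_vdw = 0.0
    for la in system.ligand:
        for ra in system.receptor:
            r = float(np.linalg.norm(la.position - ra.position))
            if r > config.cutoff:
                continue
            r_eff = max(r, config.min_distance_clamp)
            e_elec += (config.coulomb_constant * la.charge * ra.charge
                       / (config.dielectric * r_eff))
            sigma = 0.5 * (la.sigma + ra.sigma)
            eps = np.sqrt(la.epsilon * ra.epsilon)
            a6 = (sigma / r_eff) ** 6
            e_vdw += 4.0 * eps * (a6 * a6 - a6)
    return e_elec, e_vdw
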