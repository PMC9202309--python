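"""Score function, ball sampling and the DE optimizer against analytic minima."""

import numpy as np
import pytest

import depull as dp
from depull.desearch import _sample_ball


class TestEScore:
    def test_identity_when_unchanged_and_alpha_zero(self):
        e = dp.EnergyPair(-50.0, -30.0)
        assert dp.e_score(e, e, dp.ScoreConfig(alpha=0.0)) == 0.0

    def test_forced_arithmetic(self):
        cur, prev = dp.EnergyPair(-50, -30), dp.EnergyPair(-60, -40)
        assert dp.e_score(cur, prev, dp.ScoreConfig(alpha=2.0)) == \
            pytest.approx(20 + 2 * 80)

    def test_zero_current_any_alpha(self):
        cur, prev = dp.EnergyPair(0, 0), dp.EnergyPair(-10, -5)
        for alpha in (0.0, 1.0, 2.0, 7.5):
            assert dp.e_score(cur, prev, dp.ScoreConfig(alpha=alpha)) == \
                pytest.approx(15.0)

    def test_alpha_zero_reduces_to_energy_difference(self, rng):
        for _ in range(20):
            cur = dp.EnergyPair(*rng.uniform(-100, 100, 2))
            prev = dp.EnergyPair(*rng.uniform(-100, 100, 2))
            assert dp.e_score(cur, prev, dp.ScoreConfig(alpha=0.0)) == \
                pytest.approx(cur.total - prev.total)

    def test_current_equals_previous_gives_alpha_term(self, rng):
        cur = dp.EnergyPair(-12.5, 3.5)
        assert dp.e_score(cur, cur, dp.ScoreConfig(alpha=2.0)) == \
            pytest.approx(2.0 * abs(cur.total))


class TestSamplePopulation:
    def test_all_vectors_within_ball(self, rng):
        cfg = dp.DEConfig(population_size=500)
        pop = dp.sample_population(cfg, rng)
        assert len(pop) == 500
        assert all(np.linalg.norm(c.vector) <= 0.7 + 1e-12 for c in pop)

    def test_mean_norm_is_three_quarters_radius(self):
        # E||v|| = 3R/4 for the uniform ball; Monte-Carlo check at 1e5 samples
        rng = np.random.default_rng(2024)
        v = _sample_ball(100_000, 0.7, rng)
        norms = np.linalg.norm(v, axis=1)
        expected = 0.75 * 0.7
        sem = norms.std() / np.sqrt(len(norms))
        assert abs(norms.mean() - expected) < 3 * sem

    def test_same_seed_reproduces_population(self):
        cfg = dp.DEConfig(population_size=64, seed=9)
        a = dp.sample_population(cfg, np.random.default_rng(9))
        b = dp.sample_population(cfg, np.random.default_rng(9))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.vector, cb.vector)


class TestDEMinimize:
    CFG = dp.DEConfig(population_size=50, iterations=100)

    def test_interior_quadratic_recovered_over_seeds(self):
        target = np.array([0.2, -0.1, 0.3])
        for seed in range(10):
            v, val = dp.de_minimize(
                lambda vs: ((vs - target) ** 2).sum(axis=1),
                self.CFG, np.random.default_rng(seed), vectorized=True)
            assert np.linalg.norm(v - target) < 1e-3

    def test_boundary_quadratic_projects_onto_ball(self):
        w = np.array([0.9, 0.6, -0.3])
        proj = w / np.linalg.norm(w) * 0.7
        for seed in range(10):
            v, _ = dp.de_minimize(
                lambda vs: ((vs - w) ** 2).sum(axis=1),
                self.CFG, np.random.default_rng(seed), vectorized=True)
            assert np.linalg.norm(v - proj) < 1e-3

    def test_constant_objective_feasible_result(self, rng):
        v, val = dp.de_minimize(lambda vs: np.full(len(vs), 4.25),
                                self.CFG, rng, vectorized=True)
        assert val == 4.25
        assert np.linalg.norm(v) <= 0.7 + 1e-12

    def test_scalar_objective_interface(self, rng):
        v, _ = dp.de_minimize(lambda x: float((x ** 2).sum()),
                              dp.DEConfig(population_size=30, iterations=60), rng)
        assert np.linalg.norm(v) < 1e-3

    def test_non_finite_objective_never_selected(self, rng):
        def objective(vs):
            out = (vs ** 2).sum(axis=1)
            out[vs[:, 0] > 0] = np.nan
            return out
        v, val = dp.de_minimize(objective, self.CFG, rng, vectorized=True)
        assert np.isfinite(val)
        assert v[0] <= 0

    def test_best_score_monotone_over_generations(self, rng):
        # re-run with increasing iteration counts; the final best never worsens
        target = np.array([0.1, 0.2, -0.2])

        def obj(vs):
            return ((vs - target) ** 2).sum(axis=1)

        values = []
        for iters in (1, 5, 20, 60):
            _, val = dp.de_minimize(obj, dp.DEConfig(population_size=40,
                                                     iterations=iters),
                                    np.random.default_rng(5), vectorized=True)
            values.append(val)
        assert all(b <= a + 1e-15 for a, b in zip(values, values[1:]))

    def test_population_size_validation(self):
        with pytest.raises(ValueError):
            dp.DEConfig(population_size=3)


class TestFindDirection:
    def _one_atom_system(self, rec_pos, rec_sigma=0.6, rec_eps=50.0):
        rec = [dp.AtomRecord(1, "R", np.asarray(rec_pos, float), 0.0,
                             rec_sigma, rec_eps, "receptor")]
        lig = [dp.AtomRecord(2, "L", np.zeros(3), 0.0, 0.3, 1.0, "ligand")]
        system = dp.MolecularSystem(rec, lig)
        system.pulled_atom_id = 2
        return system

    def _grid_oracle(self, system, prev, alpha=2.0, radius=0.7, n=40,
                     energy_cfg=None):
        """Exhaustive scoring on a dense ball grid; returns best direction."""
        ax = np.linspace(-radius, radius, n)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        ws = dp.NonbondedWorkspace(system, energy_cfg or dp.EnergyConfig())
        lig0 = system.ligand_positions()
        e1, e2 = ws.energies_batch(lig0[None] + pts[:, None, :])
        cur = e1 + e2
        scores = cur - prev.total + alpha * np.abs(cur)
        best = pts[np.argmin(scores)]
        return best / np.linalg.norm(best)

    def test_repulsive_atom_pushes_away(self):
        # sigma so large that r_min lies beyond the probe reach: the atom is
        # purely repulsive everywhere the search can go, so the unique optimum
        # is the antipodal pose
        system = self._one_atom_system([0.4, 0.0, 0.0], rec_sigma=2.0)
        ecfg = dp.EnergyConfig(cutoff=1.3)
        ws = dp.NonbondedWorkspace(system, ecfg)
        prev = ws.energies(system.ligand_positions())
        oracle = self._grid_oracle(system, prev, energy_cfg=ecfg)
        away = np.array([-1.0, 0.0, 0.0])
        cfg = dp.DEConfig(population_size=60, iterations=50)
        for seed in range(5):
            r = dp.find_direction(system, prev, cfg, dp.ScoreConfig(),
                                  ecfg, np.random.default_rng(seed))
            assert float(r.direction @ away) >= 0.9
        assert float(oracle @ away) >= 0.9

    def test_zero_field_degenerate_flag(self):
        system = self._one_atom_system([50.0, 0.0, 0.0])
        prev = dp.EnergyPair(0.0, 0.0)
        cfg = dp.DEConfig(population_size=30, iterations=10)
        r = dp.find_direction(system, prev, cfg, dp.ScoreConfig(),
                              dp.EnergyConfig(), np.random.default_rng(0),
                              previous_direction=np.array([0, 0, 1.0]))
        assert r.degenerate
        np.testing.assert_allclose(r.direction, [0, 0, 1.0])
        assert r.best_score == 0.0

    def test_zero_field_first_interval_raises(self):
        system = self._one_atom_system([50.0, 0.0, 0.0])
        with pytest.raises(dp.DegenerateDirectionError):
            dp.find_direction(system, dp.EnergyPair(0, 0),
                              dp.DEConfig(population_size=30, iterations=10),
                              dp.ScoreConfig(), dp.EnergyConfig(),
                              np.random.default_rng(0))

    def test_alpha_zero_dives_into_attractive_well(self):
        # deep attractive atom displaced +x; with alpha = 0 the score is the
        # plain energy difference, so the best translation points into the well
        system = self._one_atom_system([0.55, 0.0, 0.0], rec_sigma=0.25,
                                       rec_eps=30.0)
        ws = dp.NonbondedWorkspace(system, dp.EnergyConfig())
        prev = ws.energies(system.ligand_positions())
        cfg = dp.DEConfig(population_size=60, iterations=50)
        r = dp.find_direction(system, prev, cfg, dp.ScoreConfig(alpha=0.0),
                              dp.EnergyConfig(), np.random.default_rng(3))
        oracle = self._grid_oracle(system, prev, alpha=0.0)
        # minimizers tie on the ring of LJ minima around the well atom, a cone
        # of half-angle asin(r_min/0.55) about +x: dot bounded below by ~0.86
        assert float(r.direction @ np.array([1.0, 0, 0])) > 0.8
        assert float(oracle @ np.array([1.0, 0, 0])) > 0.8

    def test_bitwise_reproducible_given_seed(self):
        system = self._one_atom_system([0.4, 0.1, -0.2])
        ws = dp.NonbondedWorkspace(system, dp.EnergyConfig())
        prev = ws.energies(system.ligand_positions())
        cfg = dp.DEConfig(population_size=40, iterations=20)
        a = dp.find_direction(system, prev, cfg, dp.ScoreConfig(),
                              dp.EnergyConfig(), np.random.default_rng(11))
        b = dp.find_direction(system, prev, cfg, dp.ScoreConfig(),
                              dp.EnergyConfig(), np.random.default_rng(11))
        np.testing.assert_array_equal(a.direction, b.direction)
        assert a.best_score == b.best_score

    def test_cage_with_hole_mean_direction_toward_hole(self, desk_de):
        # spherically symmetric cage with one axial hole: over many seeds the
        # chosen directions concentrate toward the hole
        spec = dp.standard_fixtures()["STRAIGHT"]
        system, _ = dp.make_system(spec)
        system.pulled_atom_id = dp.select_pulled_atom(system)
        ws = dp.NonbondedWorkspace(system, dp.EnergyConfig())
        prev = ws.energies(system.ligand_positions())
        dots = []
        for seed in range(20):
            r = dp.find_direction(system, prev, desk_de, dp.ScoreConfig(),
                                  dp.EnergyConfig(), np.random.default_rng(seed))
            dots.append(float(r.direction[2]))
        assert np.mean(dots) > 0.5
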