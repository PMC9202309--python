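"""Work/rupture analysis, correlations, pathway classification, bootstrap."""

import numpy as np
import pytest

import depull as dp
from depull.dynamics import ForceProfile


def _profile(times, disps, forces):
    return ForceProfile(np.asarray(times, float), np.asarray(forces, float),
                        np.asarray(disps, float))


class TestComputeWork:
    def test_constant_force_over_one_nm(self):
        x = np.linspace(0, 1, 11)
        prof = _profile(np.arange(11) + 1.0, x, np.full(11, 100.0))
        w = dp.compute_work(prof)
        assert w.w_pull == pytest.approx(100.0)
        assert w.f_max == 100.0

    def test_zero_force(self):
        prof = _profile([1, 2, 3], [0, 0.5, 1.0], [0, 0, 0])
        w = dp.compute_work(prof)
        assert w.w_pull == 0.0 and w.f_max == 0.0

    def test_linear_ramp_matches_half_c_d_squared(self):
        c, d, n = 50.0, 2.0, 10_000
        x = np.linspace(0, d, n)
        prof = _profile(np.arange(n) + 1.0, x, c * x)
        w = dp.compute_work(prof)
        assert w.w_pull == pytest.approx(0.5 * c * d * d, rel=1e-3)

    def test_additive_over_concatenation(self, rng):
        n = 200
        x = np.cumsum(rng.uniform(0, 0.01, n))
        f = rng.uniform(-50, 150, n)
        t = np.arange(n) + 1.0
        whole = dp.compute_work(_profile(t, x, f)).w_pull
        a = dp.compute_work(_profile(t[:120], x[:120], f[:120])).w_pull
        # second segment must start from the last displacement of the first
        b_prof = _profile(t[119:], x[119:], f[119:])
        b = dp.compute_work(b_prof).w_pull
        assert whole == pytest.approx(a + b, abs=1e-9)

    def test_kcal_conversion(self):
        prof = _profile([1, 2], [0, 1.0], [4.184, 4.184])
        assert dp.compute_work(prof).w_pull_kcal == pytest.approx(1.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            dp.compute_work(_profile([], [], []))


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(1.0, 11.0)
        res = dp.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(1.0, 8.0)
        res = dp.pearson(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.5, 3.0, 4.7, 5.1, 6.0])
        y = np.array([2.1, 1.9, 3.5, 4.0, 5.2, 4.9])
        xm, ym = x.mean(), y.mean()
        r_direct = (((x - xm) * (y - ym)).sum()
                    / np.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()))
        assert dp.pearson(x, y).r == pytest.approx(r_direct, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = dp.pearson(x, y).r
        assert dp.pearson(3 * x + 7, y).r == pytest.approx(r0, abs=1e-12)
        assert dp.pearson(-2 * x, y).r == pytest.approx(-r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dp.pearson(np.ones(5), np.arange(5.0))

    def test_affinity_record_ln(self):
        rec = dp.AffinityRecord("lig1", 1e-6)
        assert rec.ln_ic50 == pytest.approx(np.log(1e-6))
        with pytest.raises(ValueError):
            dp.AffinityRecord("bad", 0.0)


class _FakePath:
    def __init__(self, waypoints, status="exited"):
        self.waypoints = np.asarray(waypoints, float)
        self.status = status

    def exit_direction(self):
        v = self.waypoints[-1] - self.waypoints[0]
        return v / np.linalg.norm(v)


class TestClassifyPathways:
    GATES = [("A", np.array([0, 0, 2.0]), 0.5), ("B", np.array([2.0, 0, 0]), 0.5)]

    def test_path_through_single_gate(self):
        p = _FakePath([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        assert dp.classify_pathways([p], gates=self.GATES) == ["A"]

    def test_path_missing_all_gates_unassigned(self):
        p = _FakePath([[0, 0, 0], [0, -2, 0]])
        assert dp.classify_pathways([p], gates=self.GATES) == ["unassigned"]

    def test_gate_entry_only_counts_after_leaving_site(self):
        # a gate sphere overlapping the start is ignored until the track has
        # left the binding-site sphere
        gates = [("near", np.array([0.2, 0, 0]), 0.3),
                 ("far", np.array([0, 0, 2.0]), 0.5)]
        p = _FakePath([[0, 0, 0], [0, 0, 0.2], [0, 0, 1.0], [0, 0, 2.0]])
        assert dp.classify_pathways([p], gates=gates, site_radius=0.5) == ["far"]

    def test_overlapping_gates_rejected(self):
        bad = [("A", np.array([0, 0, 0]), 1.0), ("B", np.array([0.5, 0, 0]), 1.0)]
        with pytest.raises(ValueError, match="overlap"):
            dp.classify_pathways([], gates=bad)

    def test_angular_clustering_fallback(self):
        ups = [_FakePath([[0, 0, 0], [0.05 * i, 0, 2.0]]) for i in range(3)]
        sides = [_FakePath([[0, 0, 0], [2.0, 0, 0.05 * i]]) for i in range(2)]
        labels = dp.classify_pathways(ups + sides, gates=None,
                                      angle_threshold_deg=45.0)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4]
        assert labels[0] != labels[3]


class TestBootstrap:
    def test_single_label_degenerate(self):
        pops = dp.bootstrap_populations(["only"] * 12, n_resamples=2000, seed=0)
        assert len(pops) == 1
        assert pops[0].mean_percent == pytest.approx(100.0)
        assert pops[0].sd_percent == 0.0

    def test_counts_match_binomial_theory(self):
        counts = {"PW1": 11, "PW2": 31, "PW3": 9, "PW4": 2, "PW5": 7}
        labels = [l for l, c in counts.items() for _ in range(c)]
        pops = dp.bootstrap_populations(labels, n_resamples=20_000, seed=1)
        n = len(labels)
        by_label = {p.label: p for p in pops}
        for label, c in counts.items():
            p_hat = 100.0 * c / n
            sd_theory = 100.0 * np.sqrt((c / n) * (1 - c / n) / n)
            assert abs(by_label[label].mean_percent - p_hat) < 0.5
            assert abs(by_label[label].sd_percent - sd_theory) < 0.15 * sd_theory
        assert sum(p.mean_percent for p in pops) == pytest.approx(100.0, abs=0.5)
        assert sum(p.count for p in pops) == n

    def test_two_labels_even_split(self):
        pops = dp.bootstrap_populations(["a", "b"], n_resamples=20_000, seed=2)
        for p in pops:
            assert abs(p.mean_percent - 50.0) < 1.5

    def test_means_converge_with_more_resamples(self):
        labels = ["x"] * 3 + ["y"] * 7
        small = dp.bootstrap_populations(labels, n_resamples=20_000, seed=3)
        large = dp.bootstrap_populations(labels, n_resamples=200_000, seed=3)
        for s, l in zip(small, large):
            assert abs(s.mean_percent - l.mean_percent) < 0.3


class TestRatesAndPercentages:
    def test_success_rate_variants(self):
        mk = lambda s: _FakePath([[0, 0, 0], [0, 0, 1]], status=s)
        assert dp.success_rate([mk("exited")] * 20) == 100.0
        assert dp.success_rate([mk("stuck")] * 5) == 0.0
        mixed = [mk("exited")] * 3 + [mk("stuck"), mk("max_intervals")]
        assert dp.success_rate(mixed) == pytest.approx(60.0)

    def test_pathway_percentage_rounding(self):
        out = dp.pathway_percentage([("PW4", 2), ("rest", 58)])
        label, exact, rounded = out[0]
        assert exact == pytest.approx(100 * 2 / 60)
        assert rounded == 3

    def test_single_label_is_hundred(self):
        assert dp.pathway_percentage([("only", 5)])[0][1] == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            dp.pathway_percentage([("a", 0)])


class TestSecondaryPeak:
    def test_clean_single_peak_not_flagged(self):
        t = np.linspace(0, 10, 200)
        f = 100 * np.exp(-((t - 3) ** 2))
        prof = _profile(t + 1, np.linspace(0, 1, 200), f)
        assert not dp.has_secondary_peak(prof)

    def test_double_peak_flagged(self):
        t = np.linspace(0, 10, 400)
        f = 100 * np.exp(-((t - 3) ** 2)) + 70 * np.exp(-((t - 7) ** 2) / 0.5)
        prof = _profile(t + 1, np.linspace(0, 1, 400), f)
        assert dp.has_secondary_peak(prof)

    def test_terminal_rise_counts_as_secondary(self):
        t = np.linspace(0, 10, 300)
        f = np.where(t < 3, 100 * t / 3, np.maximum(0, 100 - 60 * (t - 3)))
        f = f + np.where(t > 7, 40 * (t - 7), 0.0)
        prof = _profile(t + 1, np.linspace(0, 1, 300), f)
        assert dp.has_secondary_peak(prof)
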