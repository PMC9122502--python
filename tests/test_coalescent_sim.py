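"""Coalescent simulator: closed forms, msprime oracle, batch-kernel agreement."""

import numpy as np
import pytest
from scipy import stats as sps

from sdmal.coalescent_sim import (
    CoalescentTree,
    DemographicModel,
    SimConfig,
    batch_summaries,
    place_mutations_fixed_S,
    simulate_genealogy,
    summarise_replicates,
)
from sdmal.errors import ConfigError
from sdmal.popgen_windows import matrix_pi_sum, tajima_Dmin, tajimas_D


def _mean_se(x):
    x = np.asarray(x)
    return x.mean(), x.std(ddof=1) / np.sqrt(len(x))


class TestGenealogy:
    def test_pair_tmrca_closed_form(self, rng):
        # E[TMRCA] for n=2 is 0.5 in 4*Ne units
        tm = [simulate_genealogy(2, DemographicModel(), rng).root_time for _ in range(20_000)]
        mean, se = _mean_se(tm)
        assert abs(mean - 0.5) < 3 * se

    def test_sweep_forces_root_at_or_before_t(self, rng):
        for _ in range(50):
            tree = simulate_genealogy(6, DemographicModel.sweep(0.001), rng)
            assert tree.root_time <= 0.001 + 1e-15

    def test_growth_alpha_zero_identical_to_constant(self):
        t1 = simulate_genealogy(7, DemographicModel.growth(0.0), np.random.default_rng(3))
        t2 = simulate_genealogy(7, DemographicModel(), np.random.default_rng(3))
        np.testing.assert_array_equal(t1.parent, t2.parent)
        np.testing.assert_allclose(t1.times, t2.times)

    def test_ancient_sweep_identical_to_constant(self):
        # a sweep far older than the TMRCA never triggers the forced merge
        t1 = simulate_genealogy(9, DemographicModel.sweep(10.0), np.random.default_rng(8))
        t2 = simulate_genealogy(9, DemographicModel(), np.random.default_rng(8))
        np.testing.assert_array_equal(t1.parent, t2.parent)
        np.testing.assert_allclose(t1.times, t2.times)

    def test_times_nondecreasing_and_lengths_nonnegative(self, rng):
        tree = simulate_genealogy(9, DemographicModel(), rng)
        internal = tree.times[tree.n :]
        assert np.all(np.diff(internal) >= 0)
        assert np.all(tree.branch_lengths() >= 0)


class TestMsprimeOracle:
    """Cross-checks against msprime at matching parameters.

    population_size = 0.5 makes msprime's time unit equal 4*N_e
    generations (haploid pair-coalescence rate 1/N = 2 = k*(k-1) at k=2).
    """

    def test_constant_tree_height_and_length(self, rng):
        import msprime

        reps = 400
        ours_h, ours_l = [], []
        for _ in range(reps):
            t = simulate_genealogy(9, DemographicModel(), rng)
            ours_h.append(t.root_time)
            ours_l.append(t.total_polymorphic_length())
        ts_h, ts_l = [], []
        for ts in msprime.sim_ancestry(
            samples=9, ploidy=1, population_size=0.5, num_replicates=reps, random_seed=99
        ):
            tree = ts.first()
            ts_h.append(tree.time(tree.root))
            ts_l.append(tree.total_branch_length)
        for a, b in [(ours_h, ts_h), (ours_l, ts_l)]:
            ma, sa = _mean_se(a)
            mb, sb = _mean_se(b)
            assert abs(ma - mb) < 3 * np.hypot(sa, sb)

    def test_growth_tree_height(self, rng):
        import msprime

        alpha, reps = 0.26, 400
        ours = [
            simulate_genealogy(9, DemographicModel.growth(alpha), rng).root_time
            for _ in range(reps)
        ]
        demog = msprime.Demography.isolated_model([0.5], growth_rate=[alpha])
        theirs = [
            ts.first().time(ts.first().root)
            for ts in msprime.sim_ancestry(
                samples=9, ploidy=1, demography=demog, num_replicates=reps, random_seed=7
            )
        ]
        ma, sa = _mean_se(ours)
        mb, sb = _mean_se(theirs)
        assert abs(ma - mb) < 3 * np.hypot(sa, sb)

    def test_neutral_mean_D_matches_oracle(self, rng):
        # fixed-S Tajima's D against msprime trees carrying the same
        # conditioned mutation count, placed by branch-length multinomial
        import msprime

        S, reps = 60, 500
        ours = summarise_replicates(SimConfig(n=9, S=S, region_length=10_000), reps, rng)
        oracle_d = []
        mut_rng = np.random.default_rng(123)
        for ts in msprime.sim_ancestry(
            samples=9, ploidy=1, population_size=0.5, num_replicates=reps, random_seed=17
        ):
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lens = np.array([tree.branch_length(u) for u in nodes])
            sizes = np.array([tree.num_samples(u) for u in nodes])
            ok = sizes < 9
            counts = mut_rng.multinomial(S, lens[ok] / lens[ok].sum())
            pi = float(np.sum(counts * 2.0 * sizes[ok] * (9 - sizes[ok]) / 72.0))
            oracle_d.append(tajimas_D(S, pi, 9))
        ma, sa = _mean_se(ours.D)
        mb, sb = _mean_se(oracle_d)
        assert abs(ma - mb) < 3 * np.hypot(sa, sb)


class TestMutations:
    def test_zero_S_monomorphic(self, rng):
        tree = simulate_genealogy(5, DemographicModel(), rng)
        m = place_mutations_fixed_S(tree, 0, 1000, rng)
        assert m.n_sites == 0

    def test_star_genealogy_all_singletons(self, rng):
        tree = simulate_genealogy(9, DemographicModel.sweep(1e-7), rng)
        m = place_mutations_fixed_S(tree, 50, 100_000, rng)
        assert np.all(m.minor_counts() == 1)
        S = int(m.is_segregating().sum())
        assert S == 50
        D = tajimas_D(S, matrix_pi_sum(m), 9)
        assert D == pytest.approx(tajima_Dmin(S, 9))

    def test_exactly_S_segregating_sites(self, rng):
        for _ in range(20):
            tree = simulate_genealogy(9, DemographicModel(), rng)
            m = place_mutations_fixed_S(tree, 37, 10_000, rng)
            assert int(m.is_segregating().sum()) == 37
            assert np.all(np.diff(m.positions) > 0)

    def test_multinomial_placement_chisquare(self, rng):
        tree = simulate_genealogy(6, DemographicModel(), rng)
        S = 10_000
        m = place_mutations_fixed_S(tree, S, 50_000, rng)
        # per-branch mutation fractions vs branch-length fractions
        lens = tree.branch_lengths()
        sizes = tree.tip_counts()
        ok = (sizes >= 1) & (sizes <= 5)
        tipsets = tree.descendant_tips()
        observed = []
        for node in np.flatnonzero(ok):
            pattern = np.zeros(6, dtype=np.int8)
            pattern[tipsets[node]] = 1
            observed.append(int(np.sum((m.alleles == pattern[:, None]).all(axis=0))))
        # each branch has a unique tip pattern in a binary genealogy
        expected = S * lens[ok] / lens[ok].sum()
        obs = np.asarray(observed, dtype=float)
        _, p = sps.chisquare(obs, expected * obs.sum() / expected.sum())
        assert p > 0.01


class TestBatchKernel:
    def test_agrees_with_per_tree_path(self, rng):
        for model in (DemographicModel(), DemographicModel.sweep(0.08)):
            cfg = SimConfig(n=9, S=500, model=model, region_length=10_000)
            per_tree = summarise_replicates(cfg, 1500, rng)
            pi_b, d_b = batch_summaries(9, model, 500, 1500, rng)
            for a, b in [(per_tree.pi_sum, pi_b), (per_tree.D, d_b)]:
                ma, sa = _mean_se(a)
                mb, sb = _mean_se(b)
                assert abs(ma - mb) < 3 * np.hypot(sa, sb)

    def test_monotone_in_sweep_time(self):
        # common random numbers across the t grid
        grid = [0.001, 0.01, 0.05, 0.2, 1.0]
        mean_pi, mean_d = [], []
        for t in grid:
            pi, d = batch_summaries(
                9, DemographicModel.sweep(t), 300, 3000, np.random.default_rng(55)
            )
            mean_pi.append(pi.mean())
            mean_d.append(d.mean())
        assert all(a <= b for a, b in zip(mean_pi, mean_pi[1:]))
        assert all(a <= b for a, b in zip(mean_d, mean_d[1:]))

    def test_star_limit(self):
        pi, d = batch_summaries(
            9, DemographicModel.sweep(1e-9), 200, 500, np.random.default_rng(2)
        )
        assert np.allclose(pi, 2.0 * 200 / 9)
        assert np.allclose(d, tajima_Dmin(200, 9))


class TestDeterminismAndSymmetry:
    def test_seeded_determinism(self):
        cfg = SimConfig(n=9, S=80, model=DemographicModel.sweep(0.05), seed=77)
        rng1, rng2 = np.random.default_rng(77), np.random.default_rng(77)
        t1 = simulate_genealogy(9, cfg.model, rng1)
        t2 = simulate_genealogy(9, cfg.model, rng2)
        m1 = place_mutations_fixed_S(t1, 80, 9_920_000, rng1)
        m2 = place_mutations_fixed_S(t2, 80, 9_920_000, rng2)
        np.testing.assert_array_equal(m1.alleles, m2.alleles)
        np.testing.assert_array_equal(m1.positions, m2.positions)

    def test_tip_permutation_leaves_summaries_unchanged(self, rng):
        tree = simulate_genealogy(9, DemographicModel(), rng)
        m = place_mutations_fixed_S(tree, 120, 10_000, rng)
        perm = rng.permutation(9)
        permuted = m.alleles[perm]
        assert matrix_pi_sum(m) == pytest.approx(
            matrix_pi_sum(
                type(m)(
                    chrom=m.chrom,
                    positions=m.positions,
                    samples=m.samples,
                    alleles=permuted,
                )
            )
        )

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(n=1, S=10)
        with pytest.raises(ConfigError):
            SimConfig(n=9, S=100, region_length=50)
        with pytest.raises(ConfigError):
            DemographicModel(kind="sweep")
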