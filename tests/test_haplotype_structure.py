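"""Pairwise r^2, the Hudson-Kaplan Rm bound, and shared/private SNP runs."""

import itertools

import numpy as np
import pytest

from sdmal.coalescent_sim import DemographicModel, SimConfig
from sdmal.errors import ConfigError, DataError
from sdmal.hapio import filter_sites
from sdmal.haplotype_structure import (
    RunRecord,
    events_per_generation,
    label_shared_private,
    mean_r2_by_distance,
    min_recombination_events,
    pairwise_r2,
    run_summary,
    snp_runs,
)
from sdmal.synthetic_data import align_union, gen_panel, inject_conversion_tracts

from conftest import make_matrix


class TestPairwiseR2:
    def test_duplicated_site_full_ld(self):
        col = [0, 0, 1, 1, 0, 1]
        m = make_matrix(np.array([col, col]).T)
        pairs = pairwise_r2(m)
        assert pairs[0].r_squared == pytest.approx(1.0)

    def test_independent_counts_zero_ld(self):
        # haplotype counts exactly proportional to allele-frequency products
        a = [1, 1, 0, 0, 1, 1, 0, 0]
        b = [1, 0, 1, 0, 1, 0, 1, 0]
        m = make_matrix(np.array([a, b]).T)
        assert pairwise_r2(m)[0].r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self, rng):
        alleles = rng.integers(0, 2, size=(9, 20)).astype(np.int8)
        m = filter_sites(make_matrix(alleles), biallelic=True, drop_singletons=True)
        pairs = {(p.pos_i, p.pos_j): p.r_squared for p in pairwise_r2(m)}
        for i, j in itertools.combinations(range(m.n_sites), 2):
            x, y = m.alleles[:, i], m.alleles[:, j]
            pa, pb = x.mean(), y.mean()
            pab = np.mean((x == 1) & (y == 1))
            D = pab - pa * pb
            expected = D * D / (pa * (1 - pa) * pb * (1 - pb))
            key = (int(m.positions[i]), int(m.positions[j]))
            assert pairs[key] == pytest.approx(expected)

    def test_breakpoint_straddling_pairs_dropped(self):
        alleles = np.array([[0, 0, 1, 1, 0], [0, 1, 0, 1, 1], [1, 0, 0, 1, 0]]).T
        m = make_matrix(alleles, positions=[100, 500, 900])
        pairs = pairwise_r2(m, exclusions=[(300, 300)])
        kept = {(p.pos_i, p.pos_j) for p in pairs}
        assert kept == {(500, 900)}

    def test_missing_calls_rejected(self):
        m = make_matrix([[0, -1], [1, 1], [0, 1], [1, 0]])
        with pytest.raises(ConfigError):
            pairwise_r2(m)


class TestR2Binning:
    def test_single_distance_single_bin(self):
        alleles = np.array([[0, 0, 1, 1], [0, 1, 0, 1]]).T
        m = make_matrix(alleles, positions=[1_000, 4_000])
        df = mean_r2_by_distance(pairwise_r2(m), bin_width=10_000)
        assert len(df) == 1
        assert df.loc[0, "n_pairs"] == 1

    def test_bin_means_match_recount(self, rng):
        cfg = SimConfig(n=9, S=60, region_length=100_000)
        (panel,) = gen_panel(cfg, rng=rng)
        m = filter_sites(panel, biallelic=True, drop_singletons=True)
        pairs = pairwise_r2(m)
        df = mean_r2_by_distance(pairs, bin_width=10_000)
        for _, row in df.iterrows():
            sel = [
                p.r_squared
                for p in pairs
                if row.bin_start <= p.distance < row.bin_end
            ]
            assert row.n_pairs == len(sel)
            if sel:
                assert row.mean_r2 == pytest.approx(np.mean(sel))

    def test_small_sample_inflation(self):
        # dropping one haplotype from the same panel inflates mean r^2
        rng = np.random.default_rng(77)
        diffs = []
        for _ in range(100):
            cfg = SimConfig(n=10, S=40, region_length=50_000)
            (panel,) = gen_panel(cfg, rng=rng)
            small = make_matrix(panel.alleles[:9], positions=panel.positions)
            out = []
            for m in (small, panel):
                try:
                    mf = filter_sites(m, biallelic=True, drop_singletons=True)
                    out.append(np.mean([p.r_squared for p in pairwise_r2(mf)]))
                except (ConfigError, DataError):
                    out.append(None)
            if None not in out:
                diffs.append(out[0] - out[1])
        assert np.mean(diffs) > 0


def rm_exhaustive_oracle(incompatible):
    """Max number of pairwise-disjoint open intervals, brute force.

    Dropping an interval that strictly contains another never lowers the
    optimum, so the search space is first reduced to minimal intervals
    (at most S-1 of them) and then enumerated exhaustively.
    """
    minimal = [
        (a, b)
        for a, b in incompatible
        if not any((c, d) != (a, b) and a <= c and d <= b for c, d in incompatible)
    ]
    best = 0
    for r in range(1, len(minimal) + 1):
        for subset in itertools.combinations(minimal, r):
            ok = all(
                b1 <= a2 or b2 <= a1
                for (a1, b1), (a2, b2) in itertools.combinations(subset, 2)
            )
            if ok:
                best = max(best, r)
    return best


class TestRm:
    def test_tree_compatible_panels_have_zero_rm(self, rng):
        # no recombination in the simulator, so every panel passes the
        # four-gamete test everywhere
        for _ in range(20):
            cfg = SimConfig(n=9, S=40, region_length=100_000)
            (panel,) = gen_panel(cfg, rng=rng)
            m = filter_sites(panel, biallelic=True, drop_singletons=True)
            assert min_recombination_events(m) == 0

    def test_matches_exhaustive_oracle_on_small_matrices(self, rng):
        from sdmal.haplotype_structure import _incompatible_pairs

        for _ in range(60):
            alleles = rng.integers(0, 2, size=(6, rng.integers(4, 13))).astype(np.int8)
            m = make_matrix(alleles)
            inc = _incompatible_pairs(m.alleles)
            S = m.n_sites
            intervals = [
                (i, j) for i in range(S - 1) for j in range(i + 1, S) if inc[i, j]
            ]
            assert min_recombination_events(m) == rm_exhaustive_oracle(intervals)

    def test_alternating_incompatibility_chain(self):
        # every adjacent pair incompatible: the open intervals between
        # consecutive sites are disjoint, so one event fits in each
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 1]
        for S in (4, 5, 8, 9):
            alleles = np.array([a if k % 2 == 0 else b for k in range(S)]).T
            m = make_matrix(alleles)
            assert min_recombination_events(m) == S - 1

    def test_invariant_to_sample_order_and_allele_flip(self, rng):
        alleles = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        m = make_matrix(alleles)
        base = min_recombination_events(m)
        perm = make_matrix(alleles[rng.permutation(8)])
        assert min_recombination_events(perm) == base
        flipped = alleles.copy()
        flipped[:, 3] = 1 - flipped[:, 3]
        assert min_recombination_events(make_matrix(flipped)) == base

    def test_monotone_under_site_removal(self, rng):
        alleles = rng.integers(0, 2, size=(8, 14)).astype(np.int8)
        m = make_matrix(alleles)
        full = min_recombination_events(m)
        keep = np.sort(rng.choice(14, size=9, replace=False))
        assert min_recombination_events(m.take_sites(keep)) <= full

    def test_events_per_generation(self):
        assert events_per_generation(16_436, 15) == pytest.approx(1096, abs=0.5)
        assert events_per_generation(7, 7) == 1.0
        assert events_per_generation(200, 4) == 2 * events_per_generation(100, 4)
        with pytest.raises(DataError):
            events_per_generation(100, 0)


class TestSharedPrivate:
    def test_allele_in_one_panel_haplotype_is_shared(self):
        sd = make_matrix([[1, 0], [0, 1]], positions=[100, 200])
        panel_alleles = np.zeros((20, 2), dtype=np.int8)
        panel_alleles[3, 0] = 1
        panel = make_matrix(panel_alleles, positions=[100, 200])
        labels = label_shared_private(sd, panel)
        assert labels.tolist() == ["shared", "private"]

    def test_position_absent_from_panel_is_private(self):
        sd = make_matrix([[1], [0]], positions=[150])
        panel = make_matrix([[1], [0]], positions=[100])
        assert label_shared_private(sd, panel).tolist() == ["private"]

    def test_nucleotide_mismatch_flagged(self):
        sd = make_matrix([[1], [0]], positions=[100])
        panel = make_matrix([[1], [0]], positions=[100])
        labels = label_shared_private(sd, panel, alt_sd=["T"], alt_panel=["G"])
        assert labels.tolist() == ["unassigned"]

    def test_conversion_tract_snps_recovered_as_shared(self, rng):
        donor_cfg = SimConfig(n=10, S=600, region_length=200_000)
        recip_cfg = SimConfig(
            n=9, S=150, model=DemographicModel.sweep(0.02), region_length=200_000
        )
        (donor,) = gen_panel(donor_cfg, rng=rng)
        (recip,) = gen_panel(recip_cfg, rng=rng)
        recip_u, donor_u = align_union(recip, donor)
        converted, truth = inject_conversion_tracts(
            recip_u, donor_u, tracts_per_sample=3.0, mean_tract_bp=2_000,
            region_length=200_000, rng=rng,
        )
        assert truth, "fixture should contain at least one tract"
        seg = converted.take_sites(np.flatnonzero(converted.is_segregating()))
        labels = label_shared_private(seg, donor_u)
        donor_pos = set(donor.positions.tolist())
        in_tract = [
            lab
            for pos, lab in zip(seg.positions, labels)
            if int(pos) in donor_pos
            and any(t.start <= pos <= t.end for t in truth)
        ]
        assert in_tract
        assert np.mean([lab == "shared" for lab in in_tract]) >= 0.9


class TestRuns:
    def test_single_label_single_run(self):
        runs = snp_runs(["shared"] * 5, [10, 20, 30, 40, 55])
        assert runs == [RunRecord("shared", 10, 55, 5)]

    def test_alternating_labels_degenerate_runs(self):
        labels = ["shared", "private"] * 3
        runs = snp_runs(labels, [10, 20, 30, 40, 50, 60])
        assert all(r.n_snps == 1 and r.length_bp == 0 for r in runs)
        assert len(runs) == 6

    def test_runs_partition_the_snps(self, rng):
        labels = rng.choice(["shared", "private"], size=50).tolist()
        positions = np.sort(rng.choice(10_000, size=50, replace=False) + 1)
        runs = snp_runs(labels, positions)
        assert sum(r.n_snps for r in runs) == 50
        for a, b in zip(runs, runs[1:]):
            assert a.label != b.label  # same-label runs never adjacent

    def test_summary_fractions_and_density(self):
        runs = [
            RunRecord("shared", 100, 600, 4),  # 0.5 kb
            RunRecord("shared", 10_000, 25_000, 3),  # 15 kb
            RunRecord("shared", 40_000, 40_000, 1),  # single SNP
            RunRecord("private", 1_000, 3_000, 2),
        ]
        summary = run_summary(runs)
        sh = summary["shared"]
        assert sh["n_runs"] == 3
        assert sh["frac_lt_1kb"] == pytest.approx(2 / 3)
        assert sh["frac_lt_10kb"] == pytest.approx(2 / 3)
        assert sh["longest_bp"] == 15_000
        # density over positive-length runs only: (4+3) / (0.5 + 15) kb
        assert sh["density_per_kb"] == pytest.approx(7 / 15.5)
        assert summary["private"]["density_per_kb"] == pytest.approx(1.0)

    def test_zero_length_run_density_undefined(self):
        with pytest.raises(DataError):
            RunRecord("shared", 5, 5, 1).density_per_kb

    def test_tract_length_recovered_within_factor_two(self, rng):
        # geometric tracts with mean 1 kb: the median shared-run length
        # should land within a factor of two of the tract-length scale
        medians = []
        for _ in range(40):
            # donor SNP density high (15/kb) and recipient density low, so a
            # tract is sampled by many shared SNPs and rarely interrupted
            donor_cfg = SimConfig(n=10, S=1500, region_length=100_000)
            recip_cfg = SimConfig(
                n=9, S=30, model=DemographicModel.sweep(0.02), region_length=100_000
            )
            (donor,) = gen_panel(donor_cfg, rng=rng)
            (recip,) = gen_panel(recip_cfg, rng=rng)
            recip_u, donor_u = align_union(recip, donor)
            converted, truth = inject_conversion_tracts(
                recip_u, donor_u, tracts_per_sample=1.5, mean_tract_bp=1_000,
                region_length=100_000, rng=rng,
            )
            if not truth:
                continue
            seg = converted.take_sites(np.flatnonzero(converted.is_segregating()))
            labels = label_shared_private(seg, donor_u)
            runs = [
                r
                for r in snp_runs(labels, seg.positions)
                if r.label == "shared" and r.length_bp > 0
            ]
            if runs:
                medians.append(np.median([r.length_bp for r in runs]))
        assert medians
        assert 500 <= np.median(medians) <= 2000
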