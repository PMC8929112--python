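"""Windowed π, Weir–Cockerham Fst, and the joint top-tail sweep rule."""

import math

import numpy as np
import pytest

from nlr_atlas.core import ConfigError, GeneModel
from nlr_atlas.sweep_scan import (ComparisonSpec, SweepWindow,
                                  candidate_sweeps, comparison_overlap,
                                  genome_fst, merge_windows, scan,
                                  window_fst, window_pi, window_starts,
                                  windows_to_genes)

from .oracles import brute_force_pi, diploid_site_alleles


class TestWindowPi:
    def test_single_site_half_frequency(self, gm_factory):
        # p = 0.5, n = 4 alleles in a 100 bp window: (2*0.25*4/3)/100
        gm = gm_factory([("1A", 10, [1, 1])], ["g", "g"])
        assert window_pi(gm, "g", ("1A", 1, 100)) == pytest.approx(1 / 150)

    def test_monomorphic_window_is_zero(self, gm_factory):
        gm = gm_factory([("1A", 10, [0, 0]), ("1A", 20, [2, 2])], ["g", "g"])
        assert window_pi(gm, "g", ("1A", 1, 100)) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_pairwise_differences(self, gm_factory, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(2, 4))  # up to 6 haplotypes
        records = []
        for i in range(rng.integers(1, 12)):
            row = [int(rng.integers(-1, 3)) for _ in range(n_samples)]
            records.append(("1A", 10 * (i + 1), row))
        gm = gm_factory(records, ["g"] * n_samples)
        window = ("1A", 1, 200)
        expected = brute_force_pi(
            [diploid_site_alleles(row) for _, _, row in records], 200)
        got = window_pi(gm, "g", window)
        if math.isnan(got):
            assert expected == 0.0  # group entirely missing
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_all_missing_group_is_undefined(self, gm_factory):
        gm = gm_factory([("1A", 10, [-1, -1, 0])], ["g", "g", "h"])
        assert math.isnan(window_pi(gm, "g", ("1A", 1, 100)))

    def test_truncated_window_uses_covered_length(self, gm_factory):
        gm = gm_factory([("1A", 10, [1, 1])], ["g", "g"])
        full = window_pi(gm, "g", ("1A", 1, 100))
        trunc = window_pi(gm, "g", ("1A", 1, 100), chrom_length=50)
        assert trunc == pytest.approx(2 * full)


class TestWindowFst:
    def test_fixed_difference_is_one(self, gm_factory):
        gm = gm_factory([("1A", 10, [0, 0, 2, 2])], ["a", "a", "b", "b"])
        assert window_fst(gm, "a", "b", ("1A", 1, 100)) == pytest.approx(1.0)

    def test_fixed_difference_is_one_even_with_single_diploids(self, gm_factory):
        gm = gm_factory([("1A", 10, [0, 2])], ["a", "b"])
        assert window_fst(gm, "a", "b", ("1A", 1, 100)) == pytest.approx(1.0)

    def test_fixed_difference_is_one_with_unequal_samples(self, gm_factory):
        gm = gm_factory([("1A", 10, [0, 0, 0, 2, 2])], ["a"] * 3 + ["b"] * 2)
        assert window_fst(gm, "a", "b", ("1A", 1, 100)) == pytest.approx(1.0)

    def test_identical_half_frequencies_give_nonpositive_fst(self, gm_factory):
        # all-het: a = 0 exactly (hand evaluation of WC components)
        gm = gm_factory([("1A", 10, [1, 1, 1, 1])], ["a", "a", "b", "b"])
        assert window_fst(gm, "a", "b", ("1A", 1, 100)) <= 0.0
        # homozygote mix at p = 0.5: a < 0
        gm2 = gm_factory([("1A", 10, [0, 2, 0, 2])], ["a", "a", "b", "b"])
        assert window_fst(gm2, "a", "b", ("1A", 1, 100)) < 0.0

    def test_no_usable_sites_is_undefined(self, gm_factory):
        gm = gm_factory([("1A", 10, [-1, -1, 0, 0])], ["a", "a", "b", "b"])
        assert math.isnan(window_fst(gm, "a", "b", ("1A", 1, 100)))

    def test_balding_nichols_recovery(self):
        from nlr_atlas.synthdata import GroupSpec, SimulationConfig, \
            generate_genotypes

        cfg = SimulationConfig(
            seed=1, chrom_lengths={"1A": 10_000_000, "1B": 10_000_000},
            n_sites=20_000,
            group_specs=[GroupSpec("a", 50, divergence=0.2),
                         GroupSpec("b", 50, divergence=0.2)])
        gm = generate_genotypes(cfg)
        assert genome_fst(gm, "a", "b") == pytest.approx(0.2, abs=0.03)


class TestScan:
    def test_tiling_arithmetic(self):
        starts = window_starts(100_000, 50_000, 5_000)
        assert len(starts) == 11
        assert starts[0] == 1 and starts[-1] == 50_001

    def test_short_chromosome_gets_one_window(self):
        assert list(window_starts(30_000, 50_000, 5_000)) == [1]

    def test_windows_ordered_and_ratio_defined(self, gm_factory):
        records = [("1A", p, [0, 1, 0, 1]) for p in range(500, 90_000, 500)]
        gm = gm_factory(records, ["a", "a", "b", "b"])
        windows = scan(gm, ComparisonSpec("c", "a", "b"), 50_000, 5_000,
                       {"1A": 100_000})
        assert [(w.chrom, w.start) for w in windows] == \
            sorted((w.chrom, w.start) for w in windows)
        assert len(windows) == 11

    def test_identical_groups_give_ratio_one_and_tiny_fst(self, gm_factory):
        rng = np.random.default_rng(3)
        records = []
        for p in range(100, 50_000, 100):
            half = [int(rng.integers(0, 3)) for _ in range(10)]
            records.append(("1A", p, half + half))  # group b mirrors group a
        gm = gm_factory(records, ["a"] * 10 + ["b"] * 10)
        windows = scan(gm, ComparisonSpec("c", "a", "b"), 50_000, 50_000,
                       {"1A": 50_000})
        w = windows[0]
        assert w.pi_ratio == pytest.approx(1.0)
        # duplicated samples: no spurious positive differentiation (the WC
        # estimator may go slightly negative; reported as computed)
        assert w.fst <= 0.01

    def test_invalid_window_step_rejected(self, gm_factory):
        gm = gm_factory([("1A", 10, [0, 1])], ["a", "b"])
        with pytest.raises(ConfigError):
            scan(gm, ComparisonSpec("c", "a", "b"), 100, 200)


def _windows(ratios, fsts):
    return [SweepWindow("1A", 1 + 5000 * i, 50_000 + 5000 * i, 1.0, 1.0, r, f)
            for i, (r, f) in enumerate(zip(ratios, fsts))]


class TestCandidateSweeps:
    def test_unique_joint_maximum_is_candidate(self):
        rng = np.random.default_rng(4)
        ratios = rng.uniform(0.5, 1.5, 100)
        fsts = rng.uniform(0.0, 0.2, 100)
        ratios[7], fsts[7] = 10.0, 0.9
        cands = candidate_sweeps(_windows(ratios, fsts))
        assert any(w.start == 1 + 5000 * 7 for w in cands)

    def test_independent_statistics_give_sparse_candidates(self):
        rng = np.random.default_rng(5)
        n = 4000
        cands = candidate_sweeps(_windows(rng.uniform(size=n),
                                          rng.uniform(size=n)))
        # independence: expected 0.05 * 0.05 = 0.25% of windows
        assert 0 < len(cands) / n <= 0.01

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        ratios = rng.uniform(0.5, 3.0, 200)
        fsts = rng.uniform(0.0, 0.5, 200)
        base = {w.start for w in candidate_sweeps(_windows(ratios, fsts))}
        trans = {w.start for w in candidate_sweeps(
            _windows(np.exp(ratios), fsts ** 3))}
        assert base == trans

    def test_all_identical_windows_all_flagged_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cands = candidate_sweeps(_windows([1.0] * 25, [0.1] * 25))
        assert len(cands) == 25

    def test_too_few_defined_windows_refused(self):
        with pytest.raises(ConfigError, match="at least 20"):
            candidate_sweeps(_windows([1.0] * 5, [0.1] * 5))

    def test_undefined_windows_are_never_candidates(self):
        ratios = [float("nan")] * 10 + list(np.linspace(1, 2, 30))
        fsts = [0.5] * 10 + list(np.linspace(0, 0.4, 30))
        cands = candidate_sweeps(_windows(ratios, fsts))
        assert all(math.isfinite(w.pi_ratio) for w in cands)


class TestWindowsToGenes:
    def _cands(self):
        return [SweepWindow("1A", 10_001, 60_000, 1, 1, 5.0, 0.5, True),
                SweepWindow("1A", 15_001, 65_000, 1, 1, 5.0, 0.5, True)]

    def test_gene_inside_candidate_assigned(self):
        genes = [GeneModel("in", "1A", 20_000, 21_000)]
        res = windows_to_genes(self._cands(), genes)
        assert set(res.assignments) == {"in"}
        assert len(res.assignments["in"]) == 2

    def test_gene_one_bp_outside_not_assigned(self):
        genes = [GeneModel("out", "1A", 65_001, 66_000),
                 GeneModel("edge", "1A", 65_000, 66_000)]
        res = windows_to_genes(self._cands(), genes)
        assert set(res.assignments) == {"edge"}

    def test_merged_regions_and_total_mbp(self):
        res = windows_to_genes(self._cands(), [])
        assert res.regions == [("1A", 10_001, 65_000)]
        assert res.total_mbp == pytest.approx(0.055)

    def test_disjoint_windows_not_merged(self):
        cands = [SweepWindow("1A", 1, 50_000, 1, 1, 5, 0.5, True),
                 SweepWindow("1B", 1, 50_000, 1, 1, 5, 0.5, True)]
        assert len(merge_windows(cands)) == 2

    def test_planted_sweep_genes_recovered(self):
        from nlr_atlas.synthdata import (GroupSpec, SimulationConfig,
                                         SweepRegion, generate_genotypes)

        sweep = SweepRegion("1A", 4_000_001, 4_500_000, 0.05)
        cfg = SimulationConfig(
            seed=9, chrom_lengths={"1A": 10_000_000, "1B": 10_000_000},
            n_sites=20_000, sweep_regions=[sweep],
            group_specs=[GroupSpec("wild", 50, divergence=0.3),
                         GroupSpec("dom", 50, divergence=0.3)])
        gm = generate_genotypes(cfg)
        windows = scan(gm, ComparisonSpec("c", "wild", "dom"),
                       chrom_lengths=cfg.chrom_lengths)
        cands = candidate_sweeps(windows)
        genes = [GeneModel(f"s{i}", "1A", 4_100_000 + 60_000 * i,
                           4_100_000 + 60_000 * i + 5_000) for i in range(5)]
        genes += [GeneModel("far", "1B", 8_000_000, 8_005_000)]
        res = windows_to_genes(cands, genes)
        assert {f"s{i}" for i in range(5)} <= set(res.assignments)
        assert "far" not in res.assignments


class TestComparisonOverlap:
    def test_disjoint_sets(self):
        table = comparison_overlap({"a": {"x"}, "b": {"y"}})
        pair = table[table.comparisons == "a&b"].iloc[0]
        assert pair["count"] == 0

    def test_identical_sets(self):
        table = comparison_overlap({"a": {"x", "y"}, "b": {"x", "y"}})
        assert table[table.comparisons == "a&b"].iloc[0]["count"] == 2
        assert table[table.comparisons == "a"].iloc[0]["count"] == 0

    def test_chained_sets_share_at_most_two(self):
        sets = {"c1": {"A", "B"}, "c2": {"B", "C"}, "c3": {"C", "D"},
                "c4": {"D", "E"}}
        table = comparison_overlap(sets)
        deep = table[table.n_comparisons >= 3]
        assert (deep["count"] == 0).all()

    def test_single_comparison_rejected(self):
        with pytest.raises(ConfigError):
            comparison_overlap({"a": {"x"}})
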