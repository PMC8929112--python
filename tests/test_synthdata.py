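"""Ground-truth recovery and determinism of the synthetic-data generator."""

import numpy as np
import pytest

from nlr_atlas import molevo
from nlr_atlas.core import ConfigError
from nlr_atlas.synthdata import (ExpressionSample, GroupSpec, OmegaSetting,
                                 SimulationConfig, SweepRegion,
                                 default_expression_design,
                                 generate_annotation, generate_codon_pairs,
                                 generate_expression, generate_genotypes)


def two_group_config(seed=1, n_sites=20_000, F=0.2, n=50, sweeps=()):
    return SimulationConfig(
        seed=seed,
        chrom_lengths={"1A": 10_000_000, "1B": 10_000_000},
        n_sites=n_sites,
        sweep_regions=list(sweeps),
        group_specs=[GroupSpec("wild", n, divergence=F),
                     GroupSpec("domesticated", n, divergence=F)],
    )


class TestGenerateAnnotation:
    def test_zero_genes_gives_empty_lists(self):
        res = generate_annotation(SimulationConfig(seed=0, n_genes=0))
        assert res.genes == [] and res.proteins == [] and res.nlr_ids == set()

    def test_planted_consensus_count_matches_fraction(self, seed_consensus):
        cfg = SimulationConfig(seed=3, n_genes=100, nlr_fraction=0.2)
        res = generate_annotation(cfg)
        with_domain = [p.id for p in res.proteins if seed_consensus in p.sequence]
        assert len(with_domain) == 20
        assert set(with_domain) == res.nlr_ids

    def test_gene_spans_lie_inside_chromosomes(self):
        cfg = SimulationConfig(seed=4, n_genes=200)
        res = generate_annotation(cfg)
        for g in res.genes:
            assert 1 <= g.start <= g.end <= cfg.chrom_lengths[g.chrom]

    def test_telomere_bias_pulls_nlrs_toward_chromosome_ends(self):
        def mean_end_distance(bias, seed=11):
            cfg = SimulationConfig(seed=seed, n_genes=10_000, nlr_fraction=1.0,
                                   telomere_bias=bias)
            res = generate_annotation(cfg)
            dists = [
                min(g.start - 1, cfg.chrom_lengths[g.chrom] - g.end)
                for g in res.genes
            ]
            return np.mean(dists)

        assert mean_end_distance(5.0) < mean_end_distance(0.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError, match="nlr_fraction"):
            generate_annotation(SimulationConfig(seed=0, nlr_fraction=1.5))

    def test_determinism(self):
        a = generate_annotation(SimulationConfig(seed=9, n_genes=50))
        b = generate_annotation(SimulationConfig(seed=9, n_genes=50))
        assert a.genes == b.genes
        assert a.proteins == b.proteins


class TestGenerateGenotypes:
    def test_zero_sites_gives_empty_matrix_with_valid_panel(self):
        gm = generate_genotypes(two_group_config(n_sites=0))
        assert gm.n_sites == 0
        assert set(gm.panel["group"]) == {"wild", "domesticated"}

    def test_positions_sorted_unique_per_chromosome(self):
        gm = generate_genotypes(two_group_config(seed=2, n_sites=5000))
        for _, sub in gm.sites.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            assert np.all(np.diff(pos) > 0)

    def test_undiverged_groups_have_near_zero_fst(self):
        from nlr_atlas.sweep_scan import genome_fst

        gm = generate_genotypes(two_group_config(seed=5, F=0.0, n=30))
        assert abs(genome_fst(gm, "wild", "domesticated")) <= 0.01

    def test_theta_calibrates_genome_mean_pi(self):
        from nlr_atlas.sweep_scan import window_pi

        cfg = SimulationConfig(
            seed=6, chrom_lengths={"1A": 1_000_000}, n_sites=40_000,
            missing_rate=0.0,
            group_specs=[GroupSpec("g", 40, theta=0.01, divergence=0.05),
                         GroupSpec("h", 40, theta=0.002, divergence=0.05)])
        gm = generate_genotypes(cfg)
        pi_g = window_pi(gm, "g", ("1A", 1, 1_000_000))
        pi_h = window_pi(gm, "h", ("1A", 1, 1_000_000))
        assert pi_g == pytest.approx(0.01, rel=0.10)
        assert pi_h == pytest.approx(0.002, rel=0.10)

    def test_unachievable_theta_rejected(self):
        cfg = SimulationConfig(
            seed=6, chrom_lengths={"1A": 1_000_000}, n_sites=100,
            group_specs=[GroupSpec("g", 10, theta=0.01),
                         GroupSpec("h", 10, theta=0.01)])
        with pytest.raises(ConfigError, match="increase n_sites"):
            generate_genotypes(cfg)

    def test_sweep_region_elevates_local_pi_ratio(self):
        from nlr_atlas.sweep_scan import ComparisonSpec, scan

        sweep = SweepRegion("1A", 3_000_001, 3_500_000, 0.05)
        cfg = two_group_config(seed=7, F=0.2, sweeps=[sweep])
        gm = generate_genotypes(cfg)
        windows = scan(gm, ComparisonSpec("c", "wild", "domesticated"),
                       chrom_lengths=cfg.chrom_lengths)
        inside = [w.pi_ratio for w in windows
                  if w.chrom == "1A" and w.start >= sweep.start
                  and w.end <= sweep.end and np.isfinite(w.pi_ratio)]
        genome = [w.pi_ratio for w in windows if np.isfinite(w.pi_ratio)]
        assert np.median(inside) > np.median(genome)

    def test_sweep_truth_recorded_in_metadata(self):
        sweep = SweepRegion("1A", 1, 100_000, 0.1)
        gm = generate_genotypes(two_group_config(seed=8, sweeps=[sweep]))
        assert gm.metadata["sweep_regions"] == [
            ("1A", 1, 100_000, 0.1, "domesticated")]

    def test_sweep_on_unknown_chromosome_rejected(self):
        with pytest.raises(ConfigError, match="unknown chromosome"):
            generate_genotypes(two_group_config(
                sweeps=[SweepRegion("9Z", 1, 10, 0.1)]))

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError, match="n_samples"):
            GroupSpec("tiny", 1)

    def test_determinism(self):
        a = generate_genotypes(two_group_config(seed=12, n_sites=2000))
        b = generate_genotypes(two_group_config(seed=12, n_sites=2000))
        assert a.sites.equals(b.sites)
        assert np.array_equal(a.gt, b.gt)


class TestGenerateCodonPairs:
    def test_zero_branch_length_gives_identical_sequences(self):
        cfg = SimulationConfig(seed=1, omega_settings=[
            OmegaSetting(0.5, 0.0, n_pairs=5, n_codons=50)])
        for p in generate_codon_pairs(cfg):
            assert p.seq1 == p.seq2

    def test_sequences_are_stop_free_and_codon_phase(self):
        cfg = SimulationConfig(seed=2, omega_settings=[
            OmegaSetting(0.5, 0.5, n_pairs=5, n_codons=60)])
        for p in generate_codon_pairs(cfg):
            assert len(p.seq1) % 3 == 0
            codons = {p.seq1[i:i + 3] for i in range(0, len(p.seq1), 3)}
            assert not codons & {"TAA", "TAG", "TGA"}

    @pytest.mark.parametrize("omega", [0.2, 0.5, 1.0])
    def test_ng86_recovers_simulated_omega_within_25pct(self, omega):
        cfg = SimulationConfig(seed=20, omega_settings=[
            OmegaSetting(omega, 0.3, n_pairs=200, n_codons=300)])
        ratios = [molevo.kaks(p).ratio for p in generate_codon_pairs(cfg)]
        mean = np.nanmean(ratios)
        assert mean == pytest.approx(omega, rel=0.25)

    def test_neutral_omega_estimate_near_one(self):
        cfg = SimulationConfig(seed=21, omega_settings=[
            OmegaSetting(1.0, 0.3, n_pairs=200, n_codons=300)])
        ratios = [molevo.kaks(p).ratio for p in generate_codon_pairs(cfg)]
        assert np.nanmean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_event_truth_recorded(self):
        cfg = SimulationConfig(seed=3, omega_settings=[
            OmegaSetting(0.2, 0.3, n_pairs=10, n_codons=100)])
        pairs = generate_codon_pairs(cfg)
        assert all({"syn_events", "nonsyn_events"} <= set(p.metadata)
                   for p in pairs)
        # purifying selection: far fewer nonsynonymous than synonymous events
        syn = sum(p.metadata["syn_events"] for p in pairs)
        non = sum(p.metadata["nonsyn_events"] for p in pairs)
        assert non < syn

    def test_ks_peak_brackets_truth(self):
        cfg = SimulationConfig(seed=22, omega_settings=[
            OmegaSetting(0.5, 0.05, n_pairs=300, n_codons=300)])
        pairs = generate_codon_pairs(cfg)
        results = [molevo.kaks(p) for p in pairs]
        # truth: realised synonymous events per synonymous site
        true_ks = np.mean([
            p.metadata["syn_events"] / r.s_sites
            for p, r in zip(pairs, results)
        ])
        _, peak = molevo.ks_histogram(results, bin_width=0.04)
        assert peak[0] <= true_ks < peak[1]

    def test_negative_omega_rejected(self):
        with pytest.raises(ConfigError):
            OmegaSetting(-0.1, 0.3)


class TestGenerateExpression:
    def _design(self):
        return default_expression_design("fhb", timepoints=(12.0, 96.0),
                                         tissues=("spike",))

    def test_no_false_positives_without_planted_effect(self):
        from nlr_atlas.expression import responsive_genes

        cfg = SimulationConfig(seed=1, n_genes=200,
                               expression_design=self._design(),
                               expression_fold=1.0)
        em = generate_expression(cfg, set())
        calls = responsive_genes(em, "fhb", fold=2.0)
        assert len(calls) <= 2  # <= 1% false-positive tolerance

    def test_tenfold_genes_called_responsive_at_threshold_two(self):
        from nlr_atlas.expression import responsive_genes

        cfg = SimulationConfig(seed=2, n_genes=200,
                               expression_design=self._design(),
                               expression_fold=10.0)
        responsive = {f"G{i + 1:06d}" for i in range(20)}
        em = generate_expression(cfg, responsive)
        calls = responsive_genes(em, "fhb", fold=2.0)
        recall = len(calls & responsive) / len(responsive)
        precision = len(calls & responsive) / len(calls) if calls else 0.0
        assert recall >= 0.95 and precision >= 0.95

    def test_noiseless_fold_is_exact(self):
        cfg = SimulationConfig(seed=3, n_genes=10,
                               expression_design=self._design(),
                               expression_fold=4.0,
                               expression_noise_sigma=0.0)
        em = generate_expression(cfg, {"G000001"})
        design = em.design
        ino = design.index[design["condition"] == "inoculated"]
        ctl = design.index[design["condition"] == "control"]
        ratio = em.values.loc["G000001", list(ino)].mean() / \
            em.values.loc["G000001", list(ctl)].mean()
        assert ratio == pytest.approx(4.0)

    def test_unknown_responsive_gene_rejected(self):
        cfg = SimulationConfig(seed=4, n_genes=5,
                               expression_design=self._design())
        with pytest.raises(ConfigError, match="responsive ids"):
            generate_expression(cfg, {"nope"})

    def test_empty_design_rejected(self):
        cfg = SimulationConfig(seed=5, n_genes=5, expression_design=[])
        with pytest.raises(ConfigError, match="design"):
            generate_expression(cfg, set())
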