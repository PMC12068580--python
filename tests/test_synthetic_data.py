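"""Forward simulator: SNP maps, event accrual, depth model, truth scoring."""

import numpy as np
import pandas as pd
import pytest

import lohma
from lohma import GT, SimConfig, SimEvent, SimTruth
from conftest import make_snp_map


class TestSimConfig:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimConfig(interstitial_rate=-1)
        with pytest.raises(ValueError):
            SimConfig(snm_spectrum=(0.5, 0.5, 0, 0, 0, 0.1))
        with pytest.raises(ValueError):
            SimConfig(snp_density_per_kb=0)
        with pytest.raises(ValueError):
            SimConfig(depth=0)

    def test_default_genome_is_sixteen_chromosomes(self):
        cfg = SimConfig()
        assert len(cfg.chrom_lengths) == 16
        assert cfg.genome_size == pytest.approx(12.07e6, rel=0.01)


class TestSimulateSnpMap:
    def test_count_matches_poisson_mean(self):
        cfg = SimConfig(seed=7, density_heterogeneity=0.0)
        snp_map = lohma.simulate_snp_map(cfg)
        mean = 6.1e-3 * cfg.genome_size  # ~73,600
        sd = np.sqrt(mean)
        assert abs(snp_map.n_snps - mean) < 4 * sd

    def test_sparse_density_yields_no_snps(self):
        cfg = SimConfig(
            chrom_lengths={"chrI": 1_000}, centromeres={"chrI": 500},
            snp_density_per_kb=0.001, seed=1,
        )
        assert lohma.simulate_snp_map(cfg).n_snps == 0

    def test_positions_strictly_increasing_and_alleles_differ(self):
        cfg = SimConfig(seed=3, chrom_lengths={"chrI": 500_000}, centromeres={"chrI": 1})
        df = lohma.simulate_snp_map(cfg).df
        assert (np.diff(df["pos"]) > 0).all()
        assert (df["s_allele"] != df["y_allele"]).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5, chrom_lengths={"chrI": 300_000}, centromeres={"chrI": 1})
        m1 = lohma.simulate_snp_map(cfg)
        m2 = lohma.simulate_snp_map(cfg)
        assert m1.df.equals(m2.df)


class TestSimulateLine:
    def test_all_rates_zero_means_pristine_heterozygote(self, two_chrom_config):
        cfg = SimConfig(
            chrom_lengths=two_chrom_config.chrom_lengths,
            centromeres=two_chrom_config.centromeres,
            interstitial_rate=0, terminal_rate=0, deletion_rate=0,
            snm_rate=0, indel_rate=0, gain_rate=0, loss_rate=0, seed=2,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        line = lohma.simulate_line(cfg, snp_map, 3)
        assert line.truth.events == []
        assert (line.states == GT.HET).all()
        assert lohma.call_tracts(line.states, snp_map) == []

    def test_event_counts_poisson(self, two_chrom_config):
        cfg = SimConfig(
            chrom_lengths=two_chrom_config.chrom_lengths,
            centromeres=two_chrom_config.centromeres,
            interstitial_rate=0.02, terminal_rate=0, deletion_rate=0,
            snm_rate=0, indel_rate=0, gain_rate=0, loss_rate=0,
            generations=1000, seed=4,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        counts = [
            len(lohma.simulate_line(cfg, snp_map, 100 + i).truth.events)
            for i in range(100)
        ]
        mean = np.mean(counts)
        sd_of_mean = np.sqrt(20 / 100)
        assert abs(mean - 20) < 4 * sd_of_mean

    def test_terminal_loh_reaches_chromosome_end_depth_unchanged(self):
        cfg = SimConfig(
            chrom_lengths={"chrI": 200_000}, centromeres={"chrI": 100_000},
            interstitial_rate=0, terminal_rate=0.005, deletion_rate=0,
            snm_rate=0, indel_rate=0, gain_rate=0, loss_rate=0, seed=8,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        for s in range(20):
            line = lohma.simulate_line(cfg, snp_map, s)
            for ev in line.truth.events:
                assert ev.start == 1 or ev.end == 200_000
            # copy-neutral: total depth is exactly the configured depth
            total = line.s_depth + line.y_depth
            assert (total == cfg.depth).all()

    def test_deletion_halves_total_depth_over_interval(self):
        cfg = SimConfig(
            chrom_lengths={"chrI": 500_000}, centromeres={"chrI": 250_000},
            interstitial_rate=0, terminal_rate=0, deletion_rate=0.01,
            snm_rate=0, indel_rate=0, gain_rate=0, loss_rate=0, seed=9,
            tract_length_median_bp=5_000,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        line = lohma.simulate_line(cfg, snp_map, 1)
        assert line.truth.events
        pos = snp_map.positions("chrI")
        total = line.s_depth + line.y_depth
        # expected copy from the event log: each deletion removes the lost
        # haplotype; overlapping opposite-parent deletions remove both
        lost_s = np.zeros(len(pos), dtype=bool)
        lost_y = np.zeros(len(pos), dtype=bool)
        for ev in line.truth.events:
            inside = (pos >= ev.start) & (pos <= ev.end)
            if ev.parent == "S288C":
                lost_y |= inside
            else:
                lost_s |= inside
        expected_copy = 2 - lost_s.astype(int) - lost_y.astype(int)
        assert np.array_equal(total, np.round(cfg.depth * expected_copy / 2).astype(int))
        assert (total[lost_s ^ lost_y] == cfg.depth // 2).all()

    def test_gain_shifts_allele_fraction_and_coverage(self):
        cfg = SimConfig(
            chrom_lengths={"chrI": 500_000}, centromeres={"chrI": 250_000},
            interstitial_rate=0, terminal_rate=0, deletion_rate=0,
            snm_rate=0, indel_rate=0, gain_rate=0.002, loss_rate=0, seed=12,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        for s in range(30):
            line = lohma.simulate_line(cfg, snp_map, s)
            gains = line.truth.of_kind("gain")
            if len(gains) == 1:
                break
        assert len(gains) == 1
        total = line.s_depth + line.y_depth
        assert (total == int(cfg.depth * 1.5)).all()
        frac = line.s_depth / total
        assert abs(frac.mean() - (1 / 3 if gains[0].parent == "YJM789" else 2 / 3)) < 0.02
        # binned coverage scaled ~1.5x relative to a euploid line
        euploid = lohma.simulate_line(
            SimConfig(
                chrom_lengths=cfg.chrom_lengths, centromeres=cfg.centromeres,
                interstitial_rate=0, terminal_rate=0, deletion_rate=0,
                snm_rate=0, indel_rate=0, gain_rate=0, loss_rate=0, seed=1,
            ),
            snp_map, 2,
        )
        ratio = line.coverage_bins["count"].median() / euploid.coverage_bins["count"].median()
        assert ratio == pytest.approx(1.5, rel=0.05)

    def test_bit_reproducible_under_seed(self, two_chrom_config):
        snp_map = lohma.simulate_snp_map(two_chrom_config)
        a = lohma.simulate_line(two_chrom_config, snp_map, 77)
        b = lohma.simulate_line(two_chrom_config, snp_map, 77)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.s_depth, b.s_depth)
        assert a.coverage_bins.equals(b.coverage_bins)
        assert a.truth.events == b.truth.events

    def test_missing_rate_masks_genotypes(self, two_chrom_config):
        cfg = SimConfig(
            chrom_lengths=two_chrom_config.chrom_lengths,
            centromeres=two_chrom_config.centromeres,
            missing_rate=0.2, seed=6,
        )
        snp_map = lohma.simulate_snp_map(cfg)
        line = lohma.simulate_line(cfg, snp_map, 1)
        frac = (line.states == GT.MISSING).mean()
        assert 0.15 < frac < 0.25

    def test_empty_map_rejected(self, two_chrom_config):
        empty = make_snp_map({})
        with pytest.raises(ValueError):
            lohma.simulate_line(two_chrom_config, empty, 1)


class TestTruthCompare:
    def test_noise_free_recovery_is_exact(self, two_chrom_config):
        snp_map = lohma.simulate_snp_map(two_chrom_config)
        for seed in range(10):
            line = lohma.simulate_line(two_chrom_config, snp_map, seed)
            called = lohma.call_tracts(line.states, snp_map, line.line_id)
            report = lohma.truth_compare(called, line.truth, snp_map)
            if report.n_truth_detectable:
                assert report.sensitivity == 1.0
            if report.n_called:
                assert report.precision == 1.0
                assert report.mean_boundary_error_bp == 0.0

    def test_empty_truth_and_calls_give_nan(self, tiny_map):
        report = lohma.truth_compare([], SimTruth("L"), tiny_map)
        assert np.isnan(report.sensitivity) and np.isnan(report.precision)

    def test_two_snp_event_excluded_from_detectable(self, tiny_map):
        # event covers SNPs at 15000 and 25000 only
        truth = SimTruth(
            "L", [SimEvent("interstitial-LOH", "chrI", 14_000, 26_000, 1, "S288C")]
        )
        report = lohma.truth_compare([], truth, tiny_map, min_support=3)
        assert report.n_truth_detectable == 0
        assert np.isnan(report.sensitivity)

    def test_unknown_chromosome_rejected(self, tiny_map):
        bad = [lohma.LohTract("L", "chrZ", 1, 10, 3, "S288C")]
        with pytest.raises(ValueError, match="chrZ"):
            lohma.truth_compare(bad, SimTruth("L"), tiny_map)


class TestEmission:
    def test_ad_fields_sum_to_depth(self, tmp_path, two_chrom_config):
        snp_map = lohma.simulate_snp_map(two_chrom_config)
        line = lohma.simulate_line(two_chrom_config, snp_map, 5, "L1")
        lohma.emit_depth(line, snp_map, tmp_path / "d.tsv")
        df = pd.read_csv(tmp_path / "d.tsv", sep="\t")
        assert np.array_equal(df["s_depth"] + df["y_depth"], line.s_depth + line.y_depth)

    def test_zero_sample_vcf_is_header_only(self, tmp_path, tiny_map):
        path = tmp_path / "empty.vcf"
        lohma.emit_vcf([], tiny_map, path, parent_sample=None)
        lines = path.read_text().splitlines()
        body = [l for l in lines if not l.startswith("#")]
        header_cols = [l for l in lines if l.startswith("#CHROM")][0].split("\t")
        assert header_cols == "#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT".split()
        assert all(len(l.split("\t")) == 9 for l in body)

    def test_truth_log_round_trip(self, tmp_path, two_chrom_config):
        snp_map = lohma.simulate_snp_map(two_chrom_config)
        line = lohma.simulate_line(two_chrom_config, snp_map, 5, "L1")
        lohma.emit_truth([line], tmp_path / "t.tsv")
        df = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        assert len(df) == len(line.truth.events)
        assert set(df["kind"]) <= set(
            ["interstitial-LOH", "terminal-LOH", "deletion-LOH", "SNM", "indel", "gain", "loss"]
        )
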