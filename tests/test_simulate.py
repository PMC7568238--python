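"""The synthetic-study generator: determinism, constructive validity, planted truth."""

import filecmp

import numpy as np
import pytest
from scipy.stats import kstest

from regdomain.domains import DomainMap
from regdomain.enrichment import capture_genes, extend_peaks
from regdomain.genome import GenomicInterval, read_bed, read_chrom_sizes, read_cluster, read_genes
from regdomain.motifs import best_hit_score
from regdomain.simulate import (
    ClusterSpec,
    SimConfig,
    default_pwm,
    simulate_annotation,
    simulate_clusters,
    simulate_domains,
    simulate_peaks_planted,
    simulate_sequences,
    simulate_study,
)


def small_config(seed=11, **kw):
    defaults = dict(
        seed=seed,
        n_chroms=3,
        chrom_length_bp=20_000_000,
        n_genes=1_500,
        n_peaks=700,
        cluster_specs=[
            ClusterSpec("up", 40, 0.6, 5_000),
            ClusterSpec("down", 25, None, 5_000),
        ],
        n_domains_per_chrom=8,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestAnnotation:
    def test_deterministic_given_seed(self):
        cfg = small_config()
        s1, g1 = simulate_annotation(cfg)
        s2, g2 = simulate_annotation(cfg)
        assert s1 == s2 and g1 == g2

    def test_genes_confined_to_configured_chromosomes(self):
        cfg = small_config(n_chroms=2)
        sizes, genes = simulate_annotation(cfg)
        assert {g.chrom for g in genes} <= {"chr1", "chr2"}
        assert len(genes) == cfg.n_genes
        assert len({g.gene_id for g in genes}) == cfg.n_genes

    def test_tss_positions_consistent_with_uniform_placement(self):
        cfg = small_config(n_genes=10_000, n_chroms=1)
        _, genes = simulate_annotation(cfg)
        pos = np.array([g.tss for g in genes]) / cfg.chrom_length_bp
        assert kstest(pos, "uniform").pvalue > 0.01

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_annotation(SimConfig(n_chroms=1, chrom_length_bp=30_000, n_genes=50_000,
                                          cluster_specs=[], n_peaks=10))


class TestClusters:
    def test_clusters_are_disjoint_subsets_of_the_annotation(self, rng):
        cfg = small_config()
        _, genes = simulate_annotation(cfg, rng)
        clusters = simulate_clusters(cfg, genes, rng)
        ids = {g.gene_id for g in genes}
        seen = set()
        for spec in cfg.cluster_specs:
            members = clusters[spec.name].members
            assert len(members) == spec.size
            assert members <= ids and not (members & seen)
            seen |= members


class TestPlantedPeaks:
    def run(self, cfg):
        rng = np.random.default_rng(cfg.seed)
        sizes, genes = simulate_annotation(cfg, rng)
        clusters = simulate_clusters(cfg, genes, rng)
        peaks, truth = simulate_peaks_planted(cfg, genes, clusters, rng)
        return sizes, genes, clusters, peaks, truth

    def test_forced_planting_captures_every_cluster_gene(self):
        cfg = small_config(cluster_specs=[ClusterSpec("up", 10, 1.0, 5_000)])
        sizes, genes, clusters, peaks, truth = self.run(cfg)
        planted = truth[truth.kind == "planted"]
        assert set(clusters["up"].members) <= set(planted.target_gene)
        windows = extend_peaks(peaks, 5_000, sizes)
        assert clusters["up"].members <= capture_genes(windows, genes)

    def test_no_planting_when_all_rates_are_zero(self):
        cfg = small_config(cluster_specs=[ClusterSpec("up", 10, 0.0, 5_000)],
                           background_capture_prob=0.0)
        *_, truth = self.run(cfg)
        assert (truth.kind == "desert").all()
        assert (truth.target_gene == "none").all()

    def test_peak_budget_and_truth_table_align(self):
        cfg = small_config()
        _, _, _, peaks, truth = self.run(cfg)
        assert len(peaks) == cfg.n_peaks == len(truth)
        assert [p.name for p in peaks] == list(truth.peak)

    def test_infeasible_budget_is_a_diagnosed_error(self):
        cfg = small_config(n_peaks=20, cluster_specs=[ClusterSpec("up", 100, 1.0, 5_000)])
        with pytest.raises(ValueError, match="infeasible peak budget"):
            self.run(cfg)

    def test_planted_truth_entries_lie_within_their_tier_distance(self):
        cfg = small_config()
        sizes, genes, clusters, peaks, truth = self.run(cfg)
        tss = {g.gene_id: g.tss for g in genes}
        chrom = {g.gene_id: g.chrom for g in genes}
        for row in truth[truth.kind == "planted"].itertuples():
            t = tss[row.target_gene]
            assert chrom[row.target_gene] == row.chrom
            edge = max(row.start - t, t - (row.end - 1), 0)
            assert edge <= row.tier_distance_bp

    def test_capture_proportions_recover_planted_rates(self):
        """Cluster and background capture at the calibration distance sit within
        binomial sampling error of the planted probabilities."""
        cfg = small_config(n_genes=4_000, n_peaks=1_500,
                           cluster_specs=[ClusterSpec("up", 120, 0.6, 5_000)])
        sizes, genes, clusters, peaks, _ = self.run(cfg)
        windows = extend_peaks(peaks, 5_000, sizes)
        captured = capture_genes(windows, genes)
        members = clusters["up"].members
        pc = len(captured & members) / len(members)
        pu = len(captured) / len(genes)
        assert abs(pc - 0.6) <= 3 * np.sqrt(0.6 * 0.4 / 120)
        assert abs(pu - 0.15) <= 3 * np.sqrt(0.15 * 0.85 / 4_000)


class TestDomains:
    def test_zero_gap_tiles_each_chromosome_exactly(self):
        cfg = small_config()
        domains = simulate_domains(cfg)
        per_chrom = {}
        for d in domains:
            per_chrom.setdefault(d.chrom, []).append(d)
        for chrom, doms in per_chrom.items():
            assert len(doms) == cfg.n_domains_per_chrom
            assert doms[0].start == 0 and doms[-1].end == cfg.chrom_length_bp
            assert all(a.end == b.start for a, b in zip(doms, doms[1:]))

    def test_single_domain_per_chromosome(self):
        cfg = small_config(n_domains_per_chrom=1)
        domains = simulate_domains(cfg)
        assert all(len(d) == cfg.chrom_length_bp for d in domains)

    def test_gapped_output_still_validates_and_shrinks(self):
        cfg = small_config(domain_gap_fraction=0.2)
        domains = simulate_domains(cfg)
        DomainMap(domains)  # non-overlap validation
        total = sum(len(d) for d in domains if d.chrom == "chr1")
        assert total < cfg.chrom_length_bp


class TestSequences:
    def regions(self, n, width=200):
        return [GenomicInterval("r", i * width, (i + 1) * width) for i in range(n)]

    def test_full_plant_rate_logs_an_instance_in_every_region(self, rng):
        pwm = default_pwm()
        rs, plant_log = simulate_sequences(self.regions(50), pwm, 1.0, rng)
        assert plant_log.planted.all()
        for seq, row in zip(rs.sequences, plant_log.itertuples()):
            assert 0 <= row.offset <= len(seq) - len(pwm)

    def test_zero_plant_rate_hit_fraction_matches_threshold_false_positive_rate(self, rng):
        pwm = default_pwm()
        rs, plant_log = simulate_sequences(self.regions(300), pwm, 0.0, rng)
        assert not plant_log.planted.any()
        fp = rs.hit_mask(pwm).mean()
        assert fp < 0.2  # threshold keeps the unplanted hit rate low

    def test_planted_instances_raise_scores_at_the_logged_offset(self, rng):
        """Sampled instances are stochastic, so assert in aggregate: the mean
        score at logged plant sites far exceeds the unplanted expectation."""
        pwm = default_pwm()
        rs, plant_log = simulate_sequences(self.regions(60), pwm, 1.0, rng)
        planted_scores = [
            best_hit_score(seq[row.offset : row.offset + len(pwm)], pwm)
            for seq, row in zip(rs.sequences, plant_log.itertuples())
        ]
        null, _ = simulate_sequences(self.regions(60), pwm, 0.0, rng)
        null_scores = [best_hit_score(s[: len(pwm)], pwm) for s in null.sequences]
        assert np.mean(planted_scores) > 0.6 * pwm.max_score
        assert np.mean(planted_scores) > np.mean(null_scores) + 0.3 * pwm.max_score

    def test_region_shorter_than_motif_is_an_error(self, rng):
        pwm = default_pwm()
        with pytest.raises(ValueError, match="shorter"):
            simulate_sequences([GenomicInterval("r", 0, 5)], pwm, 0.5, rng)


class TestStudyFixture:
    def test_two_runs_are_byte_identical(self, tmp_path):
        cfg = small_config()
        p1 = simulate_study(cfg, tmp_path / "run1")
        p2 = simulate_study(cfg, tmp_path / "run2")
        files = [
            "chrom.sizes", "genes.bed", "peaks.bed", "tads.bed",
            "target_regions.fa", "background_regions.fa",
            "clusters/up.txt", "truth/peaks.tsv", "sim_config.yaml",
        ]
        match, mismatch, errors = filecmp.cmpfiles(p1.root, p2.root, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ_but_share_schema(self, tmp_path):
        pa = simulate_study(small_config(seed=1), tmp_path / "a")
        pb = simulate_study(small_config(seed=2), tmp_path / "b")
        assert pa.peaks.read_text() != pb.peaks.read_text()
        assert len(read_bed(pa.peaks)) == len(read_bed(pb.peaks))

    def test_emitted_files_pass_the_package_validators(self, tmp_path):
        paths = simulate_study(small_config(), tmp_path / "study")
        sizes = read_chrom_sizes(paths.chrom_sizes)
        genes = read_genes(paths.genes)
        peaks = read_bed(paths.peaks)
        DomainMap(read_bed(paths.domains, kind="domains"))
        cluster = read_cluster(paths.clusters["up"], (g.gene_id for g in genes))
        assert cluster.n_unresolved == 0
        assert {p.chrom for p in peaks} <= set(sizes)
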