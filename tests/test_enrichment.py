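"""Peak extension, TSS capture, and the distance-sweep enrichment statistic."""

import numpy as np
import pytest

from regdomain.domains import DomainMap
from regdomain.enrichment import (
    DEFAULT_DISTANCES,
    GeneIndex,
    capture_genes,
    distance_sweep,
    enrich_at_distance,
    extend_peaks,
    proportion_within,
)
from regdomain.genome import ChromSizes, GeneCluster

from conftest import gene, iv, random_genes, random_intervals

SIZES = ChromSizes({"chr1": 100_000, "chr2": 100_000})


class TestExtendPeaks:
    def test_symmetric_extension(self):
        (w,) = extend_peaks([iv("chr1", 1000, 1200)], 100, SIZES)
        assert (w.start, w.end) == (900, 1300)

    def test_clipped_at_chromosome_bounds(self):
        (w,) = extend_peaks([iv("chr1", 50, 100)], 100, SIZES)
        assert (w.start, w.end) == (0, 200)
        (w,) = extend_peaks([iv("chr1", 99_900, 99_950)], 100, SIZES)
        assert (w.start, w.end) == (99_800, 100_000)

    def test_peak_beyond_chromosome_end_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds chromosome length"):
            extend_peaks([iv("chr1", 99_900, 100_100)], 10, SIZES)

    def test_domain_clip_dominates_distance(self):
        domains = DomainMap([iv("chr1", 800, 1250, name="d1")])
        (w,) = extend_peaks([iv("chr1", 1000, 1200)], 500, SIZES, domains=domains)
        assert (w.start, w.end) == (800, 1250)

    def test_peak_outside_every_domain_is_excluded(self):
        domains = DomainMap([iv("chr1", 0, 500, name="d1")])
        assert extend_peaks([iv("chr1", 1000, 1200)], 100, SIZES, domains=domains) == []

    def test_unknown_chromosome_is_an_error(self):
        with pytest.raises(KeyError):
            extend_peaks([iv("chrX", 0, 10)], 100, SIZES)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            extend_peaks([iv("chr1", 0, 10)], -1, SIZES)


class TestCaptureGenes:
    def test_window_bounds_are_start_inclusive_end_exclusive(self):
        window = [iv("chr1", 900, 1300)]
        at_start = gene("a", "chr1", 900, 1000, "+")
        at_end_minus = gene("b", "chr1", 1200, 1300, "-")  # tss = 1299
        at_end = gene("c", "chr1", 1300, 1400, "+")
        assert capture_genes(window, [at_start, at_end_minus, at_end]) == {"a", "b"}

    def test_gene_counted_once_across_overlapping_windows(self):
        windows = [iv("chr1", 0, 1000), iv("chr1", 500, 1500)]
        assert capture_genes(windows, [gene("a", "chr1", 600, 700, "+")]) == {"a"}

    def test_matches_all_pairs_scan_on_random_instances(self, rng):
        for _ in range(15):
            windows = random_intervals(rng, 80, max_pos=20_000, max_len=3_000)
            genes = random_genes(rng, 150, max_pos=20_000)
            expected = {
                g.gene_id
                for g in genes
                if any(w.contains_point(g.chrom, g.tss) for w in windows)
            }
            assert capture_genes(windows, genes) == expected


def toy_universe():
    """20 genes at 1 kb spacing on chr1; one peak; d=3.5 kb captures 8 TSSs."""
    genes = [gene(f"g{i:02d}", "chr1", 1000 * i, 1000 * i + 100, "+") for i in range(20)]
    sizes = ChromSizes({"chr1": 100_000})
    peaks = [iv("chr1", 8500, 8600)]  # at d=3500: window [5000, 12100) -> TSSs g05..g12

    return genes, sizes, peaks


class TestEnrichAtDistance:
    def test_composed_counts_match_the_enumeration_oracle(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("up", frozenset({"g05", "g06", "g07", "g08", "g19"}))
        res = enrich_at_distance(peaks, genes, cluster, 3500, sizes)
        assert (res.N, res.K, res.n, res.k) == (20, 5, 8, 4)
        assert res.p_upper == pytest.approx(7280 / 125970, rel=1e-12)

    def test_cluster_equal_to_universe_is_degenerate(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("all", frozenset(g.gene_id for g in genes))
        res = enrich_at_distance(peaks, genes, cluster, 3500, sizes)
        assert res.k == res.n and res.p_upper == 1.0 and res.fold == 1.0

    def test_peaks_on_geneless_chromosome_capture_nothing(self):
        genes, _, _ = toy_universe()
        sizes = ChromSizes({"chr1": 100_000, "chr2": 100_000})
        cluster = GeneCluster("up", frozenset({"g00"}))
        res = enrich_at_distance([iv("chr2", 0, 100)], genes, cluster, 5000, sizes)
        assert (res.n, res.k, res.p_upper) == (0, 0, 1.0)
        assert np.isnan(res.fold)

    def test_unresolved_cluster_ids_rejected(self):
        genes, sizes, peaks = toy_universe()
        with pytest.raises(ValueError, match="outside the gene universe"):
            enrich_at_distance(peaks, genes, GeneCluster("x", frozenset({"nope"})), 100, sizes)

    def test_proportion_within_matches_enrichment_fields(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("up", frozenset({"g05", "g06", "g19", "g18", "g17"}))
        pc, pu = proportion_within(peaks, genes, cluster, 3500, sizes)
        assert pc == pytest.approx(2 / 5)
        assert pu == pytest.approx(8 / 20)

    def test_saturating_distance_captures_everything(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("up", frozenset({"g00", "g19"}))
        pc, pu = proportion_within(peaks, genes, cluster, 100_000, sizes)
        assert (pc, pu) == (1.0, 1.0)


class TestDistanceSweep:
    def test_counts_are_monotone_in_distance(self, rng):
        genes = random_genes(rng, 400, max_pos=90_000)
        peaks = random_intervals(rng, 40, max_pos=90_000)
        cluster = GeneCluster("c", frozenset(g.gene_id for g in genes[:40]))
        table = distance_sweep(peaks, genes, [cluster], DEFAULT_DISTANCES, SIZES)
        assert (table.n.diff().dropna() >= 0).all()
        assert (table.k.diff().dropna() >= 0).all()

    def test_nested_capture_sets(self, rng):
        genes = random_genes(rng, 300, max_pos=90_000)
        peaks = random_intervals(rng, 30, max_pos=90_000)
        index = GeneIndex(genes)
        cluster = GeneCluster("c", frozenset(g.gene_id for g in genes[:30]))
        prev = frozenset()
        for d in (100, 1000, 10_000):
            cur = enrich_at_distance(peaks, index, cluster, d, SIZES).captured_ids
            assert prev <= cur
            prev = cur

    def test_empty_peak_list_gives_null_rows(self):
        genes, sizes, _ = toy_universe()
        cluster = GeneCluster("up", frozenset({"g00"}))
        table = distance_sweep([], genes, [cluster], (100, 1000), sizes)
        assert (table.n == 0).all() and (table.k == 0).all() and (table.p_upper == 1.0).all()

    def test_distances_must_be_strictly_increasing(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("up", frozenset({"g00"}))
        with pytest.raises(ValueError, match="strictly increasing"):
            distance_sweep(peaks, genes, [cluster], (1000, 1000), sizes)

    def test_identical_inputs_give_identical_tables(self, rng):
        genes = random_genes(rng, 200, max_pos=90_000)
        peaks = random_intervals(rng, 20, max_pos=90_000)
        cluster = GeneCluster("c", frozenset(g.gene_id for g in genes[:20]))
        t1 = distance_sweep(peaks, genes, [cluster], DEFAULT_DISTANCES, SIZES)
        t2 = distance_sweep(peaks, genes, [cluster], DEFAULT_DISTANCES, SIZES)
        assert t1.equals(t2)

    def test_report_columns_and_bonferroni(self):
        genes, sizes, peaks = toy_universe()
        cluster = GeneCluster("up", frozenset({"g05"}))
        table = distance_sweep(peaks, genes, [cluster], (100, 3500), sizes)
        assert list(table.columns)[:11] == [
            "cluster", "distance_bp", "N", "K", "n", "k", "p_upper",
            "neg_log10_p", "fold", "prop_cluster", "prop_universe",
        ]
        assert (table.p_bonferroni >= table.p_upper).all()
        assert (table.p_bonferroni <= 1.0).all()
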