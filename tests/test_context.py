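"""Per-locus context: categories, nearest genes, distances, sequences."""

import numpy as np
import pytest

from conftest import random_genes
from genomecontext import (
    Category,
    ElementTrack,
    GeneModel,
    Locus,
    annotate_loci,
    categorize,
    distance_histogram,
    extract_sequences,
    flatten_categories,
    nearest_gene_context,
    overlap_elements,
    summarize,
    tss_in_window,
)


class TestCategorize:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1090, 1110, Category.EXON),       # midpoint 1100 in G1 exon 1
            (2290, 2310, Category.THREE_FAR),  # midpoint 2300, 300 bp past G1 TES
            (6990, 7010, Category.DISTANT),
        ],
    )
    def test_midpoint_category(self, toy_map, start, end, expected):
        assert categorize(Locus("chr1", start, end), toy_map) is expected

    def test_unknown_chromosome_reported_distant(self, toy_map, caplog):
        with caplog.at_level("WARNING"):
            cat = categorize(Locus("chrUn", 0, 100), toy_map)
        assert cat is Category.DISTANT
        assert any("absent" in r.message for r in caplog.records)


class TestNearestGene:
    def test_inside_forward_gene(self, toy_genes, toy_map):
        ctx = nearest_gene_context(Locus("chr1", 1490, 1510), toy_genes, toy_map)
        assert ctx.nearest_gene_id == "G1"
        assert ctx.dist_to_5prime == 500
        assert ctx.dist_to_3prime == -500
        assert ctx.nearest_gene_strand == "+"

    def test_inside_reverse_gene_strand_aware(self, toy_genes, toy_map):
        ctx = nearest_gene_context(Locus("chr1", 4490, 4510), toy_genes, toy_map)
        assert ctx.nearest_gene_id == "G2"
        assert ctx.dist_to_5prime == 500
        assert ctx.dist_to_3prime == -500

    def test_equidistant_tie_breaks_to_smaller_start(self, toy_genes, toy_map):
        # midpoint 3000 is 1000 bp from both G1 ([1000,2000)) and G2 ([4000,5000))
        ctx = nearest_gene_context(Locus("chr1", 2990, 3010), toy_genes, toy_map)
        assert ctx.nearest_gene_id == "G1"

    def test_no_genes_anywhere_gives_none_fields(self, toy_map):
        ctx = nearest_gene_context(Locus("chr1", 100, 200), [], toy_map)
        assert ctx.nearest_gene_id is None
        assert ctx.dist_to_5prime is None and ctx.dist_to_3prime is None

    def test_distance_difference_equals_span_length(self, synth_setup):
        _, genes, cmap = synth_setup
        rng = np.random.default_rng(5)
        by_id = {g.gene_id: g for g in genes}
        loci = [
            Locus("chr1", int(p), int(p) + 50)
            for p in rng.integers(0, 999_900, size=200)
        ]
        for ctx in annotate_loci(loci, genes, cmap):
            gene = by_id[ctx.nearest_gene_id]
            assert abs(ctx.dist_to_5prime - ctx.dist_to_3prime) == gene.span_length
            if gene.start <= ctx.midpoint < gene.end:
                assert ctx.dist_to_5prime >= 0 >= ctx.dist_to_3prime

    def test_mirror_symmetry_of_categories_and_distances(self):
        """Reflecting annotation and loci through the chromosome leaves every
        category and signed distance unchanged."""
        rng = np.random.default_rng(9)
        L = 200_000
        genes = random_genes(rng, n_chroms=1, chrom_length=L, n_genes=10)
        flip = {"+": "-", "-": "+"}
        mirrored = [
            GeneModel(
                g.gene_id, g.chrom, L - g.end, L - g.start, flip[g.strand],
                [(L - e, L - s) for s, e in reversed(g.exons)],
            )
            for g in genes
        ]
        near, far = 700, 3_000
        cmap = flatten_categories(genes, near, far, {"chr1": L})
        cmap_m = flatten_categories(mirrored, near, far, {"chr1": L})
        starts = rng.integers(0, L - 100, size=300)
        loci = [Locus("chr1", int(s), int(s) + 100) for s in starts]  # even length
        loci_m = [Locus("chr1", L - l.end, L - l.start) for l in loci]

        def span_dist(m, g):
            return max(g.start - m, m - g.end, 0)

        for locus, ctx, ctx_m in zip(
            loci, annotate_loci(loci, genes, cmap), annotate_loci(loci_m, mirrored, cmap_m)
        ):
            assert ctx.category is ctx_m.category
            # signed distances are only comparable when the nearest gene is
            # unique; exact distance ties resolve to different genes after
            # reflection by the deterministic smallest-start tie-break
            dists = sorted(span_dist(locus.midpoint, g) for g in genes)
            if len(dists) > 1 and dists[0] == dists[1]:
                continue
            assert ctx.dist_to_5prime == ctx_m.dist_to_5prime
            assert ctx.dist_to_3prime == ctx_m.dist_to_3prime


class TestSummaries:
    def test_summarize_counts_and_total(self, toy_genes, toy_map):
        loci = [
            Locus("chr1", 1090, 1110),  # exon
            Locus("chr1", 1890, 1910),  # exon
            Locus("chr1", 1490, 1510),  # intron
            Locus("chr1", 6990, 7010),  # distant
        ]
        dist = summarize(annotate_loci(loci, toy_genes, toy_map), label="toy")
        assert dist.counts[Category.EXON] == 2
        assert dist.counts[Category.INTRON] == 1
        assert dist.counts[Category.DISTANT] == 1
        assert dist.total == 4 == sum(dist.counts.values())

    def test_summarize_empty(self):
        dist = summarize([])
        assert dist.total == 0 and all(v == 0 for v in dist.counts.values())

    def test_histogram_bins_are_half_open(self, toy_genes, toy_map):
        ctx = annotate_loci([Locus("chr1", 1490, 1510)], toy_genes, toy_map)
        hist = distance_histogram(ctx, "5prime", bin_width=500, hist_range=(-1000, 1000))
        assert hist.bin_edges == [-1000, -500, 0, 500, 1000]
        assert hist.counts == [0, 0, 0, 1]  # +500 falls in [500, 1000)
        assert hist.n_out_of_range == 0

    def test_histogram_value_at_upper_bound_is_out_of_range(self, toy_genes, toy_map):
        ctx = annotate_loci([Locus("chr1", 1490, 1510)], toy_genes, toy_map)
        hist = distance_histogram(ctx, "5prime", bin_width=250, hist_range=(0, 500))
        assert sum(hist.counts) == 0
        assert hist.n_out_of_range == 1

    def test_histogram_conservation(self, synth_setup):
        _, genes, cmap = synth_setup
        rng = np.random.default_rng(3)
        loci = [
            Locus("chr2", int(p), int(p) + 50)
            for p in rng.integers(0, 999_900, size=300)
        ]
        contexts = annotate_loci(loci, genes, cmap)
        hist = distance_histogram(contexts, "3prime", 2_000, (-20_000, 20_000))
        with_gene = sum(1 for c in contexts if c.dist_to_3prime is not None)
        assert sum(hist.counts) + hist.n_out_of_range == with_gene

    def test_histogram_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            distance_histogram([], "5prime", 0, (-10, 10))
        with pytest.raises(ValueError):
            distance_histogram([], "5prime", 10, (10, -10))
        with pytest.raises(ValueError):
            distance_histogram([], "middle", 10, (-10, 10))


class TestTssWindow:
    @pytest.mark.parametrize(
        "mid,window,expected",
        [(1500, 1000, 1), (7000, 1000, 0), (3000, 2000, 2)],
    )
    def test_counts_tss_in_inclusive_window(self, toy_genes, mid, window, expected):
        locus = Locus("chr1", mid - 10, mid + 10)
        assert tss_in_window(locus, toy_genes, window) == expected

    def test_negative_window_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            tss_in_window(Locus("chr1", 0, 10), toy_genes, -1)


class TestSequences:
    @pytest.fixture
    def ref(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1\nACGTACGT\n")
        return p

    def test_forward_reverse_and_full_length(self, ref):
        loci = [
            Locus("chr1", 0, 4),
            Locus("chr1", 1, 5, strand="-"),
            Locus("chr1", 0, 8),
        ]
        seqs = [s for _, s in extract_sequences(loci, ref)]
        assert seqs == ["ACGT", "TACG", "ACGTACGT"]

    def test_missing_chromosome_and_overrun(self, ref):
        with pytest.raises(KeyError):
            extract_sequences([Locus("chr9", 0, 4)], ref)
        with pytest.raises(ValueError):
            extract_sequences([Locus("chr1", 0, 9)], ref)


class TestElementOverlap:
    def test_half_open_intersection(self):
        track = ElementTrack("CpG", {"chr1": [(150, 300)]})
        assert overlap_elements(Locus("chr1", 100, 200), [track]) == {"CpG": True}
        track2 = ElementTrack("CpG", {"chr1": [(200, 300)]})
        assert overlap_elements(Locus("chr1", 100, 200), [track2]) == {"CpG": False}
        empty = ElementTrack("EST", {})
        assert overlap_elements(Locus("chr1", 100, 200), [empty]) == {"EST": False}

    def test_flags_attached_to_context(self, toy_genes, toy_map):
        track = ElementTrack("CpG", {"chr1": [(1000, 1200)]})
        (ctx,) = annotate_loci(
            [Locus("chr1", 1090, 1110)], toy_genes, toy_map, tracks=[track]
        )
        assert ctx.element_flags == {"CpG": True}
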