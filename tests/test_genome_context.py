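"""Gene annotation parsing, context interval derivation, and locus association."""

import numpy as np
import pytest

from epimodules.genome_context import (
    ContextDefinition,
    GeneModel,
    ParseError,
    associate_loci,
    derive_intervals,
    load_gene_bed,
    load_score_track,
)

from conftest import make_loci


class TestLoadGeneBed:
    def test_field_mapping(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t1000\t5000\tGENEA\t0\t+\n")
        (gene,) = load_gene_bed(str(bed))
        assert gene == GeneModel("GENEA", "chr1", 1000, 5000, "+")

    def test_inverted_coordinates_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t5000\t1000\tGENEB\n")
        with pytest.raises(ParseError, match="start >= end"):
            load_gene_bed(str(bed))

    def test_strands_preserved_and_defaulted(self, tmp_path, caplog):
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "# comment\n"
            "chr1\t100\t200\tG1\t0\t+\n"
            "chr1\t300\t400\tG2\t0\t-\n"
            "chr2\t100\t200\tG3\n"
        )
        with caplog.at_level("WARNING"):
            genes = load_gene_bed(str(bed))
        assert [g.strand for g in genes] == ["+", "-", "+"]
        assert "defaulted" in caplog.text

    def test_duplicate_gene_id_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tG1\nchr1\t300\t400\tG1\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_gene_bed(str(bed))


class TestLoadScoreTrack:
    def test_one_based_shift(self, tmp_path):
        tsv = tmp_path / "track.tsv"
        tsv.write_text("chrom\tposition\teffect\tpvalue\nchr1\t100\t0.5\t0.01\n")
        (l0,) = load_score_track(str(tsv), "meth", one_based=False)
        (l1,) = load_score_track(str(tsv), "meth", one_based=True)
        assert l0.position == 100
        assert l1.position == 99

    def test_bad_p_rejected(self, tmp_path):
        tsv = tmp_path / "track.tsv"
        tsv.write_text("chrom\tposition\teffect\tpvalue\nchr1\t100\t0.5\t1.5\n")
        with pytest.raises(ParseError):
            load_score_track(str(tsv), "meth")


class TestDeriveIntervals:
    def test_promoter_truncated_at_zero(self, promoter_ctx):
        gene = GeneModel("GENEA", "chr1", 1000, 5000, "+")
        # window 1000 upstream of TSS=1000 would start at 0 exactly; push further
        ctx = ContextDefinition("promoter", "meth", ("promoter_window", 2000, 500))
        (iv,) = derive_intervals([gene], ctx)
        assert (iv.start, iv.end) == (0, 1500)

    def test_promoter_minus_strand(self):
        gene = GeneModel("GENEC", "chr1", 2000, 7000, "-")
        ctx = ContextDefinition("promoter", "meth", ("promoter_window", 1000, 500))
        (iv,) = derive_intervals([gene], ctx)
        # TSS = 7000; upstream extends to larger coordinates on '-'
        assert (iv.start, iv.end) == (6500, 8000)

    def test_gene_body(self, simple_genes, body_ctx):
        ivs = derive_intervals(simple_genes, body_ctx)
        assert [(iv.start, iv.end) for iv in ivs] == [(1000, 5000), (20000, 26000), (40000, 45000)]

    def test_custom_bed_nearest_tss(self, tmp_path):
        peaks = tmp_path / "peaks.bed"
        peaks.write_text("chr1\t900\t950\tpk1\n")
        genes = [
            GeneModel("NEAR", "chr1", 1000, 2000, "+"),
            GeneModel("FAR", "chr1", 40000, 41000, "+"),
        ]
        ctx = ContextDefinition("enh", "meth", ("custom_bed", str(peaks), 0))
        ivs = derive_intervals(genes, ctx, max_link_distance=10_000)
        assert len(ivs) == 1 and ivs[0].gene_id == "NEAR"

    def test_custom_bed_beyond_max_distance_dropped(self, tmp_path):
        peaks = tmp_path / "peaks.bed"
        peaks.write_text("chr1\t900\t950\tpk1\n")
        genes = [GeneModel("FAR", "chr1", 400000, 401000, "+")]
        ctx = ContextDefinition("enh", "meth", ("custom_bed", str(peaks), 0))
        assert derive_intervals(genes, ctx, max_link_distance=10_000) == []

    def test_strand_symmetry(self):
        """Reflecting all coordinates and flipping strands mirrors the intervals."""
        length = 100_000
        plus = GeneModel("G", "chr1", 10_000, 15_000, "+")
        minus = GeneModel("G", "chr1", length - 15_000, length - 10_000, "-")
        ctx = ContextDefinition("promoter", "meth", ("promoter_window", 1000, 500))
        (iv_p,) = derive_intervals([plus], ctx)
        (iv_m,) = derive_intervals([minus], ctx)
        assert (iv_m.start, iv_m.end) == (length - iv_p.end, length - iv_p.start)


class TestAssociateLoci:
    def test_half_open_boundary(self, body_ctx):
        gene = GeneModel("G", "chr1", 0, 1500, "+")
        ctx = ContextDefinition("body", "meth", ("gene_body",))
        (iv,) = derive_intervals([gene], ctx)
        loci = make_loci([100, 1499, 1500], [0.5, 0.5, 0.5])
        (assoc,) = associate_loci([iv], loci, ctx)
        assert assoc.n == 2
        assert [l.position for l in assoc.loci] == [100, 1499]

    def test_tss_distance_decay_weights(self):
        gene = GeneModel("G", "chr1", 1000, 9000, "+")
        ctx = ContextDefinition(
            "body", "meth", ("gene_body",), locus_weighting=("tss_distance_decay", 1000)
        )
        (iv,) = derive_intervals([gene], ctx)
        loci = make_loci([1000, 2000], [0.5, 0.5])  # at TSS, and TSS + 1000
        (assoc,) = associate_loci([iv], loci, ctx)
        assert assoc.locus_weights == pytest.approx([1.0, 0.5])

    def test_empty_interval_retained_and_flagged(self, simple_genes, body_ctx):
        assocs = associate_loci(derive_intervals(simple_genes, body_ctx), [], body_ctx)
        assert len(assocs) == 3
        assert all(a.missing_data and a.n == 0 for a in assocs)

    def test_matches_brute_force_overlap_scan(self, rng, body_ctx):
        """Binary-search association equals the naive all-pairs overlap scan."""
        genes = [
            GeneModel(f"G{i}", "chr1", s, s + 3000, "+")
            for i, s in enumerate(range(0, 100_000, 10_000))
        ]
        positions = sorted(int(p) for p in rng.integers(0, 110_000, size=500))
        loci = make_loci(positions, [0.5] * 500)
        ctx = body_ctx
        assocs = associate_loci(derive_intervals(genes, ctx), loci, ctx)

        by_gene = {a.gene_id: {l.position for l in a.loci} for a in assocs}
        for g in genes:
            expected = {p for p in positions if g.start <= p < g.end}
            assert by_gene[g.gene_id] == expected
        # disjoint intervals: every locus lands in at most one gene's body
        total = sum(len(v) for v in by_gene.values())
        assert total == len({p for p in positions if any(g.start <= p < g.end for g in genes)})
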