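import itertools

import pytest
from hypothesis import given, settings, strategies as st

from adipomir import genomic_context as gc
from adipomir.io_formats import GenomicInterval

from conftest import make_gene, make_mirna


# ---------------------------------------------------------------------------
# Brute-force oracle for the cluster rule: transitive closure of the
# pairwise "same chromosome & strand, separation < max_gap" relation.
# ---------------------------------------------------------------------------

def bruteforce_clusters(mirnas, max_gap=10_000):
    def close(a, b):
        la, lb = a.locus, b.locus
        if la.chrom != lb.chrom or la.strand != lb.strand:
            return False
        sep = max(la.start, lb.start) - min(la.end, lb.end)
        return sep < max_gap  # overlap gives negative separation

    parent = {g.gene_id: g.gene_id for g in mirnas}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(mirnas, 2):
        if close(a, b):
            parent[find(a.gene_id)] = find(b.gene_id)
    groups = {}
    for g in mirnas:
        groups.setdefault(find(g.gene_id), []).append(g.gene_id)
    return sorted(sorted(v) for v in groups.values() if len(v) >= 2)


def found_clusters(mirnas, max_gap=10_000):
    return sorted(sorted(c.gene_ids) for c in gc.detect_clusters(mirnas, max_gap))


# ---------------------------------------------------------------------------

class TestDeriveIntrons:
    def test_gap_between_exons(self, two_exon_gene):
        (_, introns), = gc.derive_introns(two_exon_gene)
        assert [(i.start, i.end) for i in introns] == [(1200, 1500)]

    def test_single_exon_has_no_introns(self):
        gene = make_gene("G", "chr1", [(100, 400)])
        (_, introns), = gc.derive_introns(gene)
        assert introns == []

    def test_exons_and_introns_tile_the_transcript_span(self):
        gene = make_gene("G", "chr1", [(100, 200), (300, 500), (900, 1000)])
        (_, introns), = gc.derive_introns(gene)
        pieces = sorted(gene.transcripts[0][1] + introns,
                        key=lambda iv: iv.start)
        assert pieces[0].start == 100 and pieces[-1].end == 1000
        for a, b in zip(pieces, pieces[1:]):
            assert a.end == b.start
        assert len(introns) == 2


class TestClassifyLocation:
    def test_precursor_inside_intron_is_intronic(self, two_exon_gene):
        m = make_mirna("M", "chr1", 1250, 1330)
        ann = gc.classify_location(m, [two_exon_gene])
        assert ann.location_class == "intronic"
        assert ann.host_gene_ids == ["G1"]
        assert ann.host_orientation["G1"] == "sense"

    def test_exon_overlap_is_exonic(self, two_exon_gene):
        # mirrors a miRNA overlapping a coding exon of its host
        m = make_mirna("M", "chr1", 1190, 1270)  # 10 bp into exon 1
        ann = gc.classify_location(m, [two_exon_gene])
        assert ann.location_class == "exonic"

    def test_exact_intron_bounds_is_mirtron(self, two_exon_gene):
        m = make_mirna("M", "chr1", 1200, 1500)
        assert gc.classify_location(m, [two_exon_gene]).location_class == "mirtron"

    def test_mirtron_tolerance_admits_jittered_bounds(self, two_exon_gene):
        m = make_mirna("M", "chr1", 1202, 1498)
        assert gc.classify_location(m, [two_exon_gene]).location_class == "intronic"
        assert gc.classify_location(
            m, [two_exon_gene], mirtron_tolerance=2).location_class == "mirtron"

    def test_no_gene_overlap_is_intergenic(self, two_exon_gene):
        m = make_mirna("M", "chr1", 5000, 5080)
        ann = gc.classify_location(m, [two_exon_gene])
        assert ann.location_class == "intergenic"
        assert ann.host_gene_ids == []

    def test_two_overlapping_host_genes_both_listed(self):
        # mirrors one miRNA inside introns of two pantothenate-kinase genes
        g1 = make_gene("PANK2", "chr1", [(1000, 1200), (1500, 1800)])
        g2 = make_gene("PANK3", "chr1", [(900, 1150), (1600, 1900)], strand="-")
        m = make_mirna("M103", "chr1", 1250, 1330)
        ann = gc.classify_location(m, [g1, g2])
        assert ann.location_class == "intronic"
        assert ann.host_gene_ids == ["PANK2", "PANK3"]
        assert ann.host_orientation == {"PANK2": "sense", "PANK3": "antisense"}

    def test_exonic_precedence_across_transcripts(self):
        # intronic in transcript 1 but overlapping an exon of transcript 2
        g = make_gene("G", "chr1", [(1000, 1200), (1500, 1800)])
        extra_exon = GenomicInterval("chr1", 1240, 1340, "+")
        g.transcripts.append(("G.t2", [g.transcripts[0][1][0], extra_exon]))
        m = make_mirna("M", "chr1", 1250, 1330)
        assert gc.classify_location(m, [g]).location_class == "exonic"

    def test_unknown_chromosome_flagged_intergenic(self, two_exon_gene, caplog):
        m = make_mirna("M", "chrZ", 100, 180)
        with caplog.at_level("WARNING"):
            ann = gc.classify_location(m, [two_exon_gene])
        assert ann.location_class == "intergenic" and ann.unplaced

    def test_every_gene_gets_exactly_one_class(self, annotation_sim):
        anns = [gc.classify_location(m, annotation_sim.gene_models)
                for m in annotation_sim.mirna_genes]
        assert all(a.location_class in gc.LOCATION_CLASSES for a in anns)
        assert len(anns) == len(annotation_sim.mirna_genes)


class TestDetectClusters:
    def test_two_genes_within_gap_cluster(self):
        a = make_mirna("A", "chr1", 1000, 1080)
        b = make_mirna("B", "chr1", 6080, 6160)  # gap 5000
        assert found_clusters([a, b]) == [["A", "B"]]

    def test_opposite_strands_never_cluster(self):
        a = make_mirna("A", "chr1", 1000, 1080, "+")
        b = make_mirna("B", "chr1", 6080, 6160, "-")
        assert found_clusters([a, b]) == []

    def test_chain_of_three_is_one_cluster(self):
        # A–B and B–C within 8 kb, A–C 16 kb apart: single-linkage chains all
        a = make_mirna("A", "chr1", 0, 80)
        b = make_mirna("B", "chr1", 8080, 8160)
        c = make_mirna("C", "chr1", 16160, 16240)
        assert found_clusters([a, b, c]) == [["A", "B", "C"]]
        assert bruteforce_clusters([a, b, c]) == [["A", "B", "C"]]

    def test_gap_exactly_10kb_excluded(self):
        a = make_mirna("A", "chr1", 0, 80)
        b = make_mirna("B", "chr1", 10_080, 10_160)  # gap == 10,000
        assert found_clusters([a, b]) == []
        c = make_mirna("C", "chr1", 10_079, 10_159)  # gap 9,999
        assert found_clusters([a, c]) == [["A", "C"]]

    def test_overlapping_precursors_cluster(self):
        a = make_mirna("A", "chr1", 1000, 1080)
        b = make_mirna("B", "chr1", 1040, 1120)
        assert found_clusters([a, b]) == [["A", "B"]]

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_transitive_closure(self, data):
        n = data.draw(st.integers(2, 40))
        mirnas = []
        for i in range(n):
            chrom = data.draw(st.sampled_from(["chr1", "chr2"]))
            strand = data.draw(st.sampled_from("+-"))
            start = data.draw(st.integers(0, 60_000))
            length = data.draw(st.integers(60, 2000))
            mirnas.append(make_mirna(f"g{i}", chrom, start, start + length,
                                     strand))
        assert found_clusters(mirnas) == bruteforce_clusters(mirnas)

    @given(st.permutations(range(6)))
    @settings(max_examples=20, deadline=None)
    def test_membership_invariant_under_input_order(self, order):
        base = [make_mirna(f"g{i}", "chr1", i * 4000, i * 4000 + 80)
                for i in range(6)]
        shuffled = [base[i] for i in order]
        assert found_clusters(shuffled) == found_clusters(base)

    @given(st.integers(1000, 30_000), st.integers(0, 20_000))
    @settings(max_examples=40, deadline=None)
    def test_wider_gap_never_shrinks_clusters(self, gap1, extra):
        mirnas = [make_mirna(f"g{i}", "chr1", i * 3000, i * 3000 + 100)
                  for i in range(8)]
        small = gc.detect_clusters(mirnas, max_gap=gap1)
        large = gc.detect_clusters(mirnas, max_gap=gap1 + extra)
        small_sets = sorted(sorted(c.gene_ids) for c in small)
        large_member = {g for c in large for g in c.gene_ids}
        for members in small_sets:
            assert set(members) <= large_member


class TestMatureContext:
    def test_single_intronic_locus(self):
        from adipomir.io_formats import MatureMiRNA
        ann = gc.ContextAnnotation("G1", "intronic", ["H"], {"H": "sense"})
        mat = MatureMiRNA("m1", "miR-1", gene_ids=["G1"])
        (ctx,) = gc.mature_context([mat], [ann])
        assert ctx.location_classes == frozenset({"intronic"})
        assert not ctx.clustered

    def test_clustered_if_any_locus_clustered(self):
        from adipomir.io_formats import MatureMiRNA
        a1 = gc.ContextAnnotation("G1", "intergenic", cluster_id="cluster_001")
        a2 = gc.ContextAnnotation("G2", "intergenic")
        mat = MatureMiRNA("let-7a", "let-7a", gene_ids=["G1", "G2"])
        (ctx,) = gc.mature_context([mat], [a1, a2])
        assert ctx.clustered

    def test_multi_locus_reports_all_classes(self):
        # mirrors a mature coded intronic on one chromosome, intergenic
        # on another
        from adipomir.io_formats import MatureMiRNA
        a1 = gc.ContextAnnotation("G7", "intronic", ["PPARGC1B"],
                                  {"PPARGC1B": "sense"})
        a2 = gc.ContextAnnotation("G4", "intergenic")
        mat = MatureMiRNA("miR-378", "miR-378", gene_ids=["G4", "G7"])
        (ctx,) = gc.mature_context([mat], [a1, a2])
        assert ctx.location_classes == frozenset({"intronic", "intergenic"})

    def test_dangling_gene_id_raises(self):
        from adipomir.io_formats import MatureMiRNA
        mat = MatureMiRNA("m", "miR-x", gene_ids=["GHOST"])
        with pytest.raises(KeyError, match="GHOST"):
            gc.mature_context([mat], [])


class TestLocationTally:
    def test_per_gene_and_per_mature_denominators(self, annotation_sim):
        anns, clusters = gc.annotate_all(annotation_sim.mirna_genes,
                                         annotation_sim.gene_models)
        mats = gc.mature_context(annotation_sim.matures, anns)
        tally = gc.location_tally(anns, mats)
        assert tally["n_genes"].sum() == len(anns)
        assert tally["pct_genes"].sum() == pytest.approx(100.0)
        # per-mature counts can exceed per-gene percentages' denominator
        # logic: a dual-locus mature is counted in every class it occupies
        assert tally["n_matures"].sum() >= len(mats)
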