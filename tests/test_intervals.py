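"""Coordinate core: GFF3 parsing, TSS distances, annotation, interval algebra."""

import numpy as np
import pytest

from ocrlandscape.intervals import (CATEGORIES, AnnotatedOCR, GeneModel,
                                    GenomicInterval, ParseError, annotate_ocr,
                                    annotate_ocrs, classify_locality,
                                    distance_histogram, overlap_pairs,
                                    parse_gff3, tss_distance)

GFF = """##gff-version 3
chr1\t.\tgene\t101\t200\t.\t+\t.\tID=gA
chr1\t.\tgene\t1001\t2000\t.\t-\t.\tID=gB
chr1\t.\tmRNA\t1001\t2000\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\t.\texon\t1001\t1400\t.\t-\t.\tParent=gB.t1
chr1\t.\texon\t1601\t2000\t.\t-\t.\tParent=gB.t1
chr2\t.\tgene\t501\t900\t.\t+\t.\tID=gC
"""


def _gene(chrom, start, end, strand, gid="g"):
    return GeneModel(GenomicInterval(chrom, start, end, strand, gid))


class TestParseGff3:
    def test_coordinate_conversion_and_tss(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF)
        models = parse_gff3(p)
        assert [m.id for m in models] == ["gA", "gB", "gC"]
        gA, gB, gC = models
        # 1-based closed -> 0-based half-open
        assert (gA.interval.start, gA.interval.end) == (100, 200)
        assert gA.tss == 100 and gA.tes == 199
        assert gB.tss == 1999 and gB.tes == 1000  # minus strand: TSS at the right
        assert [(e.start, e.end) for e in gB.exons] == [(1000, 1400), (1600, 2000)]
        assert [(i.start, i.end) for i in gB.introns()] == [(1400, 1600)]
        assert gC.interval.chrom == "chr2"

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\nchr1\tgene\tbroken\n")
        with pytest.raises(ParseError, match=":2:"):
            parse_gff3(p)

    def test_exon_outside_gene_rejected(self, tmp_path):
        p = tmp_path / "bad2.gff3"
        p.write_text(
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\t.\texon\t101\t300\t.\t+\t.\tParent=t1\n")
        with pytest.raises(ValueError, match="outside"):
            parse_gff3(p)


class TestTssDistance:
    @pytest.mark.parametrize("span,expected", [
        ((500, 700), -300),    # upstream of a + TSS
        ((1000, 1100), 0),     # overlaps the TSS base
        ((1200, 1300), 200),   # downstream, positive
    ])
    def test_plus_strand(self, span, expected):
        g = _gene("chr1", 1000, 3000, "+")
        assert tss_distance(GenomicInterval("chr1", *span), g) == expected

    def test_minus_strand_upstream(self):
        # gene on -, TSS base 1000: an OCR at higher coordinates is upstream
        g = _gene("chr1", 200, 1001, "-")
        assert g.tss == 1000
        assert tss_distance(GenomicInterval("chr1", 1200, 1300), g) == -199

    def test_strand_flip_symmetry(self):
        rng = np.random.default_rng(0)
        L = 100_000
        for _ in range(200):
            s = int(rng.integers(0, L - 500))
            e = s + int(rng.integers(1, 400))
            gs = int(rng.integers(0, L - 3000))
            ge = gs + int(rng.integers(100, 2500))
            g_plus = _gene("chr1", gs, ge, "+")
            ocr = GenomicInterval("chr1", s, e)
            # reflect everything about the origin of a length-L chromosome
            g_minus = _gene("chr1", L - ge, L - gs, "-")
            ocr_r = GenomicInterval("chr1", L - e, L - s)
            assert tss_distance(ocr, g_plus) == tss_distance(ocr_r, g_minus)

    def test_cross_chromosome_rejected(self):
        g = _gene("chr2", 0, 100, "+")
        with pytest.raises(ValueError):
            tss_distance(GenomicInterval("chr1", 0, 10), g)


def _structured_gene():
    g = GeneModel(
        GenomicInterval("chr1", 10_000, 12_000, "+", "gX"),
        exons=[GenomicInterval("chr1", 10_000, 10_400),
               GenomicInterval("chr1", 10_800, 11_200),
               GenomicInterval("chr1", 11_600, 12_000)],
        five_utr=[GenomicInterval("chr1", 10_000, 10_150)],
        three_utr=[GenomicInterval("chr1", 11_800, 12_000)],
    )
    return g


class TestAnnotate:
    def test_promoter_window(self):
        a = annotate_ocr(GenomicInterval("chr1", 8500, 8700), [_structured_gene()])
        assert a.category == "promoter" and a.locality == "pOCR"

    def test_exon_far_from_tss(self):
        a = annotate_ocr(GenomicInterval("chr1", 10_850, 11_100), [_structured_gene()])
        assert a.category == "exon" and a.locality == "genic"

    def test_priority_five_utr_over_exon(self):
        a = annotate_ocr(GenomicInterval("chr1", 10_050, 10_120), [_structured_gene()])
        assert a.category == "five_utr"

    def test_three_utr_and_intron_and_downstream(self):
        g = _structured_gene()
        assert annotate_ocr(GenomicInterval("chr1", 11_850, 11_950), [g]).category == "three_utr"
        assert annotate_ocr(GenomicInterval("chr1", 10_500, 10_700), [g]).category == "intron"
        assert annotate_ocr(GenomicInterval("chr1", 12_300, 12_500), [g]).category == "downstream"

    def test_distal_upstream_is_docr(self):
        a = annotate_ocr(GenomicInterval("chr1", 6800, 7000), [_structured_gene()])
        assert a.category == "distal_intergenic"
        assert a.tss_distance == -3000 and a.locality == "dOCR"

    def test_empty_gene_set(self):
        a = annotate_ocr(GenomicInterval("chr1", 0, 100), [])
        assert a.category == "distal_intergenic"
        assert a.nearest_gene is None and a.tss_distance is None

    def test_category_partition(self, annotations):
        counts = {c: 0 for c in CATEGORIES}
        for a in annotations:
            counts[a.category] += 1
        assert sum(counts.values()) == len(annotations)

    def test_planted_category_recovery(self, annotations, bundle):
        planted = bundle.truth["ocrs"]
        match = sum(a.category == planted[a.id]["category"] for a in annotations)
        assert match >= 0.99 * len(annotations)

    def test_strand_equivariance_of_annotation(self):
        # mirror a small locus; categories and |tss_distance| must not change
        g = _structured_gene()
        ocrs = [GenomicInterval("chr1", s, e) for s, e in
                [(8500, 8700), (10_850, 11_100), (6800, 7000), (12_300, 12_500)]]
        fwd = annotate_ocrs(ocrs, [g])
        L = 50_000
        g_r = GeneModel(
            GenomicInterval("chr1", L - 12_000, L - 10_000, "-", "gX"),
            exons=[GenomicInterval("chr1", L - e.end, L - e.start) for e in g.exons],
            five_utr=[GenomicInterval("chr1", L - u.end, L - u.start) for u in g.five_utr],
            three_utr=[GenomicInterval("chr1", L - u.end, L - u.start) for u in g.three_utr],
        )
        rev = annotate_ocrs([GenomicInterval("chr1", L - o.end, L - o.start)
                             for o in ocrs], [g_r])
        for a, b in zip(fwd, rev):
            assert a.category == b.category
            assert abs(a.tss_distance) == abs(b.tss_distance)


class TestLocality:
    @pytest.mark.parametrize("cat,dist,expected", [
        ("distal_intergenic", -2500, "dOCR"),
        ("promoter", -1500, "pOCR"),
        ("intron", 300, "genic"),
        ("distal_intergenic", -1500, "genic"),
    ])
    def test_rules(self, cat, dist, expected):
        assert classify_locality(cat, dist) == expected


class TestDistanceHistogram:
    def _docr(self, d):
        return AnnotatedOCR(GenomicInterval("chr1", 0, 100), "distal_intergenic",
                            "g", -d, "dOCR")

    def test_hand_counts(self):
        counts, _ = distance_histogram([self._docr(d) for d in (3000, 3500, 5000)],
                                       bin_edges=[2000, 4000, 8000])
        assert counts.tolist() == [2, 1]

    def test_empty(self):
        counts, edges = distance_histogram([], bin_edges=[2000, 4000, 8000])
        assert counts.sum() == 0

    def test_below_first_edge_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([self._docr(1500)], bin_edges=[2000, 4000])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(1)
        dists = rng.integers(2001, 400_000, size=100)
        docrs = [self._docr(int(d)) for d in dists]
        counts, edges = distance_histogram(docrs)
        assert counts.sum() == 100
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            assert c == sum(lo <= d < hi for d in dists)


class TestOverlap:
    def test_simple_overlap(self):
        pairs = overlap_pairs([GenomicInterval("chr1", 0, 10)],
                              [GenomicInterval("chr1", 5, 15)])
        assert pairs == [(0, 0, 5)]

    def test_disjoint(self):
        assert overlap_pairs([GenomicInterval("chr1", 0, 10)],
                             [GenomicInterval("chr1", 20, 30)]) == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(2)

        def rand_set(n):
            out = []
            for i in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 5000))
                out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 300))))
            return out

        a, b = rand_set(200), rand_set(200)
        got = set((i, j) for i, j, _ in overlap_pairs(a, b))
        want = set()
        for i, x in enumerate(a):
            for j, y in enumerate(b):
                if x.overlap_bp(y) >= 1:
                    want.add((i, j))
        assert got == want
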