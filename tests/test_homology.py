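"""Local alignment, E-values, hOCR detection and duplication analyses."""

import math

import numpy as np
import pytest
from Bio import Align

from ocrlandscape.homology import (AlignmentScore, AsymmetricPair, antagonism_classify,
                                   asymmetric_pairs, classify_relation,
                                   classify_relations, evalue, find_hocrs,
                                   pair_expression_test, smith_waterman, sw_score)
from ocrlandscape.intervals import AnnotatedOCR, GeneModel, GenomicInterval
from ocrlandscape.seqs import revcomp
from ocrlandscape.signal import SignalTrack


def reference_aligner():
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


class TestSmithWaterman:
    def test_identity_scores_length(self):
        s, span1, span2 = smith_waterman("ACGTACGT", "ACGTACGT")
        assert s == 8
        assert span1 == (0, 8) and span2 == (0, 8)

    def test_no_positive_window(self):
        assert smith_waterman("AAAA", "CCCC")[0] == 0

    def test_empty_sequence(self):
        assert smith_waterman("", "ACGT")[0] == 0

    def test_n_scores_as_mismatch(self):
        assert smith_waterman("ACGNACG", "ACGTACG")[0] == sw_score("ACGNACG", "ACGTACG")
        assert sw_score("NNNN", "NNNN") == 0

    def test_matches_reference_dp_on_random_pairs(self):
        rng = np.random.default_rng(13)
        al = reference_aligner()
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 51)), int(rng.integers(5, 51))
            a = "".join(rng.choice(list("ACGT"), size=n1))
            b = "".join(rng.choice(list("ACGT"), size=n2))
            want = int(al.score(a, b)) if al.score(a, b) > 0 else 0
            assert smith_waterman(a, b)[0] == want
            assert sw_score(a, b) == want

    def test_traceback_span_scores_consistently(self):
        rng = np.random.default_rng(14)
        core = "".join(rng.choice(list("ACGT"), size=30))
        a = "TTTTT" + core + "GGGGG"
        b = "CCCC" + core + "AAAA"
        s, (s1, e1), (s2, e2) = smith_waterman(a, b)
        assert s >= 30
        assert sw_score(a[s1:e1], b[s2:e2]) == s


class TestEvalue:
    def test_closed_form(self):
        assert evalue(10, 100, 100, K=0.1, lambda_=1.0) == pytest.approx(
            1000 * math.exp(-10), rel=1e-12)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 200, 200) for s in range(0, 50, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_linear_in_search_space(self):
        assert evalue(10, 100, 200) == pytest.approx(2 * evalue(10, 100, 100))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100)
        with pytest.raises(ValueError):
            evalue(-1, 10, 10)

    def test_alignment_score_wrapper(self):
        sc = AlignmentScore(30, 250, 250)
        assert sc.evalue == pytest.approx(evalue(30, 250, 250))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestFindHocrs:
    def _ocrs(self, seqs):
        ivs, out = [], {}
        for i, (chrom, seq) in enumerate(seqs):
            iv = GenomicInterval(chrom, 1000 * i, 1000 * i + len(seq), ".", f"o{i}")
            ivs.append(iv)
            out[iv.name] = seq
        return ivs, out

    def test_planted_duplicate_detected(self):
        rng = np.random.default_rng(15)
        a = _random_seq(rng, 250)
        ivs, seqs = self._ocrs([("chr1", a), ("chr2", _mutate(a, 0.05, rng)),
                                ("chr2", _random_seq(rng, 250))])
        res = find_hocrs(ivs, seqs)
        assert len(res.pairs) == 1
        assert {res.pairs[0].ocr_a, res.pairs[0].ocr_b} == {"o0", "o1"}
        assert res.pairs[0].evalue < 1e-10

    def test_reverse_orientation_duplicate_detected(self):
        rng = np.random.default_rng(16)
        a = _random_seq(rng, 250)
        ivs, seqs = self._ocrs([("chr1", a), ("chr2", revcomp(_mutate(a, 0.05, rng)))])
        res = find_hocrs(ivs, seqs)
        assert len(res.pairs) == 1 and res.pairs[0].strand == "-"

    def test_same_chromosome_duplicate_excluded(self):
        rng = np.random.default_rng(17)
        a = _random_seq(rng, 250)
        ivs, seqs = self._ocrs([("chr1", a), ("chr1", _mutate(a, 0.05, rng))])
        res = find_hocrs(ivs, seqs)
        assert res.pairs == [] and res.fraction == 0.0
        assert len(res.same_chrom_pairs) == 1

    def test_unrelated_sequences_yield_no_pairs(self):
        rng = np.random.default_rng(18)
        ivs, seqs = self._ocrs([("chr1" if i % 2 else "chr2", _random_seq(rng, 200))
                                for i in range(50)])
        res = find_hocrs(ivs, seqs, prefilter=False)
        assert res.pairs == []

    def test_prefilter_equivalent_to_full_search(self):
        rng = np.random.default_rng(19)
        base = [_random_seq(rng, 200) for _ in range(6)]
        entries = [("chr1", s) for s in base]
        entries += [("chr2", _mutate(base[0], 0.05, rng)),
                    ("chr2", _mutate(base[1], 0.1, rng)),
                    ("chr2", _random_seq(rng, 200))]
        ivs, seqs = self._ocrs(entries)
        fast = find_hocrs(ivs, seqs, prefilter=True)
        full = find_hocrs(ivs, seqs, prefilter=False)
        key = lambda r: sorted((p.ocr_a, p.ocr_b, p.score.S) for p in r.pairs)
        assert key(fast) == key(full)
        assert fast.fraction == full.fraction

    def test_evalue_threshold_monotone(self):
        rng = np.random.default_rng(20)
        a = _random_seq(rng, 250)
        entries = [("chr1", a), ("chr2", _mutate(a, 0.05, rng))]
        entries += [("chr2", _random_seq(rng, 250)) for _ in range(10)]
        ivs, seqs = self._ocrs(entries)
        strict = find_hocrs(ivs, seqs, evalue_max=1e-10, prefilter=False)
        loose = find_hocrs(ivs, seqs, evalue_max=1e-3, prefilter=False)
        strict_pairs = {(p.ocr_a, p.ocr_b) for p in strict.pairs}
        loose_pairs = {(p.ocr_a, p.ocr_b) for p in loose.pairs}
        assert strict_pairs <= loose_pairs

    def test_input_order_invariance(self):
        rng = np.random.default_rng(21)
        a = _random_seq(rng, 250)
        b = _random_seq(rng, 250)
        entries = [("chr1", a), ("chr2", _mutate(a, 0.05, rng)),
                   ("chr1", b), ("chr3", _mutate(b, 0.05, rng))]
        ivs, seqs = self._ocrs(entries)
        res1 = find_hocrs(ivs, seqs)
        res2 = find_hocrs(list(reversed(ivs)), seqs)
        assert res1.fraction == res2.fraction
        assert {frozenset((p.ocr_a, p.ocr_b)) for p in res1.pairs} == \
               {frozenset((p.ocr_a, p.ocr_b)) for p in res2.pairs}

    def test_short_ocr_skipped_with_warning(self):
        ivs, seqs = self._ocrs([("chr1", "ACGTA"), ("chr2", "ACGTACGTACGTACGT")])
        with pytest.warns(UserWarning, match="shorter"):
            res = find_hocrs(ivs, seqs)
        assert res.n_ocrs == 1

    def test_planted_fraction_recovered_on_bundle(self, bundle, ocrs):
        """Recovered hOCR fraction within 3 binomial SEs of the planted one."""
        res = find_hocrs(ocrs, str(bundle.paths["genome"]))
        f = bundle.truth["summary"]["hocr_fraction"]
        tol = 3 * np.sqrt(f * (1 - f) / len(ocrs))
        assert abs(res.fraction - f) <= tol
        planted_pairs = {frozenset((oid, rec["partner"]))
                         for oid, rec in bundle.truth["ocrs"].items() if rec["partner"]}
        got = {frozenset((p.ocr_a, p.ocr_b)) for p in res.pairs}
        assert got == planted_pairs


def _ann(name, gene, chrom="chr1", loc="pOCR"):
    return AnnotatedOCR(GenomicInterval(chrom, 0, 100, ".", name),
                        "promoter" if loc == "pOCR" else "distal_intergenic",
                        gene, -500 if loc == "pOCR" else -3000, loc)


class TestRelations:
    def _pair(self, a="oA", b="oB"):
        from ocrlandscape.homology import HomologyPair
        return HomologyPair(a, b, "chr1", "chr3", AlignmentScore(200, 250, 250))

    def test_homolog_genes_give_hgene_relation(self):
        ann = {"oA": _ann("oA", "g1"), "oB": _ann("oB", "g2", "chr3")}
        p = classify_relation(self._pair(), ann, [("g1", "g2")])
        assert p.relation == "hOCR_hGene" and p.locality_conserved

    def test_non_homolog_genes(self):
        ann = {"oA": _ann("oA", "g1"), "oB": _ann("oB", "g9", "chr3", loc="dOCR")}
        p = classify_relation(self._pair(), ann, [("g1", "g2")])
        assert p.relation == "hOCR_nonhGene" and not p.locality_conserved

    def test_missing_nearest_gene_flagged(self):
        ann = {"oA": _ann("oA", "g1"),
               "oB": AnnotatedOCR(GenomicInterval("chr3", 0, 100, ".", "oB"),
                                  "distal_intergenic", None, None, "genic")}
        p = classify_relation(self._pair(), ann, [("g1", "g2")])
        assert p.relation is None

    def test_planted_relation_fractions_on_bundle(self, bundle, ocrs, annotations):
        res = find_hocrs(ocrs, str(bundle.paths["genome"]))
        ann = {a.id: a for a in annotations}
        rel = classify_relations(res.pairs, ann,
                                 [tuple(p) for p in bundle.truth["homolog_pairs"]])
        f = bundle.truth["summary"]["gene_linked_fraction"]
        n = rel["n_classified"]
        tol = 3 * np.sqrt(f * (1 - f) / max(n, 1))
        assert abs(rel["hOCR_hGene"] - f) <= tol


class TestAsymmetricPairs:
    def _genes(self, fpkms):
        out = {}
        for gid, f in fpkms.items():
            g = GeneModel(GenomicInterval("chr1", 0, 500, "+", gid))
            g.fpkm = f
            out[gid] = g
        return out

    def test_hand_classification_of_ten_pairs(self):
        genes = self._genes({f"g{i}": float(i) for i in range(20)})
        # OCRs on even-numbered genes only
        anns = [_ann(f"o{i}", f"g{i}") for i in range(0, 20, 2)]
        pairs = [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(10)]
        asym = asymmetric_pairs(pairs, anns, genes)
        assert len(asym) == 10
        assert all(a.gene_with == f"g{2 * i}" for i, a in enumerate(asym))

    def test_both_or_neither_excluded(self):
        genes = self._genes({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        anns = [_ann("o1", "a"), _ann("o2", "b")]
        assert asymmetric_pairs([("a", "b"), ("c", "d")], anns, genes) == []

    def test_expression_test_exact_case(self):
        pairs = [AsymmetricPair("a1", "b1", 10, 1), AsymmetricPair("a2", "b2", 12, 2),
                 AsymmetricPair("a3", "b3", 14, 3)]
        res, medians = pair_expression_test(pairs, side="greater")
        assert res.p == pytest.approx(0.05, abs=1e-12)
        assert medians == {"with_ocr": 12.0, "without_ocr": 2.0}

    def test_identical_expression_not_significant(self):
        pairs = [AsymmetricPair(f"a{i}", f"b{i}", float(i), float(i))
                 for i in range(5)]
        res, _ = pair_expression_test(pairs)
        assert res.p > 0.05


class TestAntagonism:
    def test_threshold_rules(self):
        genes = {}
        for gid, f in (("gHi", 15.0), ("gLo", 0.0), ("gMid", 4.0), ("gZ", 0.0)):
            g = GeneModel(GenomicInterval("chr1", 5000, 7000, "+", gid))
            g.fpkm = f
            genes[gid] = g
        track = SignalTrack.from_intervals([("chr1", 4000, 8000)], [1.0])
        pairs = [AsymmetricPair("gLo", "gHi", 0.0, 15.0),
                 AsymmetricPair("gZ", "gMid", 0.0, 4.0)]
        recs = antagonism_classify(pairs, track, track, genes)
        by_gene = {r["gene"]: r["class"] for r in recs}
        assert by_gene["gHi"] == "high_expr_no_OCR"   # FPKM > 10, no OCR
        assert by_gene["gLo"] == "silent_with_OCR"    # FPKM = 0, has OCR
        assert by_gene["gMid"] == "other"
        assert all(r["mean_k4"] == pytest.approx(1.0) for r in recs)
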