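"""Histone-mark classification, clustering and class comparisons."""

import itertools

import numpy as np
import pytest

from ocrlandscape.histone import (HISTONE_CLASSES, class_counts, classify_by_marks,
                                  docr_state_by_distance, dual_coverage_compare,
                                  expression_by_class, kmeans2, lincrna_overlap,
                                  row_max_normalize)
from ocrlandscape.intervals import AnnotatedOCR, GeneModel, GenomicInterval, read_bed


def _iv(s, e, name, chrom="chr1"):
    return GenomicInterval(chrom, s, e, ".", name)


class TestClassifyByMarks:
    def test_four_classes(self):
        ocrs = [_iv(0, 100, "a"), _iv(200, 300, "b"), _iv(400, 500, "c"),
                _iv(600, 700, "d")]
        k4 = [_iv(0, 50, "k4a"), _iv(250, 260, "k4b")]
        k27 = [_iv(240, 280, "k27a"), _iv(450, 470, "k27b")]
        got = classify_by_marks(ocrs, k4, k27)
        assert got == {"a": "K4_only", "b": "dual", "c": "K27_only",
                       "d": "unmodified"}

    def test_classes_partition_ocr_set(self, bundle, ocrs):
        k4 = read_bed(bundle.paths["k4_peaks"])
        k27 = read_bed(bundle.paths["k27_peaks"])
        classes = classify_by_marks(ocrs, k4, k27)
        assert sum(class_counts(classes).values()) == len(ocrs)
        assert set(classes.values()) <= set(HISTONE_CLASSES)

    def test_matches_planted_classes_exactly(self, bundle, ocrs):
        k4 = read_bed(bundle.paths["k4_peaks"])
        k27 = read_bed(bundle.paths["k27_peaks"])
        classes = classify_by_marks(ocrs, k4, k27)
        planted = bundle.truth["ocrs"]
        assert all(classes[o] == planted[o]["mark_class"] for o in classes)

    def test_order_independent_and_idempotent(self):
        rng = np.random.default_rng(0)
        ocrs = [_iv(100 * i, 100 * i + 80, f"o{i}") for i in range(20)]
        k4 = [_iv(100 * i + 10, 100 * i + 30, f"p{i}") for i in range(0, 20, 2)]
        first = classify_by_marks(ocrs, k4, [])
        order = rng.permutation(20)
        second = classify_by_marks([ocrs[i] for i in order], k4, [])
        assert first == second == classify_by_marks(ocrs, k4, [])


def exhaustive_best_sse(X):
    best = np.inf
    n = X.shape[0]
    for mask in itertools.product([0, 1], repeat=n):
        mask = np.array(mask, dtype=bool)
        if mask.all() or (~mask).all():
            continue
        sse = (((X[mask] - X[mask].mean(0)) ** 2).sum()
               + ((X[~mask] - X[~mask].mean(0)) ** 2).sum())
        best = min(best, sse)
    return best


class TestKmeans2:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        hi = rng.normal(10, 0.5, size=(30, 8))
        lo = rng.normal(0, 0.5, size=(30, 8))
        X = np.vstack([hi, lo])
        assign, centroids = kmeans2(X, seed=0)
        labels = [assign[str(i)] for i in range(60)]
        assert set(labels[:30]) == {"I"}      # high-signal cluster labelled I
        assert set(labels[30:]) == {"II"}
        assert centroids[0].sum() > centroids[1].sum()

    def test_matches_exhaustive_partition_at_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(size=(7, 4))
            assign, _ = kmeans2(X, seed=3, n_init=30)
            labels = np.array([assign[str(i)] == "I" for i in range(7)])
            sse = (((X[labels] - X[labels].mean(0)) ** 2).sum()
                   + ((X[~labels] - X[~labels].mean(0)) ** 2).sum())
            assert sse == pytest.approx(exhaustive_best_sse(X), rel=1e-9)

    def test_duplicate_rows_share_labels(self):
        X = np.array([[5.0, 5.0], [5.0, 5.0], [0.0, 0.0], [0.0, 0.0]])
        assign, _ = kmeans2(X, seed=0)
        assert assign["0"] == assign["1"] and assign["2"] == assign["3"]

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans2(np.zeros((1, 3)), k=2)

    def test_row_max_normalize(self):
        X = np.array([[2.0, 4.0], [0.0, 0.0]])
        assert np.allclose(row_max_normalize(X), [[0.5, 1.0], [0.0, 0.0]])


class TestDualCoverage:
    def test_hand_fractions(self):
        ocr = _iv(0, 100, "o1")
        df, _ = dual_coverage_compare([ocr], [_iv(0, 80, "k4")], [_iv(0, 20, "k27")])
        assert df.frac_K4[0] == pytest.approx(0.8)
        assert df.frac_K27[0] == pytest.approx(0.2)

    def test_identical_peak_sets_give_p_one(self):
        ocrs = [_iv(100 * i, 100 * i + 50, f"o{i}") for i in range(10)]
        peaks = [_iv(100 * i + 5, 100 * i + 25, f"p{i}") for i in range(10)]
        _, res = dual_coverage_compare(ocrs, peaks, peaks)
        assert res.p == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dual_coverage_compare([], [], [])

    def test_planted_k4_dominance_detected(self, bundle, ocrs):
        """Dual OCRs are generated with wider K4 than K27 peaks."""
        from ocrlandscape.intervals import read_bed as _rb
        planted = bundle.truth["ocrs"]
        dual = [iv for iv in ocrs if planted[iv.name]["mark_class"] == "dual"]
        df, res = dual_coverage_compare(dual, _rb(bundle.paths["k4_peaks"]),
                                        _rb(bundle.paths["k27_peaks"]))
        assert res.p < 0.05
        assert df.frac_K4.mean() > df.frac_K27.mean()


def _ann(name, gene, dist, cat="promoter", loc="pOCR"):
    return AnnotatedOCR(_iv(0, 100, name), cat, gene, dist, loc)


class TestExpressionByClass:
    def _genes(self, fpkms):
        out = {}
        for i, f in enumerate(fpkms):
            g = GeneModel(GenomicInterval("chr1", 1000 * i, 1000 * i + 500, "+", f"g{i}"))
            g.fpkm = f
            out[f"g{i}"] = g
        return out

    def test_exact_one_sided_enumeration_case(self):
        genes = self._genes([10, 12, 14, 1, 2, 3])
        classes = {f"o{i}": ("K4_only" if i < 3 else "K27_only") for i in range(6)}
        anns = [_ann(f"o{i}", f"g{i}", -500) for i in range(6)]
        fpkm, tests = expression_by_class(classes, anns, genes, side="greater")
        assert sorted(fpkm["K4_only"]) == [10, 12, 14]
        assert tests["K4_only_vs_K27_only"].p == pytest.approx(0.05, abs=1e-12)

    def test_small_class_reports_none(self):
        genes = self._genes([5, 6])
        classes = {"o0": "K4_only", "o1": "K4_only"}
        anns = [_ann("o0", "g0", -100), _ann("o1", "g1", -100)]
        _, tests = expression_by_class(classes, anns, genes)
        assert tests["K4_only_vs_K27_only"] is None

    def test_genes_deduplicated_within_class(self):
        genes = self._genes([5.0])
        classes = {"o0": "K4_only", "o1": "K4_only"}
        anns = [_ann("o0", "g0", -100), _ann("o1", "g0", -900)]
        fpkm, _ = expression_by_class(classes, anns, genes)
        assert fpkm["K4_only"].size == 1


class TestDocrStateByDistance:
    def test_all_unmodified(self):
        docrs = [_ann(f"o{i}", "g", -(2500 + 1000 * i), "distal_intergenic", "dOCR")
                 for i in range(5)]
        classes = {a.id: "unmodified" for a in docrs}
        props = docr_state_by_distance(docrs, classes)
        nonempty = props[props.n > 0]
        assert np.allclose(nonempty["unmodified"], 1.0)

    def test_hand_tally_two_bins(self):
        dists = [-2500, -2600, -2700, -3500, -3600, -3700]
        cls = ["K4_only", "K4_only", "unmodified", "unmodified", "unmodified", "dual"]
        docrs = [_ann(f"o{i}", "g", d, "distal_intergenic", "dOCR")
                 for i, d in enumerate(dists)]
        classes = {f"o{i}": c for i, c in enumerate(cls)}
        props = docr_state_by_distance(docrs, classes)
        b1 = props.loc["[2k,3k)"]
        b2 = props.loc["[3k,4k)"]
        assert b1["K4_only"] == pytest.approx(2 / 3)
        assert b1["unmodified"] == pytest.approx(1 / 3)
        assert b2["unmodified"] == pytest.approx(2 / 3)
        assert b2["dual"] == pytest.approx(1 / 3)

    def test_proportions_sum_to_one_per_nonempty_bin(self, bundle, annotations):
        docrs = [a for a in annotations if a.locality == "dOCR"]
        classes = {a.id: bundle.truth["ocrs"][a.id]["mark_class"] for a in docrs}
        props = docr_state_by_distance(docrs, classes)
        nonempty = props[props.n > 0]
        assert np.allclose(nonempty[list(HISTONE_CLASSES)].sum(axis=1), 1.0)


class TestLincrnaOverlap:
    def test_no_lincrnas(self):
        docrs = [_ann("o0", "g", -3000, "distal_intergenic", "dOCR")]
        subset, frac = lincrna_overlap(docrs, [])
        assert subset == [] and frac == 0.0

    def test_full_overlap(self):
        docrs = [_ann("o0", "g", -3000, "distal_intergenic", "dOCR")]
        _, frac = lincrna_overlap(docrs, [_iv(0, 200, "L1")])
        assert frac == 1.0

    def test_empty_docrs_rejected(self):
        with pytest.raises(ValueError):
            lincrna_overlap([], [])

    def test_planted_fraction_recovered(self, bundle, annotations):
        docrs = [a for a in annotations if a.locality == "dOCR"]
        linc = read_bed(bundle.paths["lincrnas"])
        _, frac = lincrna_overlap(docrs, linc)
        assert frac == pytest.approx(bundle.truth["summary"]["lincrna_overlap"],
                                     abs=1e-9)
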