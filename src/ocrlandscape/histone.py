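"""Histone-mark integration: OCR classification, clustering and comparisons.

OCRs are classed by overlap with H3K4me3 (activation) and H3K27me3
(repression) ChIP peaks into K4-only / K27-only / dual / unmodified —
a partition of the OCR set. Binned mark signal around OCRs is clustered
with k-means (k = 2; the higher-signal cluster is labelled I, matching
the convention that the low-signal cluster collects unmodified OCRs).
Further comparisons relate mark coverage within dual OCRs, expression by
histone class, chromatin state of distal OCRs by TSS distance, and distal
OCR overlap with LincRNA loci.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import AnnotatedOCR, GeneModel, GenomicInterval, overlap_pairs
from .signal import ProfileMatrix, covered_fraction
from .stats import TestResult, wilcoxon_ranksum

HISTONE_CLASSES = ("K4_only", "K27_only", "dual", "unmodified")


def classify_by_marks(ocrs: Sequence[GenomicInterval],
                      k4_peaks: Sequence[GenomicInterval],
                      k27_peaks: Sequence[GenomicInterval],
                      min_overlap: int = 1) -> dict[str, str]:
    """Histone class per OCR id from peak overlap (>= ``min_overlap`` bp).

    The four classes partition the OCR set; the operation is
    order-independent and idempotent.
    """
    has_k4 = {ocrs[i].name for i, _, _ in overlap_pairs(ocrs, k4_peaks, min_overlap)}
    has_k27 = {ocrs[i].name for i, _, _ in overlap_pairs(ocrs, k27_peaks, min_overlap)}
    out = {}
    for iv in ocrs:
        k4, k27 = iv.name in has_k4, iv.name in has_k27
        out[iv.name] = ("dual" if k4 and k27 else "K4_only" if k4
                        else "K27_only" if k27 else "unmodified")
    return out


def class_counts(classes: Mapping[str, str]) -> dict[str, int]:
    counts = {c: 0 for c in HISTONE_CLASSES}
    for c in classes.values():
        counts[c] += 1
    return counts


def kmeans2(matrix: ProfileMatrix | np.ndarray, k: int = 2, seed: int = 0,
            n_init: int = 10) -> tuple[dict[str, str], np.ndarray]:
    """k-means clustering of a binned signal matrix (Lloyd, k-means++ seeding).

    Best of ``n_init`` restarts by within-cluster sum of squares,
    deterministic given ``seed``. Cluster labels are roman numerals ordered
    by decreasing mean total signal (label "I" = highest), so the
    low-signal/unmodified cluster is always last.
    """
    if isinstance(matrix, ProfileMatrix):
        X, ids = matrix.values, matrix.row_ids
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    totals = [X[km.labels_ == c].sum(axis=1).mean() for c in range(k)]
    order = np.argsort(totals)[::-1]  # highest signal first
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"][:k]
    relabel = {int(c): romans[r] for r, c in enumerate(order)}
    assignment = {i: relabel[int(lbl)] for i, lbl in zip(ids, km.labels_)}
    centroids = km.cluster_centers_[order]
    return assignment, centroids


def row_max_normalize(X: np.ndarray) -> np.ndarray:
    """Per-row max normalization (rows with all-zero signal stay zero)."""
    X = np.asarray(X, dtype=float)
    mx = X.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return X / mx


def dual_coverage_compare(dual_ocrs: Sequence[GenomicInterval],
                          k4_peaks: Sequence[GenomicInterval],
                          k27_peaks: Sequence[GenomicInterval]
                          ) -> tuple[pd.DataFrame, TestResult]:
    """Per-OCR K4 vs K27 covered fractions with a paired one-sided test.

    For dual-modified OCRs, tests whether the K4 covered fraction exceeds
    the K27 covered fraction (Wilcoxon signed-rank, paired by OCR).
    """
    if not dual_ocrs:
        raise ValueError("no dual-class OCRs supplied")
    rows = []
    for iv in dual_ocrs:
        rows.append({
            "ocr_id": iv.name,
            "frac_K4": covered_fraction(k4_peaks, iv),
            "frac_K27": covered_fraction(k27_peaks, iv),
        })
    df = pd.DataFrame(rows)
    diff = df.frac_K4 - df.frac_K27
    if (diff == 0).all():
        res = TestResult(0.0, 1.0, "exact", "greater", len(df), len(df))
    else:
        from scipy.stats import wilcoxon as _signed_rank
        stat, p = _signed_rank(df.frac_K4, df.frac_K27, alternative="greater",
                               zero_method="wilcox")
        res = TestResult(float(stat), max(float(p), np.nextafter(0, 1)),
                         "normal_approx" if len(df) > 25 else "exact",
                         "greater", len(df), len(df))
    return df, res


def expression_by_class(classes: Mapping[str, str],
                        annotations: Sequence[AnnotatedOCR],
                        genes: Mapping[str, GeneModel],
                        side: str = "two") -> tuple[dict[str, np.ndarray], dict[str, TestResult | None]]:
    """FPKM distributions per histone class and pairwise rank-sum tests.

    Genes are linked via each OCR's nearest gene and deduplicated within a
    class. Returns per-class FPKM vectors and Wilcoxon rank-sum p-values
    for K4_only vs K27_only and K4_only vs dual (``None`` when a class has
    fewer than two genes).
    """
    genes_by_class: dict[str, set[str]] = defaultdict(set)
    for a in annotations:
        if a.nearest_gene is not None and a.id in classes:
            genes_by_class[classes[a.id]].add(a.nearest_gene)
    fpkm = {
        cls: np.array(sorted(genes[g].fpkm for g in gids))
        for cls, gids in genes_by_class.items()
    }
    tests: dict[str, TestResult | None] = {}
    for other in ("K27_only", "dual"):
        x, y = fpkm.get("K4_only", np.empty(0)), fpkm.get(other, np.empty(0))
        tests[f"K4_only_vs_{other}"] = (wilcoxon_ranksum(x, y, side=side)
                                        if x.size >= 2 and y.size >= 2 else None)
    return fpkm, tests


def docr_state_by_distance(docrs: Sequence[AnnotatedOCR],
                           classes: Mapping[str, str],
                           window: int = 10_000, bin_width: int = 1000,
                           start: int = 2000) -> pd.DataFrame:
    """Histone-class proportions of distal OCRs by |TSS distance| bin.

    Bins cover [start, start + window) upstream of the TSS in
    ``bin_width`` steps; proportions sum to 1 in every nonempty bin.
    dOCRs beyond the window are pooled into a final open-ended bin.
    """
    edges = list(range(start, start + window + bin_width, bin_width))
    labels = [f"[{lo // 1000}k,{hi // 1000}k)" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">={edges[-1] // 1000}k")
    counts = pd.DataFrame(0, index=labels, columns=list(HISTONE_CLASSES))
    for a in docrs:
        d = abs(a.tss_distance)
        idx = min((d - start) // bin_width, len(labels) - 1) if d >= start else 0
        counts.loc[labels[int(idx)], classes[a.id]] += 1
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0, 1), axis=0)
    props["n"] = totals
    return props


def lincrna_overlap(docrs: Sequence[AnnotatedOCR],
                    lincrna_loci: Sequence[GenomicInterval]
                    ) -> tuple[list[AnnotatedOCR], float]:
    """Distal OCRs overlapping LincRNA loci (>= 1 bp) and their fraction."""
    if not docrs:
        raise ValueError("empty dOCR set: overlap fraction undefined")
    ivs = [a.interval for a in docrs]
    hit_idx = {i for i, _, _ in overlap_pairs(ivs, list(lincrna_loci))}
    subset = [docrs[i] for i in sorted(hit_idx)]
    return subset, len(subset) / len(docrs)
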