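"""Homologous OCR detection and duplication analysis.

On a genome shaped by whole-genome duplication, an OCR may have a
homologous counterpart (hOCR) elsewhere: a sequence-similar OCR on a
*different* chromosome whose local-alignment E-value falls below a
threshold (1e-5 by default). Alignment is Smith–Waterman with affine gaps
(blastn-like scoring: match +1, mismatch −2, gap −5 open / −2 extend) and
significance follows the Karlin–Altschul form E = K·m·n·exp(−λS), applied
to the pairwise search space m = len(a), n = len(b) so that the statistic
is symmetric in the two sequences.

Downstream classification relates hOCR pairs to homologous gene pairs,
compares expression within asymmetric pairs (only one member OCR-bearing),
and classes histone antagonism cases by the FPKM > 10 / FPKM = 0 rules.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .intervals import AnnotatedOCR, GeneModel, GenomicInterval
from .seqs import encode, extract_sequences, revcomp
from .signal import SignalTrack
from .stats import TestResult, wilcoxon_ranksum

#: Karlin–Altschul defaults for the blastn-like scoring scheme
KA_K = 0.1
KA_LAMBDA = 1.0

#: FPKM thresholds: highly expressed > 10, nonexpressed = 0
FPKM_HIGH = 10.0

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2


@dataclass(frozen=True)
class AlignmentScore:
    """Raw local-alignment score with its Karlin–Altschul context."""

    S: int
    m: int
    n: int
    K: float = KA_K
    lambda_: float = KA_LAMBDA

    @property
    def evalue(self) -> float:
        return evalue(self.S, self.m, self.n, self.K, self.lambda_)


@dataclass
class HomologyPair:
    """Best-scoring cross-chromosome OCR pair below the E-value threshold."""

    ocr_a: str
    ocr_b: str
    chrom_a: str
    chrom_b: str
    score: AlignmentScore
    strand: str = "+"
    gene_a: str | None = None
    gene_b: str | None = None
    relation: str | None = None  # hOCR_hGene | hOCR_nonhGene
    locality_conserved: bool | None = None

    @property
    def evalue(self) -> float:
        return self.score.evalue


@dataclass
class AsymmetricPair:
    """Homologous gene pair in which exactly one member carries an OCR."""

    gene_with: str
    gene_without: str
    fpkm_with: float
    fpkm_without: float


# ---------------------------------------------------------------------------
# Smith–Waterman
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_score(a: np.ndarray, b: np.ndarray, match: int, mismatch: int,
              gap_open: int, gap_extend: int) -> int:
    """Affine-gap Smith–Waterman score, linear memory. N (code 4) mismatches."""
    n, m = a.size, b.size
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, -10 ** 9, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag = 0  # H[i-1][0]
        F = -10 ** 9
        Hij_prev = 0  # H[i][0]
        for j in range(1, m + 1):
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)      # gap in b (vertical)
            F = max(Hij_prev + gap_open, F + gap_extend)        # gap in a (horizontal)
            h = diag + sub
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            Hij_prev = h
            if h > best:
                best = h
    return best


def sw_score(seq1: str, seq2: str, match: int = MATCH, mismatch: int = MISMATCH,
             gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND) -> int:
    """Optimal local alignment score (score only, fast path)."""
    if not seq1 or not seq2:
        return 0
    return int(_sw_score(encode(seq1), encode(seq2), match, mismatch,
                         gap_open, gap_extend))


def smith_waterman(seq1: str, seq2: str, match: int = MATCH, mismatch: int = MISMATCH,
                   gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND
                   ) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Smith–Waterman with traceback.

    Returns ``(S, (start1, end1), (start2, end2))`` — the optimal local
    score and the half-open aligned spans in each sequence. A gap of
    length L costs ``gap_open + (L-1)*gap_extend``. Traceback ties are
    broken diagonal > up > left; empty input gives S = 0.
    """
    a, b = encode(seq1), encode(seq2)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        return 0, (0, 0), (0, 0)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            h = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, (0, 0), (0, 0)
    # traceback from the best cell until score 0; diagonal > up > left
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in seq2, move up
            up_open = H[i - 1, j] + gap_open
            if F[i, j] == up_open:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # state == "E": gap in seq1, move left
            left_open = H[i, j - 1] + gap_open
            if E[i, j] == left_open:
                j, state = j - 1, "H"
            else:
                j = j - 1
    return int(best), (i, bi), (j, bj)


def evalue(S: float, m: int, n: int, K: float = KA_K,
           lambda_: float = KA_LAMBDA) -> float:
    """Karlin–Altschul expected hit count E = K·m·n·exp(−λS)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be positive")
    if S < 0:
        raise ValueError("score must be nonnegative")
    return K * m * n * math.exp(-lambda_ * S)


# ---------------------------------------------------------------------------
# hOCR search
# ---------------------------------------------------------------------------


@dataclass
class HocrResult:
    pairs: list[HomologyPair]
    best_partner: dict[str, HomologyPair]
    fraction: float
    n_ocrs: int
    same_chrom_pairs: list[HomologyPair] = field(default_factory=list)


def _kmer_candidates(seqs: dict[str, str], k: int) -> set[tuple[str, str]]:
    """Unordered id pairs sharing at least one canonical k-mer."""
    buckets: dict[str, list[str]] = defaultdict(list)
    for name, s in seqs.items():
        kmers = set()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if "N" in w:
                continue
            kmers.add(min(w, revcomp(w)))
        for w in kmers:
            buckets[w].append(name)
    cands = set()
    for names in buckets.values():
        if len(names) < 2:
            continue
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                x, y = sorted((names[i], names[j]))
                cands.add((x, y))
    return cands


def find_hocrs(ocrs: Sequence[GenomicInterval], genome,
               evalue_max: float = 1e-5, K: float = KA_K, lambda_: float = KA_LAMBDA,
               match: int = MATCH, mismatch: int = MISMATCH,
               gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
               prefilter: bool = True, prefilter_k: int = 12,
               min_len: int = 10) -> HocrResult:
    """Find homologous OCR pairs by local alignment.

    Each OCR is compared with OCRs on other chromosomes in both
    orientations; a pair is a hit when its E-value is below ``evalue_max``
    and each OCR retains its best-scoring partner. ``genome`` is a FASTA
    path or a precomputed ``{ocr_id: sequence}`` mapping. By default a
    shared-k-mer prefilter skips pairs that cannot align significantly
    (``prefilter=False`` forces the full all-vs-all comparison; the
    resulting pair set is identical). Same-chromosome duplicates are
    collected separately and excluded from the hOCR statistics.
    """
    seqs = genome if isinstance(genome, Mapping) else extract_sequences(genome, ocrs)
    chrom_of = {iv.name: iv.chrom for iv in ocrs}
    ids = [iv.name for iv in ocrs]
    kept = []
    for name in ids:
        if len(seqs[name]) < min_len:
            warnings.warn(f"OCR {name} shorter than {min_len} bp; skipped")
        else:
            kept.append(name)
    if prefilter:
        cands = _kmer_candidates({n: seqs[n] for n in kept}, prefilter_k)
    else:
        cands = {(a, b) for i, a in enumerate(kept) for b in kept[i + 1:]}
        cands = {tuple(sorted(p)) for p in cands}
    best: dict[str, HomologyPair] = {}
    same_chrom = []
    enc_cache = {n: (encode(seqs[n]), encode(revcomp(seqs[n]))) for n in kept}
    for a, b in sorted(cands):
        ea, _ = enc_cache[a]
        eb_f, eb_r = enc_cache[b]
        s_f = int(_sw_score(ea, eb_f, match, mismatch, gap_open, gap_extend))
        s_r = int(_sw_score(ea, eb_r, match, mismatch, gap_open, gap_extend))
        s, strand = (s_f, "+") if s_f >= s_r else (s_r, "-")
        score = AlignmentScore(s, len(seqs[a]), len(seqs[b]), K, lambda_)
        if score.evalue >= evalue_max:
            continue
        pair = HomologyPair(a, b, chrom_of[a], chrom_of[b], score, strand)
        if chrom_of[a] == chrom_of[b]:
            same_chrom.append(pair)
            continue
        for name in (a, b):
            cur = best.get(name)
            if cur is None or score.S > cur.score.S:
                best[name] = pair
    uniq = {(p.ocr_a, p.ocr_b): p for p in best.values()}
    pairs = [uniq[k] for k in sorted(uniq)]
    fraction = len(best) / len(kept) if kept else 0.0
    return HocrResult(pairs, best, fraction, len(kept), same_chrom)


# ---------------------------------------------------------------------------
# Relation to homologous genes
# ---------------------------------------------------------------------------


def _norm_pairs(homolog_pairs) -> set[frozenset]:
    return {frozenset(p) for p in homolog_pairs}


def classify_relation(pair: HomologyPair,
                      annotations: Mapping[str, AnnotatedOCR],
                      homolog_pairs) -> HomologyPair:
    """Class an hOCR pair by whether its nearest genes are homologs.

    Fills ``relation`` (hOCR_hGene when the two nearest genes form a listed
    homologous pair, else hOCR_nonhGene) and ``locality_conserved`` (both
    members share the pOCR/dOCR/genic class). An OCR without a nearest
    gene leaves the relation ``None`` (flagged, not counted).
    """
    table = homolog_pairs if isinstance(homolog_pairs, set) else _norm_pairs(homolog_pairs)
    ann_a, ann_b = annotations.get(pair.ocr_a), annotations.get(pair.ocr_b)
    if ann_a is None or ann_b is None:
        raise KeyError(f"missing annotation for {pair.ocr_a} or {pair.ocr_b}")
    pair.gene_a, pair.gene_b = ann_a.nearest_gene, ann_b.nearest_gene
    if pair.gene_a is None or pair.gene_b is None:
        pair.relation = None
        return pair
    pair.relation = ("hOCR_hGene" if frozenset((pair.gene_a, pair.gene_b)) in table
                     else "hOCR_nonhGene")
    pair.locality_conserved = ann_a.locality == ann_b.locality
    return pair


def classify_relations(pairs: Sequence[HomologyPair],
                       annotations: Mapping[str, AnnotatedOCR],
                       homolog_pairs) -> dict[str, float]:
    """Classify every pair; return relation fractions over classifiable pairs."""
    table = _norm_pairs(homolog_pairs)
    for p in pairs:
        classify_relation(p, annotations, table)
    classed = [p for p in pairs if p.relation is not None]
    n = len(classed)
    return {
        "hOCR_hGene": sum(p.relation == "hOCR_hGene" for p in classed) / n if n else 0.0,
        "hOCR_nonhGene": sum(p.relation == "hOCR_nonhGene" for p in classed) / n if n else 0.0,
        "locality_conserved": (sum(bool(p.locality_conserved) for p in classed) / n
                               if n else 0.0),
        "n_classified": n,
    }


def asymmetric_pairs(homolog_pairs, ocr_annotations: Sequence[AnnotatedOCR],
                     genes: Mapping[str, GeneModel]) -> list[AsymmetricPair]:
    """Homologous gene pairs in which exactly one member has an OCR.

    A gene "has an OCR" when it is the nearest gene of at least one OCR.
    Pairs where both or neither member carries an OCR are excluded.
    """
    with_ocr = {a.nearest_gene for a in ocr_annotations if a.nearest_gene}
    out = []
    for pair in homolog_pairs:
        ga, gb = tuple(pair)[:2] if not isinstance(pair, (list, tuple)) else pair
        a_has, b_has = ga in with_ocr, gb in with_ocr
        if a_has == b_has:
            continue
        gw, gwo = (ga, gb) if a_has else (gb, ga)
        out.append(AsymmetricPair(gw, gwo, genes[gw].fpkm, genes[gwo].fpkm))
    return out


def pair_expression_test(pairs: Sequence[AsymmetricPair],
                         side: str = "greater") -> tuple[TestResult, dict[str, float]]:
    """Wilcoxon test of FPKM: OCR-bearing vs OCR-lacking pair members."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 asymmetric pairs")
    x = [p.fpkm_with for p in pairs]
    y = [p.fpkm_without for p in pairs]
    res = wilcoxon_ranksum(x, y, side=side)
    medians = {"with_ocr": float(np.median(x)), "without_ocr": float(np.median(y))}
    return res, medians


def antagonism_classify(pairs: Sequence[AsymmetricPair],
                        k4_track: SignalTrack, k27_track: SignalTrack,
                        genes: Mapping[str, GeneModel], tss_flank: int = 1000,
                        fpkm_high: float = FPKM_HIGH) -> list[dict]:
    """Histone-antagonism classes over members of asymmetric pairs.

    ``high_expr_no_OCR``: FPKM > ``fpkm_high`` without an OCR;
    ``silent_with_OCR``: FPKM = 0 with an OCR; everything else ``other``.
    Each record carries the mean H3K4me3/H3K27me3 signal at TSS ± flank.
    """
    out = []
    for p in pairs:
        for gid, has_ocr, fpkm in ((p.gene_with, True, p.fpkm_with),
                                   (p.gene_without, False, p.fpkm_without)):
            g = genes[gid]
            a = max(0, g.tss - tss_flank)
            b = g.tss + tss_flank
            iv = GenomicInterval(g.chrom, a, b)
            if fpkm > fpkm_high and not has_ocr:
                cls = "high_expr_no_OCR"
            elif fpkm == 0 and has_ocr:
                cls = "silent_with_OCR"
            else:
                cls = "other"
            out.append({
                "gene": gid, "has_ocr": has_ocr, "fpkm": fpkm, "class": cls,
                "mean_k4": k4_track.mean(iv), "mean_k27": k27_track.mean(iv),
            })
    return out
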