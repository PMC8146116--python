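"""Coordinate core: genomic intervals, gene models, and OCR annotation.

All coordinates are BED-style 0-based half-open internally. GFF3 input
(1-based, closed) is converted on read. An open chromatin region (OCR) is
annotated with exactly one genomic-feature category using a fixed priority
(promoter first), linked to its nearest gene by signed TSS distance, and
classified as promoter-proximal (pOCR), distal (dOCR, beyond the promoter
window upstream of the TSS) or genic.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: feature categories in annotation priority order (highest first)
CATEGORIES = (
    "promoter",
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)

LOCALITIES = ("pOCR", "dOCR", "genic")

#: default promoter window (bp upstream of the TSS); also the dOCR boundary
PROMOTER_BP = 2000


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return self.id or f"{self.chrom}:{self.start}-{self.end}"

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """Gene span with exon/UTR structure and attached expression/annotation.

    The TSS is the first transcribed base in gene orientation: ``start`` on
    the + strand, ``end - 1`` on the − strand (TES symmetric).
    """

    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    five_utr: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)
    fpkm: float = float("nan")
    go_terms: set[str] = field(default_factory=set)
    homolog_id: str | None = None

    def __post_init__(self):
        iv = self.interval
        for ex in self.exons:
            if ex.start < iv.start or ex.end > iv.end:
                raise ValueError(f"exon {ex} outside gene {iv.id}")

    @property
    def id(self) -> str:
        return self.interval.id

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def introns(self) -> list[GenomicInterval]:
        exs = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in itertools.pairwise(exs):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def promoter_window(self, promoter_bp: int = PROMOTER_BP) -> GenomicInterval | None:
        """Window of ``promoter_bp`` bases immediately upstream of the TSS."""
        if self.strand == "-":
            return GenomicInterval(self.chrom, self.tss + 1, self.tss + 1 + promoter_bp, "-")
        start = max(0, self.tss - promoter_bp)
        if start == self.tss:
            return None
        return GenomicInterval(self.chrom, start, self.tss, "+")

    def downstream_window(self, downstream_bp: int = PROMOTER_BP) -> GenomicInterval | None:
        """Window of ``downstream_bp`` bases immediately past the TES."""
        if self.strand == "-":
            start = max(0, self.interval.start - downstream_bp)
            if start == self.interval.start:
                return None
            return GenomicInterval(self.chrom, start, self.interval.start, "-")
        return GenomicInterval(
            self.chrom, self.interval.end, self.interval.end + downstream_bp, "+"
        )


@dataclass
class AnnotatedOCR:
    """OCR with its feature category, nearest gene and locality class."""

    interval: GenomicInterval
    category: str
    nearest_gene: str | None
    tss_distance: int | None
    locality: str = "genic"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def id(self) -> str:
        return self.interval.name


# ---------------------------------------------------------------------------
# GFF3 / BED input
# ---------------------------------------------------------------------------


def _gff3_attributes(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon, optionally UTR features).

    Coordinates are converted to 0-based half-open. When a gene has several
    transcripts the longest (by span, ties by id) is kept. Output is ordered
    by (chrom, start). Malformed lines raise :class:`ParseError` with the
    line number; an exon outside its gene raises ``ValueError``.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(path, lineno, f"invalid coordinates {start1}..{end1}")
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            attrs = _gff3_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(path, lineno, "gene feature without ID")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end, strand, gid),
                    "transcripts": [],
                }
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ParseError(path, lineno, f"{ftype} without ID/Parent")
                tx = {"id": tid, "gene": parent, "span": end - start,
                      "exons": [], "five_utr": [], "three_utr": []}
                transcripts[tid] = tx
                if parent in genes:
                    genes[parent]["transcripts"].append(tx)
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attrs.get("Parent")
                iv = GenomicInterval(chrom, start, end, strand)
                key = {"exon": "exons", "five_prime_UTR": "five_utr",
                       "three_prime_UTR": "three_utr"}[ftype]
                if parent in transcripts:
                    transcripts[parent][key].append(iv)
                elif parent in genes:
                    # exon attached directly to a gene (transcript-less GFF3)
                    genes[parent].setdefault(key, []).append(iv)
    models = []
    for gid, g in genes.items():
        txs = g["transcripts"]
        if txs:
            best = max(txs, key=lambda t: (t["span"], t["id"]))
            exons, fu, tu = best["exons"], best["five_utr"], best["three_utr"]
        else:
            exons = g.get("exons", [])
            fu, tu = g.get("five_utr", []), g.get("three_utr", [])
        if not exons:
            exons = [g["interval"]]
        models.append(GeneModel(interval=g["interval"], exons=sorted(exons, key=lambda e: e.start),
                                five_utr=fu, three_utr=tu))
    models.sort(key=lambda m: (m.chrom, m.interval.start))
    return models


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/4/6 or narrowPeak intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(path, lineno, "fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path, names: Sequence[str] | None = None):
    """Write BED6; ``names`` overrides the interval ids (e.g. categories)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            nm = names[i] if names is not None else iv.name
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# TSS distance and annotation
# ---------------------------------------------------------------------------


def tss_distance(ocr: GenomicInterval, gene: GeneModel) -> int:
    """Signed distance from an OCR to a gene's TSS.

    0 when the OCR overlaps the TSS base; otherwise the gap from the OCR
    boundary nearest the TSS, negative when the OCR lies upstream of the
    TSS in the gene's orientation. Strand handling is by reflection into
    the + frame, so the convention is exactly strand-symmetric.
    """
    if ocr.chrom != gene.chrom:
        raise ValueError("OCR and gene must be on the same chromosome")
    t = gene.tss
    if ocr.start <= t < ocr.end:
        return 0
    if gene.strand == "+":
        s, e, tt = ocr.start, ocr.end, t
    else:
        s, e, tt = -ocr.end, -ocr.start, -t - 1
    return e - tt if e <= tt else s - tt


class GeneIndex:
    """Per-chromosome interval trees over gene feature windows.

    Category lookup is by overlap in the fixed priority order; nearest-gene
    lookup is the gene with minimal absolute TSS distance (ties broken by
    lexicographically smallest gene id).
    """

    def __init__(self, genes: Sequence[GeneModel], promoter_bp: int = PROMOTER_BP,
                 downstream_bp: int = PROMOTER_BP):
        self.genes = list(genes)
        self.promoter_bp = promoter_bp
        self.downstream_bp = downstream_bp
        self.trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in genes:
            self.by_chrom[g.chrom].append(g)
            feats = {
                "promoter": [g.promoter_window(promoter_bp)],
                "five_utr": g.five_utr,
                "three_utr": g.three_utr,
                "exon": g.exons,
                "intron": g.introns(),
                "downstream": [g.downstream_window(downstream_bp)],
            }
            for cat, ivs in feats.items():
                for iv in ivs:
                    if iv is not None:
                        self.trees[(g.chrom, cat)].addi(iv.start, iv.end, g.id)

    def category(self, ocr: GenomicInterval) -> str:
        for cat in CATEGORIES[:-1]:
            tree = self.trees.get((ocr.chrom, cat))
            if tree is not None and tree.overlap(ocr.start, ocr.end):
                return cat
        return "distal_intergenic"

    def nearest_gene(self, ocr: GenomicInterval) -> tuple[str | None, int | None]:
        cands = self.by_chrom.get(ocr.chrom, [])
        if not cands:
            return None, None
        best = min(cands, key=lambda g: (abs(tss_distance(ocr, g)), g.id))
        return best.id, tss_distance(ocr, best)


def classify_locality(category: str, tss_dist: int | None,
                      promoter_bp: int = PROMOTER_BP) -> str:
    """pOCR for promoter OCRs, dOCR for distal-intergenic OCRs more than
    ``promoter_bp`` upstream of the nearest TSS, genic otherwise."""
    if category == "promoter":
        return "pOCR"
    if category == "distal_intergenic" and tss_dist is not None and tss_dist < -promoter_bp:
        return "dOCR"
    return "genic"


def annotate_ocr(ocr: GenomicInterval, genes: Sequence[GeneModel] | GeneIndex,
                 promoter_bp: int = PROMOTER_BP, downstream_bp: int = PROMOTER_BP) -> AnnotatedOCR:
    """Annotate a single OCR; see :func:`annotate_ocrs`."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp, downstream_bp)
    cat = index.category(ocr)
    gid, dist = index.nearest_gene(ocr)
    return AnnotatedOCR(ocr, cat, gid, dist,
                        classify_locality(cat, dist, index.promoter_bp))


def annotate_ocrs(ocrs: Sequence[GenomicInterval], genes: Sequence[GeneModel] | GeneIndex,
                  promoter_bp: int = PROMOTER_BP,
                  downstream_bp: int = PROMOTER_BP) -> list[AnnotatedOCR]:
    """Assign each OCR one feature category, nearest gene and locality.

    Categories follow the fixed priority promoter > 5'UTR > 3'UTR > exon >
    intron > downstream > distal_intergenic; an OCR overlapping several
    features takes the highest-priority one. With an empty gene set every
    OCR is distal_intergenic with no nearest gene.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp, downstream_bp)
    return [annotate_ocr(o, index) for o in ocrs]


def annotation_frame(annotated: Sequence[AnnotatedOCR]) -> pd.DataFrame:
    """Tabular view (TSV-ready) of an annotation run."""
    return pd.DataFrame(
        {
            "ocr_id": [a.id for a in annotated],
            "chrom": [a.interval.chrom for a in annotated],
            "start": [a.interval.start for a in annotated],
            "end": [a.interval.end for a in annotated],
            "category": [a.category for a in annotated],
            "nearest_gene": [a.nearest_gene for a in annotated],
            "tss_distance": [a.tss_distance for a in annotated],
            "locality": [a.locality for a in annotated],
        }
    )


def category_proportions(annotated: Sequence[AnnotatedOCR]) -> dict[str, float]:
    """Fraction of OCRs per category (all seven categories present)."""
    n = len(annotated)
    counts = {c: 0 for c in CATEGORIES}
    for a in annotated:
        counts[a.category] += 1
    return {c: (counts[c] / n if n else 0.0) for c in CATEGORIES}


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def default_distance_edges(max_distance: int | None = None) -> np.ndarray:
    """Doubling bin edges 2, 4, 8 ... 512 kb, extended to cover the data."""
    edges = [2000 * 2 ** i for i in range(9)]  # 2k .. 512k
    if max_distance is not None:
        while edges[-1] < max_distance:
            edges.append(edges[-1] * 2)
    return np.asarray(edges)


def distance_histogram(docrs: Sequence[AnnotatedOCR],
                       bin_edges: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of |TSS distance| of distal OCRs in half-open [lo, hi) bins.

    Default edges double from 2 kb; counts always sum to the input size.
    A distance below the first edge is a contract violation (such an OCR
    cannot be distal).
    """
    dists = np.array([abs(a.tss_distance) for a in docrs], dtype=float)
    if bin_edges is None:
        bin_edges = default_distance_edges(int(dists.max()) + 1 if dists.size else None)
    edges = np.asarray(bin_edges, dtype=float)
    if dists.size and dists.min() < edges[0]:
        raise ValueError(f"distance {dists.min():.0f} below first bin edge {edges[0]:.0f}")
    # np.histogram closes the last bin; shift guarantees strict [lo, hi)
    counts, _ = np.histogram(dists, bins=np.append(edges[:-1], np.nextafter(edges[-1], -1)))
    return counts, np.asarray(bin_edges)


def overlap_pairs(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                  min_overlap: int = 1) -> list[tuple[int, int, int]]:
    """All (i, j, bp) with a[i] and b[j] overlapping by >= ``min_overlap``."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(b):
        trees[iv.chrom].addi(iv.start, iv.end, j)
    out = []
    for i, iv in enumerate(a):
        for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            bp = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if bp >= min_overlap:
                out.append((i, hit.data, bp))
    out.sort()
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out
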