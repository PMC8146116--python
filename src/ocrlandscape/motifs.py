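"""Transcription-factor motif scanning, enrichment and network building.

A position weight matrix (PWM) is scanned over OCR sequences by log-odds
scoring against a background base composition; a window is a hit when its
score reaches a fraction of the motif's maximum attainable score. Motif
enrichment contrasts the number of sequences with at least one hit in the
OCR set against a background set (dinucleotide-preserving shuffles by
default) with Fisher's exact test and Benjamini–Hochberg correction.
Enriched motifs, OCR→gene links and gene→GO annotations combine into a
bipartite TF-motif → GO-term regulatory network in which a GO term is
"core" when targeted by at least four motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from Bio import motifs as _bio_motifs

from .intervals import AnnotatedOCR, GenomicInterval
from .seqs import BASES, encode
from .stats import benjamini_hochberg, fisher_exact

#: pseudocount added to PWM probabilities before log-odds scoring
PSEUDOCOUNT = 0.01

#: in-degree at which a GO node counts as a network "core" term
CORE_IN_DEGREE = 4


@dataclass
class PWM:
    """Position weight matrix with a TF family label.

    ``matrix`` holds per-position base probabilities (L x 4, columns
    A/C/G/T); ``background`` the scanning background frequencies.
    """

    motif_id: str
    tf_family: str
    matrix: np.ndarray
    background: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise ValueError("PWM must be L x 4 with L >= 4")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2 odds vs background after pseudocount regularization."""
        p = self.matrix + PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, motif_id: str, tf_family: str, counts: np.ndarray) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, tf_family, counts / counts.sum(axis=1, keepdims=True))

    @classmethod
    def from_consensus(cls, motif_id: str, tf_family: str, consensus: str,
                       major: float = 0.85) -> "PWM":
        """Degenerate PWM placing ``major`` probability on the consensus base."""
        mat = np.full((len(consensus), 4), (1 - major) / 3)
        for i, b in enumerate(consensus):
            mat[i, BASES.index(b)] = major
        return cls(motif_id, tf_family, mat)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float


@dataclass
class EnrichmentResult:
    motif_id: str
    tf_family: str
    n_ocr_hit: int
    n_ocr_total: int
    n_bg_hit: int
    n_bg_total: int
    p: float
    q: float = float("nan")
    enriched: bool = False

    @property
    def odds_ratio(self) -> float:
        a, b = self.n_ocr_hit, self.n_ocr_total - self.n_ocr_hit
        c, d = self.n_bg_hit, self.n_bg_total - self.n_bg_hit
        if b == 0 or c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# JASPAR-style I/O (4 rows A/C/G/T of counts, id + family in the header)
# ---------------------------------------------------------------------------


def read_jaspar(path) -> list[PWM]:
    """Read PWMs from JASPAR-format text; header name is the TF family."""
    with open(path) as fh:
        mots = _bio_motifs.parse(fh, "jaspar")
    out = []
    for m in mots:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T
        out.append(PWM.from_counts(m.matrix_id or m.name, m.name or "unknown", counts))
    return out


def write_jaspar(pwms: Sequence[PWM], path, scale: int = 100):
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\t{p.tf_family}\n")
            counts = np.rint(p.matrix * scale).astype(int)
            for j, b in enumerate(BASES):
                row = " ".join(str(c) for c in counts[:, j])
                fh.write(f"{b}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows of len(lo) plus a validity mask (no N)."""
    L = lo.shape[0]
    if codes.size < L:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win != 4).all(axis=1)
    safe = np.where(win == 4, 0, win)
    scores = lo[np.arange(L), safe].sum(axis=1)
    return scores, valid


def pwm_logodds_scan(seq: str, pwm: PWM, threshold_frac: float = 0.8,
                     chrom: str = "seq", offset: int = 0) -> list[MotifHit]:
    """Scan both strands of a sequence for log-odds hits.

    A window scores ``sum_i log2(p_i(base_i) / bg(base_i))``; it is a hit
    when the score reaches ``threshold_frac`` of the motif's maximum.
    Windows containing N are skipped; reverse-strand hits are reported in
    forward coordinates.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")
    codes = encode(seq)
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # reverse-complement: flip positions and bases
    threshold = threshold_frac * pwm.max_score()
    hits = []
    for strand, mat in (("+", lo), ("-", lo_rc)):
        scores, valid = _window_scores(codes, mat)
        for i in np.flatnonzero(valid & (scores >= threshold)):
            iv = GenomicInterval(chrom, offset + int(i), offset + int(i) + len(pwm),
                                 strand, f"{pwm.motif_id}@{offset + int(i)}")
            hits.append(MotifHit(pwm.motif_id, iv, strand, float(scores[i])))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def has_hit(seq: str, pwm: PWM, threshold_frac: float = 0.8) -> bool:
    """Fast predicate: does the sequence contain at least one hit?"""
    codes = encode(seq)
    lo = pwm.log_odds()
    threshold = threshold_frac * pwm.max_score()
    for mat in (lo, lo[::-1, ::-1]):
        scores, valid = _window_scores(codes, mat)
        if valid.size and (scores[valid] >= threshold).any():
            return True
    return False


# ---------------------------------------------------------------------------
# Background and enrichment
# ---------------------------------------------------------------------------


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian-walk construction).

    Preserves the exact dinucleotide counts of the input, so shuffled
    backgrounds control for local base composition.
    """
    if len(seq) < 3:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(succ.keys())
    # pick one terminal edge per non-sink vertex so terminal edges form a
    # tree into the sink (guarantees the shuffled walk uses every edge)
    while True:
        terminal = {}
        for v in vertices:
            if v != last:
                terminal[v] = succ[v][rng.integers(len(succ[v]))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen or cur not in succ and cur != last:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled = {}
    for v in vertices:
        edges = list(succ[v])
        if v != last:
            edges.remove(terminal[v])
        rng.shuffle(edges)
        if v != last:
            edges.append(terminal[v])
        shuffled[v] = edges
    out, cur = [seq[0]], seq[0]
    ptr = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_background(seqs: Mapping[str, str] | Sequence[str],
                        seed: int = 0) -> list[str]:
    """One dinucleotide-preserving shuffle per input sequence."""
    rng = np.random.default_rng(seed)
    vals = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    return [dinucleotide_shuffle(s, rng) for s in vals]


def motif_enrichment(ocr_seqs: Mapping[str, str] | Sequence[str],
                     bg_seqs: Sequence[str] | None,
                     pwms: Sequence[PWM], alpha: float = 0.05,
                     threshold_frac: float = 0.8,
                     seed: int = 0) -> list[EnrichmentResult]:
    """Per-motif enrichment of OCR sequences against a background.

    The unit is "sequence with >= 1 hit"; each motif yields a 2x2 table
    (hit x set) tested two-sided by Fisher's exact test, corrected across
    motifs by Benjamini–Hochberg. A motif is enriched when q < ``alpha``
    and the odds ratio exceeds 1. With ``bg_seqs=None`` a seeded
    dinucleotide-shuffled background is generated.
    """
    fg = list(ocr_seqs.values()) if isinstance(ocr_seqs, Mapping) else list(ocr_seqs)
    bg = list(bg_seqs) if bg_seqs is not None else shuffled_background(fg, seed)
    results = []
    for pwm in pwms:
        n_fg = sum(has_hit(s, pwm, threshold_frac) for s in fg)
        n_bg = sum(has_hit(s, pwm, threshold_frac) for s in bg)
        table = [[n_fg, len(fg) - n_fg], [n_bg, len(bg) - n_bg]]
        p = fisher_exact(table, side="two").p
        results.append(EnrichmentResult(pwm.motif_id, pwm.tf_family,
                                        n_fg, len(fg), n_bg, len(bg), p))
    q = benjamini_hochberg([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.enriched = bool(qi < alpha and r.odds_ratio > 1)
    return results


def enrichment_fraction(results: Sequence[EnrichmentResult]) -> float:
    """Fraction of tested motifs called enriched."""
    if not results:
        raise ValueError("no enrichment results")
    return sum(r.enriched for r in results) / len(results)


def enrichment_percentage(n_enriched: int, n_tested: int) -> float:
    """Enriched motifs as a percentage of motifs tested."""
    if n_tested <= 0 or not 0 <= n_enriched <= n_tested:
        raise ValueError("need 0 <= n_enriched <= n_tested, n_tested > 0")
    return 100.0 * n_enriched / n_tested


# ---------------------------------------------------------------------------
# Regulatory network and cotargeting
# ---------------------------------------------------------------------------


def motif_gene_targets(hit_ocrs: Mapping[str, Iterable[str]],
                       annotations: Sequence[AnnotatedOCR]) -> dict[str, set[str]]:
    """Map motif -> target genes via OCR hits and nearest-gene links."""
    ocr_gene = {a.id: a.nearest_gene for a in annotations if a.nearest_gene}
    return {
        motif: {ocr_gene[o] for o in ocrs if o in ocr_gene}
        for motif, ocrs in hit_ocrs.items()
    }


def build_network(motif_targets: Mapping[str, Iterable[str]],
                  gene_go: Mapping[str, Iterable[str]],
                  core_in_degree: int = CORE_IN_DEGREE) -> nx.DiGraph:
    """Bipartite TF-motif → GO-term network from motif target genes.

    An edge motif→GO exists iff at least one gene both carries the GO term
    and is targeted by the motif. GO nodes are classed ``core`` when their
    in-degree is at least ``core_in_degree``, else ``peripheral``.
    """
    g = nx.DiGraph()
    for motif, genes in motif_targets.items():
        g.add_node(motif, kind="motif")
        gos: set[str] = set()
        for gene in genes:
            gos.update(gene_go.get(gene, ()))
        for go in gos:
            g.add_node(go, kind="go")
            g.add_edge(motif, go)
    for node, data in g.nodes(data=True):
        if data["kind"] == "go":
            data["go_class"] = ("core" if g.in_degree(node) >= core_in_degree
                                else "peripheral")
    return g


def network_tables(g: nx.DiGraph):
    """Edge list and node table (as records) for TSV export."""
    edges = [{"motif": u, "go": v} for u, v in g.edges()]
    nodes = [{"node": n, **d} for n, d in g.nodes(data=True)]
    return edges, nodes


def cotarget_sets(genes_a: Iterable[str], genes_b: Iterable[str],
                  genes_c: Iterable[str]) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a 3-set Venn over gene ids."""
    a, b, c = set(genes_a), set(genes_b), set(genes_c)
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
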