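"""Synthetic duplicated-genome generator with planted ground truth.

Builds a small multi-chromosome genome shaped like a paleopolyploid plant
genome: chromosomes come in homeologous pairs, and selected gene
neighborhoods ("cassettes": upstream distal zone + 2-kb promoter + gene
body + downstream zone) are copied onto the partner chromosome with
per-base substitution at 1 − duplicate_identity, mimicking retention after
whole-genome duplication. Every downstream analysis input is emitted in
its standard exchange format — genome FASTA, gene models GFF3, OCR and
histone-peak BED, bedGraph signal, expression/GO/homolog TSV, JASPAR PWMs
— together with a truth table recording each planted feature.

Placement is exact-count: per-category OCR tallies, per-locality histone
class tallies and homologous-pair counts are deterministic functions of
the spec (largest-remainder rounding), so recovery tests can be tight.
Sequence content, mutation, placement jitter and expression noise remain
stochastic under the seed; the same seed reproduces every file
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import (CATEGORIES, AnnotatedOCR, GenomicInterval, annotate_ocrs,
                        parse_gff3, read_bed, tss_distance)
from .histone import classify_by_marks, lincrna_overlap
from .motifs import PWM, write_jaspar
from .seqs import extract_sequences

# gene template (all + frame offsets relative to the gene start / TSS)
GENE_LEN = 2000
EXONS = ((0, 400), (800, 1200), (1600, 2000))
UTR5 = (0, 150)
UTR3 = (1800, 2000)
PROM_BP = 2000
DOWN_BP = 2000
LPAD = 120       # minimum cassette left padding
RSPACER = 100    # spacer after each cassette
# competing-TSS clearance: a neighbor gene's TSS is always at least this
# deep inside its own cassette, measured from the cassette boundary
MIN_NEIGHBOR_TSS_DEPTH = 2120

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_pwms() -> list[tuple[str, str, str, float]]:
    """(motif_id, tf_family, consensus, per-OCR insertion probability)."""
    return [
        ("M_bHLH", "bHLH", "GCACGTGC", 0.50),
        ("M_bZIP", "bZIP", "ATGACGTC", 0.45),
        ("M_TCP", "TCP", "TGGGCCCA", 0.40),
        ("M_MYB", "MYB", "CAACCACC", 0.35),
        ("M_NAC", "NAC", "TTGCGTGT", 0.0),
        ("M_ERF", "AP2/ERF", "AGCCGCCA", 0.0),
    ]


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic genome.

    Headline fractions (category proportions, hOCR fraction, gene-linked
    fraction, distal unmodified fraction, LincRNA overlap) default to the
    values the analysis is meant to recover; layout constants and the
    expression model are the generator's own realism choices.
    """

    seed: int = 7
    n_chrom: int = 4              # homeologous pairs: chr_i <-> chr_{i + n/2}
    chrom_len: int = 500_000
    n_genes: int = 200
    n_ocrs: int = 400
    category_props: dict = field(default_factory=lambda: {
        "promoter": 0.6634, "five_utr": 0.0009, "three_utr": 0.0458,
        "exon": 0.023, "intron": 0.0186, "downstream": 0.0506,
        "distal_intergenic": 0.1977,
    })
    docr_distance_decay: float = 0.6   # geometric weight ratio across distance bins
    docr_distance_bins: tuple = ((2050, 4000), (4000, 8000), (8000, 16000))
    hocr_fraction: float = 0.403
    hocr_gene_linked_fraction: float = 0.80
    duplicate_identity: float = 0.95
    mark_probs_proximal: tuple = (0.47, 0.015, 0.175, 0.34)  # K4/K27/dual/unmod
    docr_unmodified_fraction: float = 0.65
    distal_modified_ratio: tuple = (0.22, 0.03, 0.10)        # K4/K27/dual weights
    lincrna_overlap_fraction: float = 0.036
    # expression model: log2(FPKM+1) = mu0 + beta_ocr*I(any OCR)
    #   + beta_synergy*I(pOCR & dOCR) + beta_k4*I(K4) - beta_k27*I(K27) + N(0, sigma)
    mu0: float = 2.0
    beta_ocr: float = 1.5
    beta_synergy: float = 1.0
    beta_k4: float = 1.5
    beta_k27: float = 2.0
    sigma: float = 0.8
    zero_fpkm_fraction: float = 0.15
    fpkm_high_threshold: float = 10.0
    n_asym_pairs: int = 16
    n_quiet_pairs: int = 3
    n_go_terms: int = 20
    planted_pwms: list = field(default_factory=default_pwms)

    def __post_init__(self):
        if self.n_chrom % 2:
            raise ValueError("n_chrom must be even (homeologous pairs)")
        s = sum(self.category_props.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"category proportions sum to {s}, not 1")
        for frac in (self.hocr_fraction, self.hocr_gene_linked_fraction,
                     self.duplicate_identity, self.docr_unmodified_fraction,
                     self.lincrna_overlap_fraction, self.zero_fpkm_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def mark_probs_distal(self) -> tuple:
        w = np.asarray(self.distal_modified_ratio, dtype=float)
        w = w / w.sum() * (1.0 - self.docr_unmodified_fraction)
        return (*w, self.docr_unmodified_fraction)


class CapacityError(RuntimeError):
    """The requested features do not fit the configured genome size."""


def largest_remainder(n: int, weights: Sequence[float]) -> np.ndarray:
    """Integer allocation of ``n`` by weights, deterministic rounding."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = n - base.sum()
    order = np.lexsort((np.arange(w.size), -rem))
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# plan structures
# ---------------------------------------------------------------------------

# zone -> OCR length range
_ZONE_LEN = {
    "prom0": (200, 300), "prom1": (200, 300), "distal": (200, 300),
    "downstream": (200, 250), "exon": (250, 300), "intron": (250, 300),
    "five_utr": (100, 100), "three_utr": (150, 150),
}
_ZONE_CATEGORY = {
    "prom0": "promoter", "prom1": "promoter", "distal": "distal_intergenic",
    "downstream": "downstream", "exon": "exon", "intron": "intron",
    "five_utr": "five_utr", "three_utr": "three_utr",
}


@dataclass
class _OcrPlan:
    id: str
    gene: str
    zone: str
    length: int
    distal_d: int = 0
    partner: str | None = None
    role: str | None = None       # "src" | "copy" for paired OCRs


@dataclass
class _GenePlan:
    id: str
    chrom: str
    role: str                      # linked1/linked2/asym1/asym2/quiet/src/tgt/free
    partner: str | None = None     # homologous gene (for pair roles)
    copy_of: str | None = None     # cassette copied from this gene (linked2)
    ocrs: list = field(default_factory=list)
    strand: str = "+"


def _sample_distal(spec: SimulationSpec, rng: np.random.Generator) -> int:
    bins = spec.docr_distance_bins
    w = np.array([spec.docr_distance_decay * (1 - spec.docr_distance_decay) ** i
                  for i in range(len(bins))])
    k = rng.choice(len(bins), p=w / w.sum())
    lo, hi = bins[k]
    return int(rng.integers(lo, hi))


def _build_plan(spec: SimulationSpec, rng: np.random.Generator):
    """Assign genes to chromosomes/roles and OCRs to gene zones."""
    counts = dict(zip(CATEGORIES, largest_remainder(
        spec.n_ocrs, [spec.category_props[c] for c in CATEGORIES])))
    n_pairs = round(spec.hocr_fraction * spec.n_ocrs / 2)
    n_pairs_distal = min(round(n_pairs * 0.25), counts["distal_intergenic"] // 2)
    n_pairs_prom = n_pairs - n_pairs_distal
    if 2 * n_pairs_prom > counts["promoter"]:
        raise CapacityError("not enough promoter OCRs to host the requested hOCR pairs")
    n_linked = round(spec.hocr_gene_linked_fraction * n_pairs)
    linked_distal = min(round(n_linked * (n_pairs_distal / n_pairs)) if n_pairs else 0,
                        n_pairs_distal)
    linked_prom = n_linked - linked_distal
    unlinked_prom = n_pairs_prom - linked_prom
    unlinked_distal = n_pairs_distal - linked_distal
    n_unlinked = unlinked_prom + unlinked_distal

    need = 2 * (n_linked + spec.n_asym_pairs + spec.n_quiet_pairs) + 2 * n_unlinked
    if need > spec.n_genes:
        raise CapacityError(f"{need} genes required for the requested pair structure, "
                            f"only {spec.n_genes} available")
    n_free = spec.n_genes - need

    groups = [(f"chr{i + 1}", f"chr{i + 1 + spec.n_chrom // 2}")
              for i in range(spec.n_chrom // 2)]
    gene_plans: dict[str, _GenePlan] = {}
    gid_counter = [0]

    def new_gene(chrom, role, partner=None, copy_of=None) -> _GenePlan:
        gid_counter[0] += 1
        g = _GenePlan(f"g{gid_counter[0]:04d}", chrom, role, partner, copy_of)
        gene_plans[g.id] = g
        return g

    pair_units = (["linked"] * n_linked + ["asym"] * spec.n_asym_pairs
                  + ["quiet"] * spec.n_quiet_pairs)
    for i, kind in enumerate(pair_units):
        c1, c2 = groups[i % len(groups)]
        role1, role2 = {"linked": ("linked1", "linked2"),
                        "asym": ("asym1", "asym2"),
                        "quiet": ("quiet", "quiet")}[kind]
        g1 = new_gene(c1, role1)
        g2 = new_gene(c2, role2, partner=g1.id,
                      copy_of=g1.id if kind == "linked" else None)
        g1.partner = g2.id

    src_genes, tgt_genes = [], []
    for i in range(n_unlinked):
        c1, c2 = groups[i % len(groups)]
        src_genes.append(new_gene(c1, "src"))
        tgt_genes.append(new_gene(c2, "tgt"))
    free_genes = []
    for i in range(n_free):
        grp = groups[i % len(groups)]
        free_genes.append(new_gene(grp[(i // len(groups)) % 2], "free"))

    # ---- OCR plans ----
    ocr_counter = [0]

    def new_ocr(gene: _GenePlan, zone: str, length=None, partner=None, role=None,
                distal_d=0) -> _OcrPlan:
        ocr_counter[0] += 1
        lo, hi = _ZONE_LEN[zone]
        L = int(length if length is not None else rng.integers(lo, hi + 1))
        o = _OcrPlan(f"OCR{ocr_counter[0]:05d}", gene.id, zone, L, distal_d,
                     partner, role)
        gene.ocrs.append(o)
        return o

    linked1 = [g for g in gene_plans.values() if g.role == "linked1"]
    linked2 = {g.copy_of: g for g in gene_plans.values() if g.role == "linked2"}
    # linked pair OCRs: first linked_prom promoter pairs, then distal pairs
    for i, g1 in enumerate(linked1):
        g2 = linked2[g1.id]
        if i < linked_prom:
            zone, d1, d2 = "prom0", 0, 0
        else:
            zone = "distal"
            d1 = _sample_distal(spec, rng)
            d2 = d1  # cassette copy preserves the distance
        o1 = new_ocr(g1, zone, role="src", distal_d=d1)
        o2 = new_ocr(g2, zone, length=o1.length, partner=o1.id, role="copy",
                     distal_d=d2)
        o1.partner = o2.id
    # unlinked pair OCRs: src gene -> copy near a non-homologous target gene
    for i, (gs, gt) in enumerate(zip(src_genes, tgt_genes)):
        zone = "prom0" if i < unlinked_prom else "distal"
        d1 = _sample_distal(spec, rng) if zone == "distal" else 0
        d2 = _sample_distal(spec, rng) if zone == "distal" else 0
        o1 = new_ocr(gs, zone, role="src", distal_d=d1)
        o2 = new_ocr(gt, zone, length=o1.length, partner=o1.id, role="copy",
                     distal_d=d2)
        o1.partner = o2.id

    # asym member-1 genes carry one single promoter OCR each
    prom_singles = counts["promoter"] - 2 * n_pairs_prom
    if prom_singles < spec.n_asym_pairs:
        raise CapacityError("not enough single promoter OCRs for asymmetric pairs")
    asym1 = [g for g in gene_plans.values() if g.role == "asym1"]
    for g in asym1:
        new_ocr(g, "prom0")
    prom_singles -= spec.n_asym_pairs

    # distribute remaining single OCRs over eligible hosts
    hosts = (linked1 + src_genes + tgt_genes + free_genes + asym1)
    used = {g.id: {o.zone for o in g.ocrs} for g in gene_plans.values()}

    def place(zone_options, count, distal=False):
        placed, h = 0, 0
        attempts = 0
        while placed < count:
            if attempts > len(hosts) * len(zone_options) + 10:
                raise CapacityError("cannot place all requested OCRs on the "
                                    "available genes; increase n_genes")
            g = hosts[h % len(hosts)]
            h += 1
            attempts += 1
            for zone in zone_options:
                if zone not in used[g.id]:
                    used[g.id].add(zone)
                    d = _sample_distal(spec, rng) if distal else 0
                    new_ocr(g, zone, distal_d=d)
                    placed += 1
                    attempts = 0
                    break
        return placed

    place(["prom0", "prom1"], prom_singles)
    place(["distal"], counts["distal_intergenic"] - 2 * n_pairs_distal, distal=True)
    place(["downstream"], counts["downstream"])
    place(["three_utr"], counts["three_utr"])
    place(["exon"], counts["exon"])
    place(["intron"], counts["intron"])
    place(["five_utr"], counts["five_utr"])

    meta = {
        "category_counts": {c: int(n) for c, n in counts.items()},
        "n_pairs": n_pairs, "n_linked": n_linked, "n_unlinked": n_unlinked,
        "n_pairs_prom": n_pairs_prom, "n_pairs_distal": n_pairs_distal,
    }
    return gene_plans, groups, meta


# ---------------------------------------------------------------------------
# cassette construction
# ---------------------------------------------------------------------------


def _zone_span(zone: str, L: int, tss_off: int, distal_d: int) -> tuple[int, int]:
    """OCR span (cassette offsets, + frame) for a zone."""
    if zone == "prom0":
        return tss_off - 1950, tss_off - 1950 + L
    if zone == "prom1":
        return tss_off - 1000, tss_off - 1000 + L
    if zone == "distal":
        return tss_off - distal_d - L, tss_off - distal_d
    if zone == "downstream":
        s = tss_off + GENE_LEN + 400
        return s, s + L
    if zone == "exon":
        s = tss_off + EXONS[1][0] + 50
        return s, s + L
    if zone == "intron":
        s = tss_off + EXONS[0][1] + 50
        return s, s + L
    if zone == "five_utr":
        s = tss_off + UTR5[0] + 25
        return s, s + L
    if zone == "three_utr":
        s = tss_off + UTR3[0] + 20
        return s, s + L
    raise ValueError(zone)


def _build_cassette(plan: _GenePlan, rng: np.random.Generator):
    """Cassette codes + relative feature coordinates (strand applied)."""
    distal = [o for o in plan.ocrs if o.zone == "distal"]
    left = LPAD
    if distal:
        o = distal[0]
        o_req = max(LPAD, o.distal_d - (MIN_NEIGHBOR_TSS_DEPTH - 300))
        left = max(LPAD, o_req + o.distal_d + o.length - PROM_BP)
    tss_off = left + PROM_BP
    length = left + PROM_BP + GENE_LEN + DOWN_BP + RSPACER
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    feats = {
        "gene": (tss_off, tss_off + GENE_LEN),
        "exons": [(tss_off + a, tss_off + b) for a, b in EXONS],
        "utr5": (tss_off + UTR5[0], tss_off + UTR5[1]),
        "utr3": (tss_off + UTR3[0], tss_off + UTR3[1]),
        "ocrs": {o.id: _zone_span(o.zone, o.length, tss_off, o.distal_d)
                 for o in plan.ocrs},
    }
    if plan.strand == "-":
        codes = (3 - codes)[::-1]
        m = lambda span: (length - span[1], length - span[0])
        feats = {
            "gene": m(feats["gene"]),
            "exons": [m(s) for s in feats["exons"]],
            "utr5": m(feats["utr5"]),
            "utr3": m(feats["utr3"]),
            "ocrs": {k: m(s) for k, s in feats["ocrs"].items()},
        }
    return codes, feats


def _cassette_len(plan: _GenePlan, gene_plans: dict) -> int:
    """Final cassette footprint in bp (copies mirror their source)."""
    p = gene_plans[plan.copy_of] if plan.copy_of else plan
    distal = [o for o in p.ocrs if o.zone == "distal"]
    left = LPAD
    if distal:
        o = distal[0]
        o_req = max(LPAD, o.distal_d - (MIN_NEIGHBOR_TSS_DEPTH - 300))
        left = max(LPAD, o_req + o.distal_d + o.length - PROM_BP)
    return left + PROM_BP + GENE_LEN + DOWN_BP + RSPACER


def _fit_budget(gene_plans: dict, by_chrom: dict, chrom_len: int,
                rng: np.random.Generator, margin: int = 1500):
    """Clamp the farthest distal distances until every chromosome fits.

    Distal distances are sampled from a decaying distribution whose tail
    occasionally overflows the chromosome; reassigning the largest
    distances to the nearest distance bin preserves every planted count
    while guaranteeing placement for any seed.
    """
    while True:
        totals = {c: sum(_cassette_len(g, gene_plans) for g in plans)
                  for c, plans in by_chrom.items()}
        over = [c for c, t in totals.items() if t > chrom_len - margin]
        if not over:
            return
        chrom = max(over, key=lambda c: totals[c])
        candidates = []
        for g in by_chrom[chrom]:
            src = gene_plans[g.copy_of] if g.copy_of else g
            for o in src.ocrs:
                if o.zone == "distal" and o.distal_d > 4000:
                    candidates.append(o)
        if not candidates:
            raise CapacityError(
                f"{chrom}: features need {totals[chrom]} bp > chrom_len "
                f"{chrom_len}; increase chrom_len or reduce n_genes/n_ocrs")
        worst = max(candidates, key=lambda o: o.distal_d)
        worst.distal_d = int(rng.integers(2050, 3500))


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = np.flatnonzero(rng.random(out.size) < rate)
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _triangle(arr: np.ndarray, start: int, end: int, height: float, step: int = 25):
    """Add a step-discretized triangular bump over [start, end)."""
    start, end = max(0, int(start)), min(arr.size, int(end))
    if end <= start:
        return
    n = end - start
    x = np.arange(n)
    tri = height * (1.0 - np.abs(x - (n - 1) / 2.0) / ((n - 1) / 2.0 + 1e-9))
    blocks = (x // step)
    for b in np.unique(blocks):
        mask = blocks == b
        arr[start + np.flatnonzero(mask)] += float(tri[mask].mean())


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    out_dir: Path
    paths: dict
    truth: dict


FILES = {
    "genome": "genome.fa", "gff": "genes.gff3", "ocrs": "ocrs.bed",
    "k4_peaks": "k4_peaks.bed", "k27_peaks": "k27_peaks.bed",
    "atac": "atac.bedgraph", "k4": "k4.bedgraph", "k27": "k27.bedgraph",
    "expression": "expression.tsv", "go": "go.tsv", "homologs": "homologs.tsv",
    "lincrnas": "lincrnas.bed", "pwms": "pwms.jaspar", "truth": "truth.json",
}


def simulate(spec: SimulationSpec, out_dir) -> SimulationResult:
    """Generate the file bundle and truth table for a simulation spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    gene_plans, groups, meta = _build_plan(spec, rng)

    # strands: free draw for non-copies; cassette copies keep the orientation
    for g in gene_plans.values():
        if g.copy_of is None:
            g.strand = "+" if rng.random() < 0.5 else "-"
    for g in gene_plans.values():
        if g.copy_of is not None:
            g.strand = gene_plans[g.copy_of].strand

    chroms = [c for pair in groups for c in pair]
    chroms.sort(key=lambda c: int(c[3:]))
    by_chrom: dict[str, list[_GenePlan]] = {c: [] for c in chroms}
    for g in gene_plans.values():
        by_chrom[g.chrom].append(g)
    for c in chroms:
        order = rng.permutation(len(by_chrom[c]))
        by_chrom[c] = [by_chrom[c][i] for i in order]
    _fit_budget(gene_plans, by_chrom, spec.chrom_len, rng)

    chrom_codes: dict[str, np.ndarray] = {}
    content_end: dict[str, int] = {}
    gene_abs: dict[str, dict] = {}
    ocr_abs: dict[str, GenomicInterval] = {}
    cassette_store: dict[str, tuple[np.ndarray, dict]] = {}
    ocr_plan_by_id = {o.id: o for g in gene_plans.values() for o in g.ocrs}

    for chrom in chroms:
        pos = 0
        chunks = []
        for g in by_chrom[chrom]:
            if g.copy_of is not None:
                src_codes, feats = cassette_store[g.copy_of]
                codes = _mutate(src_codes, 1.0 - spec.duplicate_identity, rng)
                # feature offsets identical; remap OCR ids to this gene's plans
                src_plan = gene_plans[g.copy_of]
                id_map = dict(zip([o.id for o in src_plan.ocrs],
                                  [o.id for o in g.ocrs]))
                feats = dict(feats)
                feats["ocrs"] = {id_map[k]: v for k, v in feats["ocrs"].items()
                                 if k in id_map}
            else:
                codes, feats = _build_cassette(g, rng)
                cassette_store[g.id] = (codes, feats)
            gs, ge = feats["gene"]
            gene_abs[g.id] = {
                "chrom": chrom, "start": pos + gs, "end": pos + ge,
                "strand": g.strand,
                "exons": [(pos + a, pos + b) for a, b in feats["exons"]],
                "utr5": (pos + feats["utr5"][0], pos + feats["utr5"][1]),
                "utr3": (pos + feats["utr3"][0], pos + feats["utr3"][1]),
            }
            for oid, (a, b) in feats["ocrs"].items():
                ocr_abs[oid] = GenomicInterval(chrom, pos + a, pos + b, ".", oid)
            chunks.append(codes)
            pos += codes.size
        if pos > spec.chrom_len:
            raise CapacityError(
                f"{chrom}: placed features span {pos} bp > chrom_len {spec.chrom_len}; "
                "increase chrom_len or reduce n_genes/n_ocrs")
        chunks.append(rng.integers(0, 4, size=spec.chrom_len - pos, dtype=np.uint8))
        chrom_codes[chrom] = np.concatenate(chunks)
        content_end[chrom] = pos

    # unlinked pair copies: overwrite the target OCR span with a mutated copy
    for o in ocr_plan_by_id.values():
        if o.role == "copy" and gene_plans[o.gene].role == "tgt":
            src = ocr_plan_by_id[ocr_plan_by_id[o.id].partner]
            siv, tiv = ocr_abs[src.id], ocr_abs[o.id]
            seq = chrom_codes[siv.chrom][siv.start:siv.end]
            chrom_codes[tiv.chrom][tiv.start:tiv.end] = _mutate(
                seq, 1.0 - spec.duplicate_identity, rng)

    # motif insertion: decisions and offsets are drawn once per OCR family
    # (an OCR and its duplicate share them, keeping pair identity high);
    # offsets are randomized per family so unrelated OCRs sharing the same
    # motifs cannot chain them into a significant local alignment
    from .seqs import encode as _encode
    active = [(mid, fam, cons, p) for mid, fam, cons, p in spec.planted_pwms if p > 0]
    planted_motifs: dict[str, list[str]] = {oid: [] for oid in ocr_abs}
    family_of = {o.id: (o.id if o.role != "copy" else o.partner)
                 for o in ocr_plan_by_id.values()}
    layout: dict[str, list[tuple[int, str, str]]] = {}  # fam_key -> (offset, id, cons)
    for oid in sorted(ocr_abs):
        fam_key = family_of[oid]
        if fam_key not in layout:
            chosen = [(mid, cons) for mid, _f, cons, p in active if rng.random() < p]
            L = len(ocr_abs[oid])
            placed: list[tuple[int, str, str]] = []
            for mid, cons in chosen:
                for _ in range(200):  # rejection-sample a non-overlapping offset
                    off = int(rng.integers(12, L - len(cons) - 12))
                    if all(off + len(cons) + 4 <= o or o + len(c) + 4 <= off
                           for o, _m, c in placed):
                        placed.append((off, mid, cons))
                        break
            layout[fam_key] = sorted(placed)
        iv = ocr_abs[oid]
        for off, mid, cons in layout[fam_key]:
            s = iv.start + off
            chrom_codes[iv.chrom][s:s + len(cons)] = _encode(cons)
            planted_motifs[oid].append(mid)

    # ---- histone classes (exact counts per locality stratum) ----
    ids_sorted = sorted(ocr_abs)
    distal_ids = [oid for oid in ids_sorted if ocr_plan_by_id[oid].zone == "distal"]
    other_ids = [oid for oid in ids_sorted if ocr_plan_by_id[oid].zone != "distal"]
    class_names = ("K4_only", "K27_only", "dual", "unmodified")
    classes: dict[str, str] = {}
    for ids, probs in ((distal_ids, spec.mark_probs_distal()),
                       (other_ids, spec.mark_probs_proximal)):
        cnt = largest_remainder(len(ids), probs)
        labels = np.repeat(class_names, cnt)
        labels = labels[rng.permutation(labels.size)]
        classes.update(dict(zip(ids, labels)))

    k4_peaks, k27_peaks = [], []
    peak_heights: dict[str, list] = {"k4": [], "k27": []}
    for oid in ids_sorted:
        iv = ocr_abs[oid]
        cls = classes[oid]
        L = len(iv)
        if cls in ("K4_only", "dual"):
            frac = rng.uniform(0.6, 0.9) if cls == "K4_only" else rng.uniform(0.55, 0.95)
            w = max(20, int(frac * L))
            s = iv.start + int(rng.integers(0, L - w + 1))
            k4_peaks.append(GenomicInterval(iv.chrom, s, s + w, ".", f"{oid}_K4"))
            peak_heights["k4"].append((iv.chrom, s, s + w, rng.uniform(2, 5)))
        if cls in ("K27_only", "dual"):
            if cls == "dual":
                k4_frac = (k4_peaks[-1].end - k4_peaks[-1].start) / L
                frac = rng.uniform(0.10, max(0.12, k4_frac - 0.1))
            else:
                frac = rng.uniform(0.5, 0.9)
            w = max(20, int(frac * L))
            s = iv.start + int(rng.integers(0, L - w + 1))
            k27_peaks.append(GenomicInterval(iv.chrom, s, s + w, ".", f"{oid}_K27"))
            peak_heights["k27"].append((iv.chrom, s, s + w, rng.uniform(2, 5)))

    # ---- expression ----
    gene_ids = sorted(gene_abs)
    ocrs_of_gene: dict[str, list[str]] = {gid: [] for gid in gene_ids}
    for o in ocr_plan_by_id.values():
        ocrs_of_gene[o.gene].append(o.id)
    fpkm: dict[str, float] = {}
    for gid in gene_ids:
        oids = ocrs_of_gene[gid]
        zones = {ocr_plan_by_id[o].zone for o in oids}
        has_p = bool(zones & {"prom0", "prom1"})
        has_d = "distal" in zones
        has_any = bool(oids)
        k4 = any(classes[o] in ("K4_only", "dual") for o in oids)
        k27 = any(classes[o] in ("K27_only", "dual") for o in oids)
        x = (spec.mu0 + spec.beta_ocr * has_any + spec.beta_synergy * (has_p and has_d)
             + spec.beta_k4 * k4 - spec.beta_k27 * k27 + rng.normal(0, spec.sigma))
        fpkm[gid] = max(0.0, 2.0 ** x - 1.0)
    n_zero = round(spec.zero_fpkm_fraction * len(gene_ids))
    for gid in rng.choice(gene_ids, size=n_zero, replace=False):
        fpkm[gid] = 0.0

    # ---- signal tracks ----
    tracks = {name: {c: np.zeros(spec.chrom_len, dtype=np.float32) for c in chroms}
              for name in ("atac", "k4", "k27")}
    for oid in ids_sorted:
        iv = ocr_abs[oid]
        _triangle(tracks["atac"][iv.chrom], iv.start - 50, iv.end + 50, 3.0)
    for name in ("k4", "k27"):
        for chrom, s, e, h in peak_heights[name]:
            _triangle(tracks[name][chrom], s, e, h)
    for gid in gene_ids:
        ga = gene_abs[gid]
        t = ga["start"] if ga["strand"] == "+" else ga["end"] - 1
        lf = np.log2(fpkm[gid] + 1.0)
        _triangle(tracks["atac"][ga["chrom"]], t - 500, t + 500, 0.3 + 1.5 * lf)
        _triangle(tracks["k4"][ga["chrom"]], t - 500, t + 500, 0.3 + 1.2 * lf)
        k27_amp = 5.0 if fpkm[gid] == 0 else max(0.1, 1.5 - 0.4 * lf)
        _triangle(tracks["k27"][ga["chrom"]], t - 500, t + 500, k27_amp)

    # ---- LincRNAs over a planted fraction of dOCRs ----
    docr_ids = list(distal_ids)
    n_linc = round(spec.lincrna_overlap_fraction * len(docr_ids))
    linc_hits = sorted(rng.choice(docr_ids, size=n_linc, replace=False)) if n_linc else []
    lincrnas = []
    for i, oid in enumerate(linc_hits):
        iv = ocr_abs[oid]
        lincrnas.append(GenomicInterval(iv.chrom, max(0, iv.start - 150),
                                        iv.end + 150, ".", f"LINC{i + 1:03d}"))
    # decoy LincRNAs in the gene-free chromosome tails
    for j, chrom in enumerate(chroms):
        start = content_end[chrom] + 500 + 600 * j
        if start + 400 < spec.chrom_len:
            lincrnas.append(GenomicInterval(chrom, start, start + 400, ".",
                                            f"LINCD{j + 1:02d}"))

    # ---- homolog table, GO ----
    homolog_pairs = sorted(
        {tuple(sorted((g.id, g.partner))) for g in gene_plans.values()
         if g.partner is not None and g.role in ("linked1", "linked2",
                                                 "asym1", "asym2", "quiet")})
    go_pool = [f"GO:{i + 1:07d}" for i in range(spec.n_go_terms)]
    gene_go = {gid: sorted(rng.choice(go_pool, size=int(rng.integers(1, 4)),
                                      replace=False)) for gid in gene_ids}

    # ---- truth ----
    truth_ocrs = {}
    for oid in ids_sorted:
        o = ocr_plan_by_id[oid]
        iv = ocr_abs[oid]
        ga = gene_abs[o.gene]
        # signed TSS distance by construction geometry
        cat = _ZONE_CATEGORY[o.zone]
        truth_ocrs[oid] = {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "category": cat,
            "locality": ("pOCR" if cat == "promoter"
                         else "dOCR" if cat == "distal_intergenic" else "genic"),
            "gene": o.gene, "mark_class": classes[oid],
            "partner": o.partner, "motifs": planted_motifs[oid],
            "distal_d": o.distal_d,
        }
    truth = {
        "seed": spec.seed,
        "meta": meta,
        "ocrs": truth_ocrs,
        "genes": {gid: {**{k: v for k, v in gene_abs[gid].items()
                           if k in ("chrom", "start", "end", "strand")},
                        "fpkm": fpkm[gid],
                        "homolog": gene_plans[gid].partner,
                        "role": gene_plans[gid].role,
                        "has_ocr": bool(ocrs_of_gene[gid])}
                  for gid in gene_ids},
        "homolog_pairs": [list(p) for p in homolog_pairs],
        "summary": {
            "category_counts": meta["category_counts"],
            "mark_counts": {c: sum(v == c for v in classes.values())
                            for c in class_names},
            "docr_mark_counts": {c: sum(classes[i] == c for i in distal_ids)
                                 for c in class_names},
            "n_docrs": len(distal_ids),
            "hocr_fraction": 2 * meta["n_pairs"] / spec.n_ocrs,
            "gene_linked_fraction": (meta["n_linked"] / meta["n_pairs"]
                                     if meta["n_pairs"] else 0.0),
            "lincrna_overlap": (n_linc / len(docr_ids) if docr_ids else 0.0),
            "n_asym_pairs": spec.n_asym_pairs,
            "duplicate_identity": spec.duplicate_identity,
        },
    }

    paths = {k: out_dir / v for k, v in FILES.items()}
    _write_fasta(paths["genome"], chrom_codes)
    _write_gff3(paths["gff"], gene_abs, gene_ids)
    _write_bed(paths["ocrs"], [ocr_abs[o] for o in ids_sorted])
    _write_bed(paths["k4_peaks"], k4_peaks)
    _write_bed(paths["k27_peaks"], k27_peaks)
    _write_bed(paths["lincrnas"], lincrnas)
    from .signal import SignalTrack
    for name in ("atac", "k4", "k27"):
        SignalTrack.from_arrays(tracks[name]).to_bedgraph(paths[name])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gid in gene_ids:
            fh.write(f"{gid}\t{fpkm[gid]:.4f}\n")
    with open(paths["go"], "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gid in gene_ids:
            for go in gene_go[gid]:
                fh.write(f"{gid}\t{go}\n")
    with open(paths["homologs"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in homolog_pairs:
            fh.write(f"{a}\t{b}\n")
    write_jaspar([PWM.from_consensus(mid, fam, cons)
                  for mid, fam, cons, _p in spec.planted_pwms], paths["pwms"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return SimulationResult(out_dir, paths, truth)


def _write_fasta(path, chrom_codes):
    with open(path, "w") as fh:
        for chrom in sorted(chrom_codes, key=lambda c: int(c[3:])):
            fh.write(f">{chrom}\n")
            seq = _DECODE[chrom_codes[chrom]].tobytes().decode("ascii")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _write_gff3(path, gene_abs, gene_ids):
    rows = []
    for gid in gene_ids:
        g = gene_abs[gid]
        rows.append((g["chrom"], g["start"], g["end"], g["strand"], gid, g))
    rows.sort(key=lambda r: (int(r[0][3:]), r[1]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, strand, gid, g in rows:
            fh.write(f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(f"{chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                     f"ID={tid};Parent={gid}\n")
            for a, b in g["exons"]:
                fh.write(f"{chrom}\tsim\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t"
                         f"Parent={tid}\n")
            u5, u3 = g["utr5"], g["utr3"]
            fh.write(f"{chrom}\tsim\tfive_prime_UTR\t{u5[0] + 1}\t{u5[1]}\t.\t"
                     f"{strand}\t.\tParent={tid}\n")
            fh.write(f"{chrom}\tsim\tthree_prime_UTR\t{u3[0] + 1}\t{u3[1]}\t.\t"
                     f"{strand}\t.\tParent={tid}\n")


def _write_bed(path, intervals):
    ivs = sorted(intervals, key=lambda v: (int(v.chrom[3:]), v.start))
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def verify_truth(out_dir, truth: dict | None = None) -> dict:
    """Re-read an emitted bundle and check it against its truth table.

    Returns per-assertion pass/fail plus an ``all_pass`` flag. Checks:
    files present; re-annotated categories match the planted ones (>= 99%,
    counts exactly); histone classes from peak overlap equal the planted
    classes; homologous OCR pairs keep at least the planted sequence
    identity (minus 3 binomial SEs); FPKM nonnegative for every gene;
    LincRNA–dOCR overlap fraction equals the planted fraction.
    """
    out_dir = Path(out_dir)
    paths = {k: out_dir / v for k, v in FILES.items()}
    report: dict[str, bool] = {}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"bundle incomplete: {missing}")
    if truth is None:
        truth = json.loads(paths["truth"].read_text())

    genes = parse_gff3(paths["gff"])
    ocrs = read_bed(paths["ocrs"])
    ann = annotate_ocrs(ocrs, genes)
    planted = truth["ocrs"]
    match = sum(a.category == planted[a.id]["category"] for a in ann)
    report["category_recovery_ge_99pct"] = match >= 0.99 * len(ann)
    got_counts: dict[str, int] = {}
    for a in ann:
        got_counts[a.category] = got_counts.get(a.category, 0) + 1
    want = truth["summary"]["category_counts"]
    report["category_counts_exact"] = all(
        got_counts.get(c, 0) == want[c] for c in want)

    k4 = read_bed(paths["k4_peaks"])
    k27 = read_bed(paths["k27_peaks"])
    cls = classify_by_marks(ocrs, k4, k27)
    report["mark_classes_exact"] = all(
        cls[oid] == planted[oid]["mark_class"] for oid in cls)

    seqs = extract_sequences(paths["genome"], ocrs)
    ident_ok = True
    planted_ident = truth["summary"].get("duplicate_identity", 0.95)
    mut = 1.0 - planted_ident
    for oid, rec in planted.items():
        p = rec["partner"]
        if p is None or oid > p:
            continue
        if oid not in seqs or p not in seqs:
            ident_ok = False
            continue
        a, b = seqs[oid], seqs[p]
        if len(a) != len(b):
            ident_ok = False
            continue
        ident = float(np.mean(np.frombuffer(a.encode(), np.uint8)
                              == np.frombuffer(b.encode(), np.uint8)))
        se = 3 * np.sqrt(mut * (1 - mut) / len(a)) if 0 < mut < 1 else 0.0
        if ident < planted_ident - se - 0.01:
            ident_ok = False
    report["pair_identity"] = ident_ok

    import pandas as pd
    expr = pd.read_csv(paths["expression"], sep="\t")
    report["fpkm_nonnegative"] = bool((expr.fpkm >= 0).all())
    report["expression_covers_genes"] = set(expr.gene_id) == {g.id for g in genes}

    docrs = [a for a in ann if a.locality == "dOCR"]
    linc = read_bed(paths["lincrnas"])
    if docrs:
        _, frac = lincrna_overlap(docrs, linc)
        report["lincrna_overlap_planted"] = (
            abs(frac - truth["summary"]["lincrna_overlap"]) < 0.5 / len(docrs) + 1e-9)
    report["all_pass"] = all(report.values())
    return report
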