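# Methods

`ocrlandscape` reimplements, at desk scale, the downstream analysis of an
ATAC-seq open-chromatin study on a paleopolyploid plant genome: feature
annotation of open chromatin regions (OCRs), coupling of accessibility and
histone marks to expression, transcription-factor motif enrichment, distal
enhancer calling, and detection of homologous OCRs retained from
whole-genome duplication (WGD). Because the original sequencing data are
not required, a first-class synthetic-genome generator supplies every
input with planted ground truth; all quantitative claims in this note are
computed by the test suite or by `scripts/acceptance.py`, nothing is
transcribed from elsewhere.

## Coordinates and annotation

All intervals are 0-based half-open (BED convention); GFF3 input (1-based
closed) is converted on read, and one gene model per gene is kept (the
longest transcript). The TSS is `start` on the + strand and `end − 1` on
the − strand.

Signed TSS distance is 0 when the OCR overlaps the TSS base; otherwise it
is the offset of the OCR boundary nearest the TSS, negative upstream in
gene orientation. Minus-strand genes are handled by reflecting both
operands into the + frame, so the convention is exactly strand-symmetric
(a property the suite tests directly).

Each OCR receives exactly one of seven categories by a fixed priority —
promoter > 5′UTR > 3′UTR > exon > intron > downstream > distal intergenic
— the ChIPseeker-style convention. The promoter window is the 2 kb
immediately upstream of the TSS; the downstream window mirrors it past the
TES; both are configurable, but 2 kb is also the boundary that defines
distal OCRs (dOCRs: distal-intergenic category with TSS distance below
−2 kb), so the default is load-bearing. Nearest genes are chosen by
minimal |TSS distance| with lexicographic gene-id tie-breaking. Interval
joins run on `intervaltree`; a quadratic all-pairs oracle checks them in
the tests.

## Signal tracks and metaprofiles

Signal is a nonnegative step function per chromosome (bedGraph
semantics), stored with a breakpoint prefix integral so means, covered
fractions and binned matrices are exact rather than per-base
approximations. The scaled metaprofile anchors genes at TSS and TES,
rescales each body to 100 bins, bins ±2-kb flanks at 50 bp, reverses
minus-strand rows, and groups genes into FPKM quintiles plus a zero-FPKM
class. Bin widths and flanks are conventional choices (the underlying
study does not state its heatmap parameters) and are configurable; empty
bins report 0.

## Histone integration

OCR classes (K4-only / K27-only / dual / unmodified) come from ≥1-bp
overlap with H3K4me3/H3K27me3 peak sets; the threshold is configurable
but the four classes always partition the OCR set. Clustering of binned
mark signal uses k-means (scikit-learn; Lloyd with k-means++ seeding,
best of `n_init` restarts, deterministic given a seed) with k = 2, the
higher-total-signal cluster labelled I so the unmodified cluster is
always II. The default feature space is ±1 kb around the OCR midpoint in
50-bp bins, per-row max-normalized, both marks concatenated. Within dual
OCRs, K4 vs K27 covered fractions are compared with a *paired* one-sided
Wilcoxon signed-rank test — pairing by OCR is the natural design even
though the original figures show only distributions. Expression contrasts
between classes use the Wilcoxon rank-sum test on deduplicated
nearest-gene FPKM vectors.

## Motif analysis

PWMs (JASPAR text, read via Biopython) are scanned by log-odds scoring
against a uniform background after adding a 0.01 pseudocount and
renormalizing; a window is a hit at ≥ 0.8 of the motif's maximum score
(fraction-of-maximum is deterministic and simple; the threshold is
exposed). Both strands are scanned; N-containing windows are skipped.
Enrichment is per-motif Fisher's exact test on "sequence has ≥1 hit"
counts, OCRs against a background of one dinucleotide-preserving shuffle
per OCR sequence (Altschul–Erikson random Eulerian walk, seeded) —
shuffling controls composition where the study leaves its background
unstated — with Benjamini–Hochberg correction and an enriched call at
q < 0.05 and odds ratio > 1. The regulatory network connects enriched
motif families (best member by q) to GO terms through nearest-gene links;
a GO node is "core" at in-degree ≥ 4. Cotargeting reports the 7-region
Venn partition of the top three families' target-gene sets.

## Homology and duplication

Homologous OCRs (hOCRs) are sequence-similar OCR pairs on *different*
chromosomes with Karlin–Altschul E below 1e-5. Alignment is in-package
affine-gap Smith–Waterman with blastn-like scoring (match +1, mismatch −2,
gap −5 open / −2 per additional base; N is a mismatch); a numba-compiled
linear-memory kernel scores pairs, and a traceback variant returns aligned
spans (ties diagonal > up > left). Biopython's `PairwiseAligner` serves as
an independent oracle in the tests only. E = K·m·n·exp(−λS) with K = 0.1,
λ = 1.0 and the pairwise search space m = len(a), n = len(b); the pairwise
(rather than query-vs-database) space keeps the statistic symmetric in the
two sequences, which the pair semantics require. Both orientations are
scored; each OCR retains its best partner; same-chromosome duplicates are
collected separately and excluded from hOCR statistics.

By default the all-vs-all search is preceded by a shared-k-mer prefilter
(canonical 12-mers): at the E < 1e-5 threshold a significant pair of
~250-bp sequences needs a raw score around 21, far above what sequences
sharing no 12-mer can reach, while duplicates at ≥ 90% identity share
dozens. `prefilter=False` forces the literal all-vs-all comparison and is
tested to give the identical pair set.

Gene homology is consumed as an input table, never inferred. Relation
classes (hOCR–hGene vs hOCR–non-hGene) use nearest genes; asymmetric
pairs are homologous gene pairs with an OCR on exactly one member, their
expression compared by Wilcoxon on FPKM. Histone antagonism uses the
stated FPKM thresholds (> 10 highly expressed, = 0 silent) and mean mark
signal at TSS ± 1 kb.

## Statistics

`stats` wraps scipy/statsmodels behind explicit contracts: Wilcoxon
rank-sum uses the exact null distribution when the pooled sample is ≤ 25
and tie-free, otherwise a midrank normal approximation with tie and
continuity corrections, and the result records which method ran; Fisher's
exact two-sided p sums hypergeometric probabilities ≤ the observed one;
Spearman is Pearson on midranks (undefined, and an error, for constant
input); Benjamini–Hochberg is the standard step-up. The suite checks all
of these against independent enumeration oracles and verifies an
empirical type-I error in [0.03, 0.07] at α = 0.05 over 2000 null
simulations.

## The synthetic genome

The generator emulates the *processed products* of the study — peaks,
signal tracks, an FPKM table, homolog and GO tables — on a small genome,
not reads or realistic nucleotide composition.

Layout. Four 500-kb chromosomes form two homeologous pairs. Each gene
occupies a "cassette": optional distal zone, 2-kb promoter, a 2-kb gene
body (3 exons, 150-bp 5′UTR, 200-bp 3′UTR), 2-kb downstream zone, spacer.
Cassettes of minus-strand genes are built in the + frame and mirrored, so
strand handling is uniform. OCR placements are chosen so that each OCR
overlaps exactly one feature and its planted nearest gene is
unambiguous (distal zones get extra padding so a neighbor's TSS can never
be closer than the host's); per-category counts follow the study's
reported proportions by largest-remainder rounding, exactly — so the
annotation acceptance check is tight while sequence content stays random.

Duplication. A planted fraction of OCRs (40.3% by default) have a
homologous partner: for gene-linked pairs (80% of pairs) the whole
cassette — gene plus OCR — is copied onto the homeolog chromosome with
independent per-base substitution at 1 − identity (identity 0.95), so the
gene pair, the OCR pair and their conserved locality arise from one copy
event, mimicking WGD retention. Non-gene-linked pairs copy only the OCR
sequence into the neighborhood of an unrelated gene. Homologous gene
pairs without shared OCRs provide asymmetric pairs (one member gets an
OCR) and quiet pairs (neither does).

Marks and signal. Histone classes are assigned per locality stratum by
exact-count rounding — distal OCRs pin the 65% unmodified default, other
OCRs a mix derived from the study's genome-wide class counts — and peaks
are drawn inside each OCR (dual OCRs get stochastically wider K4 than K27
peaks). Tracks are step-discretized triangular kernels over peaks plus
TSS bumps whose amplitudes follow expression (K4 and ATAC increasing with
log-FPKM, K27 high only for silent genes); kernel shape is irrelevant to
every tested statistic, only means and coverage matter.

Expression. log2(FPKM+1) = μ0 + β_OCR·I(any OCR) + β_syn·I(pOCR ∧ dOCR)
+ β_K4·I(K4) − β_K27·I(K27) + N(0, σ²), with μ0 = 2, β_OCR = 1.5,
β_syn = 1, β_K4 = 1.5, β_K27 = 2, σ = 0.8, and 15% of genes forced to
FPKM = 0 afterwards. The coefficients are generator choices made once for
a realistic FPKM spread (medians in the tens, a silent class) and planted
effect directions; the explicit synergy term plants the
promoter-plus-distal expression boost as its own effect rather than
leaving it implied. Motif consensus sequences are inserted into OCRs at
per-family probabilities (four active families, two inert) at random
non-overlapping offsets; an OCR and its duplicate share insertion
decisions and offsets so duplication identity is preserved, while
unrelated OCRs sharing motifs cannot chain them into a spuriously
significant alignment.

Feasibility. Cassette footprints are computed before building; if a
chromosome would overflow, the largest distal distances are re-drawn into
the nearest distance bin (all planted counts unchanged), and a hard
capacity error is raised only when even that cannot fit. Every output is
byte-reproducible from the seed, and `verify_truth` re-reads a bundle
with the package's own readers and checks every planted assertion.

What passing tests do and do not show: the generator plants clean,
unambiguous features — real data have overlapping genes, alternative
TSSs, fractional peak overlaps, copy-number variation and
composition-biased backgrounds, so recovery here demonstrates
correctness of the implementations under the stated models, not
robustness to messy genomes.

## Problem sizes and defaults

Default study conditions: 4 × 500 kb chromosomes, 200 genes, 400 OCRs,
seed-reproducible. At this scale the full pipeline runs in seconds and
the homology stage (prefiltered Smith–Waterman over 400 OCR sequences,
both orientations) in about a second. The direction checks that need
~200 units per group use their own stated conditions (balanced mark
probabilities for the class-expression contrast; 486 genes / 200
asymmetric pairs on 1.05-Mb chromosomes for the pair-expression
contrast), chosen once as the comparison's sample-size requirements.

## Known limitations

- One transcript per gene; no alternative TSSs or overlapping gene
  handling beyond annotation priority.
- The E-value calibration (K, λ) is nominal for the scoring scheme, not
  fitted; the threshold behaves correctly relative to the planted null
  and is configurable.
- The LincRNA analysis only measures interval overlap; no transcription
  of enhancer RNAs is modeled.
- GO terms are opaque labels consumed from a table; no ontology structure
  or enrichment testing on GO itself.
- k-means at k = 2 is the stated clustering; no model selection over k.
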