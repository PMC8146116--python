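"""Annotate open chromatin regions against gene models.

Generates a small synthetic duplicated genome, assigns every OCR one
genomic-feature category (promoter, UTRs, exon, intron, downstream or
distal intergenic), links it to its nearest gene by signed TSS distance,
and tallies the distal OCRs by distance bin.
"""

import tempfile

from ocrlandscape.intervals import (annotate_ocrs, category_proportions,
                                    distance_histogram, parse_gff3, read_bed)
from ocrlandscape.simulate import SimulationSpec, simulate

bundle = simulate(SimulationSpec(seed=7), tempfile.mkdtemp(prefix="ocr_example_"))
genes = parse_gff3(bundle.paths["gff"])
ocrs = read_bed(bundle.paths["ocrs"])

annotated = annotate_ocrs(ocrs, genes, promoter_bp=2000)

print(f"{len(ocrs)} OCRs annotated against {len(genes)} genes")
print("\nCategory shares (fraction of all OCRs):")
for cat, frac in category_proportions(annotated).items():
    print(f"  {cat:18s} {100 * frac:6.2f}%")

docrs = [a for a in annotated if a.locality == "dOCR"]
counts, edges = distance_histogram(docrs)
print(f"\n{len(docrs)} distal OCRs (beyond the 2-kb promoter window); "
      "|TSS distance| histogram:")
for lo, hi, c in zip(edges[:-1], edges[1:], counts):
    if c:
        print(f"  {int(lo) // 1000:3d}-{int(hi) // 1000}-kb bin: {c}")
print("\nMost OCRs sit in promoters; distal OCRs (putative enhancers) "
      "concentrate within a few kb of their target TSS.")
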