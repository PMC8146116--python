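"""Motif enrichment at OCRs and the TF -> GO regulatory network.

Scans JASPAR-style PWMs over OCR sequences, tests each motif against a
dinucleotide-shuffled background (Fisher exact + Benjamini–Hochberg),
builds the motif-family -> GO-term network from nearest-gene links, and
counts genes cotargeted by the top three enriched families.
"""

import tempfile

import pandas as pd

from ocrlandscape.intervals import annotate_ocrs, parse_gff3, read_bed
from ocrlandscape.motifs import (build_network, cotarget_sets, has_hit,
                                 motif_enrichment, motif_gene_targets, read_jaspar)
from ocrlandscape.seqs import extract_sequences
from ocrlandscape.simulate import SimulationSpec, simulate

bundle = simulate(SimulationSpec(seed=7), tempfile.mkdtemp(prefix="ocr_example_"))
ocrs = read_bed(bundle.paths["ocrs"])
seqs = extract_sequences(bundle.paths["genome"], ocrs)
pwms = read_jaspar(bundle.paths["pwms"])

results = motif_enrichment(seqs, None, pwms, alpha=0.05, seed=7)
print(f"{sum(r.enriched for r in results)}/{len(results)} motifs enriched "
      "vs shuffled background:")
for r in results:
    flag = "*" if r.enriched else " "
    print(f" {flag} {r.motif_id:8s} ({r.tf_family:8s}) hits {r.n_ocr_hit:3d} fg "
          f"vs {r.n_bg_hit:3d} bg, q = {r.q:.2e}")

ann = annotate_ocrs(ocrs, parse_gff3(bundle.paths["gff"]))
enriched = sorted((r for r in results if r.enriched), key=lambda r: r.q)
pwm_by_id = {p.motif_id: p for p in pwms}
hit_ocrs = {r.tf_family: {n for n, s in seqs.items()
                          if has_hit(s, pwm_by_id[r.motif_id])} for r in enriched}
targets = motif_gene_targets(hit_ocrs, ann)

go = pd.read_csv(bundle.paths["go"], sep="\t")
gene_go = go.groupby("gene_id").go_id.apply(set).to_dict()
net = build_network(targets, gene_go)
core = [n for n, d in net.nodes(data=True) if d.get("go_class") == "core"]
print(f"\nNetwork: {net.number_of_edges()} motif->GO edges, "
      f"{len(core)} core GO terms (targeted by >= 4 motif families)")

fams = [r.tf_family for r in enriched[:3]]
venn = cotarget_sets(targets[fams[0]], targets[fams[1]], targets[fams[2]])
print(f"Top-3 families {fams}: {venn['ABC']} genes cotargeted by all three "
      f"(Venn regions: {venn})")
print("\nA handful of TF families dominate the accessible regulatory space "
      "and converge on shared target pathways.")
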