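"""Classify OCRs by histone marks and relate the classes to expression.

Overlaps OCRs with H3K4me3 (activation) and H3K27me3 (repression) ChIP
peaks into K4-only / K27-only / dual / unmodified classes, compares mark
coverage inside dual OCRs, and tests expression differences between the
gene sets behind each class.
"""

import tempfile

import numpy as np
import pandas as pd

from ocrlandscape.histone import (classify_by_marks, class_counts,
                                  dual_coverage_compare, expression_by_class)
from ocrlandscape.intervals import annotate_ocrs, parse_gff3, read_bed
from ocrlandscape.simulate import SimulationSpec, simulate

bundle = simulate(SimulationSpec(seed=7), tempfile.mkdtemp(prefix="ocr_example_"))
genes = parse_gff3(bundle.paths["gff"])
expr = pd.read_csv(bundle.paths["expression"], sep="\t")
for g in genes:
    g.fpkm = float(dict(zip(expr.gene_id, expr.fpkm))[g.id])
ocrs = read_bed(bundle.paths["ocrs"])
k4 = read_bed(bundle.paths["k4_peaks"])
k27 = read_bed(bundle.paths["k27_peaks"])

classes = classify_by_marks(ocrs, k4, k27)
print("Histone classes:", class_counts(classes))

dual = [iv for iv in ocrs if classes[iv.name] == "dual"]
cov, test = dual_coverage_compare(dual, k4, k27)
print(f"\nDual OCRs (n={len(dual)}): mean K4 coverage {cov.frac_K4.mean():.2f} vs "
      f"K27 {cov.frac_K27.mean():.2f} (paired one-sided p = {test.p:.2e})")

ann = annotate_ocrs(ocrs, genes)
fpkm_by_class, tests = expression_by_class(classes, ann, {g.id: g for g in genes})
print("\nMedian FPKM of genes behind each OCR class:")
for cls, v in sorted(fpkm_by_class.items()):
    print(f"  {cls:11s} {np.median(v):8.2f}  (n={v.size})")
for name, t in tests.items():
    if t is not None:
        print(f"  Wilcoxon {name}: p = {t.p:.3g}")
print("\nActivation-marked (K4) OCRs sit next to the most expressed genes; "
      "dual-marked OCRs flank significantly less expressed, poised loci. "
      "(At these defaults only a handful of OCRs are K27-only, so that "
      "contrast has little power.)")
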