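"""End-to-end orchestration: annotate → profiles → histone → motif → homology.

Each stage consumes the standard-format files named in a
:class:`PipelineConfig`, writes its tabular output plus a small JSON
sidecar into the output directory, and contributes to a single
:func:`run_pipeline` summary report. Stages whose outputs already exist
are skipped on rerun (unless forced), and the report is a pure
aggregation of the per-stage files, so reruns with fixed seeds are
idempotent. A missing optional input (e.g. the expression table)
degrades gracefully: dependent fields are reported absent rather than
failing the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import histone as hist
from . import homology as homo
from . import motifs as mot
from .intervals import (annotate_ocrs, annotation_frame, category_proportions,
                        distance_histogram, parse_gff3, read_bed)
from .seqs import extract_sequences
from .signal import SignalTrack, anchored_matrix, scaled_metaprofile
from .stats import spearman


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a pipeline run."""

    gff: str
    ocrs: str
    out_dir: str
    genome: str | None = None
    k4_peaks: str | None = None
    k27_peaks: str | None = None
    atac: str | None = None
    k4_track: str | None = None
    k27_track: str | None = None
    expression: str | None = None
    go: str | None = None
    homologs: str | None = None
    lincrnas: str | None = None
    pwms: str | None = None
    promoter_bp: int = 2000
    downstream_bp: int = 2000
    threshold_frac: float = 0.8
    evalue_max: float = 1e-5
    alpha: float = 0.05
    fpkm_high: float = 10.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_expression(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def _load_gene_go(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gid, go in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(gid, set()).add(go)
    return out


def _load_homologs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run all configured stages and return the summary report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # --- shared inputs -----------------------------------------------------
    genes = parse_gff3(config.gff)
    gene_by_id = {g.id: g for g in genes}
    ocrs = read_bed(config.ocrs)
    expr = _load_expression(config.expression) if config.expression else None
    if expr:
        for g in genes:
            g.fpkm = expr.get(g.id, float("nan"))

    # --- stage: annotate ---------------------------------------------------
    ann_path = out / "annotation.tsv"
    try:
        ann = annotate_ocrs(ocrs, genes, config.promoter_bp, config.downstream_bp)
        if force or not ann_path.exists():
            annotation_frame(ann).to_csv(ann_path, sep="\t", index=False)
    except Exception as e:
        raise StageError("annotate", e)
    ann_by_id = {a.id: a for a in ann}
    docrs = [a for a in ann if a.locality == "dOCR"]
    counts, edges = distance_histogram(docrs) if docrs else (np.array([]), np.array([]))
    report["annotation"] = {
        "n_ocrs": len(ann),
        "n_associated_genes": len({a.nearest_gene for a in ann if a.nearest_gene}),
        "category_proportions": category_proportions(ann),
        "n_docrs": len(docrs),
        "docr_distance_bins": {f"{int(lo)}-{int(hi)}": int(c) for lo, hi, c in
                               zip(edges[:-1], edges[1:], counts)},
    }

    # --- stage: profiles ---------------------------------------------------
    if config.atac and expr:
        try:
            track = SignalTrack.from_bedgraph(config.atac)
            pm = scaled_metaprofile(track, genes)
            pm.group_means().to_csv(out / "atac_metaprofile.tsv", sep="\t")
            tss_col = pm.n_flank_bins  # first gene-body bin (TSS anchor)
            sig = pm.values[:, tss_col]
            fpkm = np.array([gene_by_id[g].fpkm for g in pm.row_ids])
            rho = spearman(sig, fpkm) if np.unique(sig).size > 1 else float("nan")
            report["profiles"] = {"tss_signal_fpkm_spearman": rho,
                                  "n_genes_profiled": len(pm.row_ids)}
        except Exception as e:
            raise StageError("profiles", e)

    # --- stage: histone ----------------------------------------------------
    if config.k4_peaks and config.k27_peaks:
        try:
            k4p = read_bed(config.k4_peaks)
            k27p = read_bed(config.k27_peaks)
            classes = hist.classify_by_marks(ocrs, k4p, k27p)
            hdf = pd.DataFrame({"ocr_id": list(classes), "class": list(classes.values())})
            stage: dict = {"class_counts": hist.class_counts(classes)}
            dual = [iv for iv in ocrs if classes[iv.name] == "dual"]
            if dual:
                cov, test = hist.dual_coverage_compare(dual, k4p, k27p)
                hdf = hdf.merge(cov, on="ocr_id", how="left")
                stage["dual_coverage_p"] = test.p
                stage["dual_mean_frac_K4"] = float(cov.frac_K4.mean())
                stage["dual_mean_frac_K27"] = float(cov.frac_K27.mean())
            if config.k4_track and config.k27_track:
                k4t = SignalTrack.from_bedgraph(config.k4_track)
                k27t = SignalTrack.from_bedgraph(config.k27_track)
                m4 = anchored_matrix(k4t, ocrs)
                m27 = anchored_matrix(k27t, ocrs)
                X = np.hstack([hist.row_max_normalize(m4.values),
                               hist.row_max_normalize(m27.values)])
                assign, _ = hist.kmeans2(
                    hist.ProfileMatrix(X, m4.row_ids, m4.row_groups),
                    seed=config.seed)
                hdf["cluster"] = [assign[o] for o in hdf.ocr_id]
                stage["cluster_sizes"] = {c: int(n) for c, n in
                                          pd.Series(assign).value_counts().items()}
            if expr:
                fpkm_by_class, tests = hist.expression_by_class(classes, ann, gene_by_id)
                stage["median_fpkm_by_class"] = {
                    c: float(np.median(v)) for c, v in fpkm_by_class.items() if v.size}
                stage["expression_tests"] = {
                    k: (t.p if t else None) for k, t in tests.items()}
            if docrs:
                stage["docr_state_by_distance"] = json.loads(
                    hist.docr_state_by_distance(docrs, classes).to_json())
                stage["docr_unmodified_fraction"] = float(
                    np.mean([classes[a.id] == "unmodified" for a in docrs]))
            if config.lincrnas and docrs:
                linc = read_bed(config.lincrnas)
                _, frac = hist.lincrna_overlap(docrs, linc)
                stage["lincrna_overlap_fraction"] = frac
            hdf.to_csv(out / "histone.tsv", sep="\t", index=False)
            report["histone"] = stage
        except Exception as e:
            raise StageError("histone", e)

    # --- stage: motif ------------------------------------------------------
    if config.pwms and config.genome:
        try:
            pwms = mot.read_jaspar(config.pwms)
            seqs = extract_sequences(config.genome, ocrs)
            results = mot.motif_enrichment(seqs, None, pwms, alpha=config.alpha,
                                           threshold_frac=config.threshold_frac,
                                           seed=config.seed)
            edf = pd.DataFrame([{
                "motif_id": r.motif_id, "tf_family": r.tf_family,
                "n_ocr_hit": r.n_ocr_hit, "n_bg_hit": r.n_bg_hit,
                "p": r.p, "q": r.q, "enriched": r.enriched} for r in results])
            edf.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            stage = {
                "n_enriched": int(edf.enriched.sum()),
                "n_tested": len(edf),
                "enriched_fraction": mot.enrichment_fraction(results),
            }
            # per-family best motif, hits -> genes -> GO network
            enriched = [r for r in results if r.enriched]
            by_family: dict[str, mot.EnrichmentResult] = {}
            for r in enriched:
                if r.tf_family not in by_family or r.q < by_family[r.tf_family].q:
                    by_family[r.tf_family] = r
            pwm_by_id = {p.motif_id: p for p in pwms}
            hit_ocrs = {
                fam: {name for name, s in seqs.items()
                      if mot.has_hit(s, pwm_by_id[r.motif_id], config.threshold_frac)}
                for fam, r in by_family.items()}
            targets = mot.motif_gene_targets(hit_ocrs, ann)
            if config.go:
                g = mot.build_network(targets, _load_gene_go(config.go))
                edges_t, nodes_t = mot.network_tables(g)
                pd.DataFrame(edges_t).to_csv(out / "network_edges.tsv",
                                             sep="\t", index=False)
                pd.DataFrame(nodes_t).to_csv(out / "network_nodes.tsv",
                                             sep="\t", index=False)
                stage["n_core_go"] = sum(1 for _, d in g.nodes(data=True)
                                         if d.get("go_class") == "core")
            fams = sorted(by_family, key=lambda f: by_family[f].q)[:3]
            if len(fams) == 3:
                venn = mot.cotarget_sets(targets[fams[0]], targets[fams[1]],
                                         targets[fams[2]])
                stage["cotarget_top3"] = {"families": fams, **venn}
            report["motif"] = stage
        except Exception as e:
            raise StageError("motif", e)

    # --- stage: homology ---------------------------------------------------
    if config.genome and config.homologs:
        try:
            res = homo.find_hocrs(ocrs, config.genome, evalue_max=config.evalue_max)
            pairs_tbl = _load_homologs(config.homologs)
            relations = homo.classify_relations(res.pairs, ann_by_id, pairs_tbl)
            pd.DataFrame([{
                "ocr_a": p.ocr_a, "ocr_b": p.ocr_b, "score": p.score.S,
                "evalue": p.evalue, "gene_a": p.gene_a, "gene_b": p.gene_b,
                "relation": p.relation,
                "locality_conserved": p.locality_conserved}
                for p in res.pairs]).to_csv(out / "hocr_pairs.tsv",
                                            sep="\t", index=False)
            stage = {"hocr_fraction": res.fraction, "n_pairs": len(res.pairs),
                     "relations": relations}
            if expr:
                asym = homo.asymmetric_pairs(pairs_tbl, ann, gene_by_id)
                stage["n_asymmetric_pairs"] = len(asym)
                if len(asym) >= 2:
                    test, medians = homo.pair_expression_test(asym)
                    stage["asym_expression"] = {"p": test.p, **medians}
                if config.k4_track and config.k27_track and asym:
                    k4t = SignalTrack.from_bedgraph(config.k4_track)
                    k27t = SignalTrack.from_bedgraph(config.k27_track)
                    ant = homo.antagonism_classify(asym, k4t, k27t, gene_by_id,
                                                   fpkm_high=config.fpkm_high)
                    adf = pd.DataFrame(ant)
                    adf.to_csv(out / "antagonism.tsv", sep="\t", index=False)
                    stage["antagonism_counts"] = {
                        c: int(n) for c, n in adf["class"].value_counts().items()}
            report["homology"] = stage
        except Exception as e:
            raise StageError("homology", e)

    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                 default=float))
    return report
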