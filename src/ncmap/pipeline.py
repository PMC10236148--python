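"""End-to-end pipeline: 3FT build -> classify -> map -> annotate -> ORF/IR
-> frameshift match -> selectivity, with a JSON run summary.

Stages are pure functions of their inputs and the run configuration; a
light content-hash sidecar lets an unchanged stage be skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import classify as clf
from . import genome_mapper as gmap
from . import orf_ir
from . import frameshift as fs
from . import selectivity as sel
from .genome_model import load_reference
from .threeft import ThreeFTIndex, build_3ft, write_3ft_fasta


@dataclass
class RunConfig:
    genome: str
    gtf: str
    proteome: str
    peptides: str
    outdir: str
    expression: str | None = None
    protein_evidence: str | None = None
    panel: str | None = None
    peptide_genes: str | None = None
    vcf: str | None = None
    min_mismatch: int = 3
    min_overlap: int = 21
    tpm_cutoff: float = 1.0
    tis_threshold: float = 0.5
    target_accuracy: float = 0.90
    min_len: int = 7
    max_len: int = 25
    xle_tolerant_3ft: bool = False
    extra: dict = dc_field(default_factory=dict)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        for name in ("genome", "gtf", "proteome", "peptides", "expression",
                     "protein_evidence", "panel", "peptide_genes", "vcf"):
            p = getattr(self, name)
            if p and Path(p).exists():
                h.update(Path(p).read_bytes())
        h.update(
            json.dumps(
                {k: v for k, v in self.__dict__.items()
                 if isinstance(v, (int, float, str, bool)) and k != "outdir"},
                sort_keys=True,
            ).encode()
        )
        return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    run_hash = config.content_hash()
    hash_file = out / ".run_hash"
    summary_file = out / "summary.json"
    if hash_file.exists() and summary_file.exists() and \
            hash_file.read_text() == run_hash:
        return json.loads(summary_file.read_text())

    summary: dict = {"stages": []}

    ref = load_reference(config.genome, config.gtf)
    summary["stages"].append({"stage": "load_reference",
                              "genes": len(ref.genes)})

    segments = build_3ft(ref, min_len=config.min_len)
    write_3ft_fasta(segments, out / "threeft.fa")
    summary["stages"].append({"stage": "build_3ft", "segments": len(segments)})

    proteome = clf.read_fasta_proteome(config.proteome)
    peptides = clf.read_peptide_table(config.peptides)
    for rec in peptides:
        if not (config.min_len <= len(rec.sequence) <= config.max_len):
            summary.setdefault("warnings", []).append(
                f"peptide {rec.sequence} length outside "
                f"[{config.min_len}, {config.max_len}]"
            )
    index = ThreeFTIndex(segments)
    results = clf.classify_all(
        peptides, proteome, index,
        min_mismatch=config.min_mismatch,
        xle_tolerant_3ft=config.xle_tolerant_3ft,
    )
    counts = {"canonical": 0, "noncanonical": 0, "unmapped": 0}
    with open(out / "classification.tsv", "w") as fh:
        fh.write("sequence\tcategory\thard\tli\tn_proteome_hits\tn_3ft_hits\n")
        for r in results:
            counts[r.category] += 1
            fh.write(
                f"{r.peptide.sequence}\t{r.category}\t"
                f"{r.best_proteome_profile.hard}\t{r.best_proteome_profile.li}"
                f"\t{len(r.proteome_hits)}\t{len(r.threeft_hits)}\n"
            )
    summary["stages"].append({"stage": "classify", **counts})

    noncanonical = [r for r in results if r.category == "noncanonical"]
    bed = gmap.peptides_to_bed(noncanonical)
    gmap.write_bed(bed, out / "noncanonical.bed")
    summary["stages"].append({"stage": "map_bed", "bed_records": len(bed)})

    annotations = gmap.annotate_results(noncanonical, ref)
    label_counts = {label: 0 for label in gmap.FEATURE_LABELS}
    with open(out / "features.tsv", "w") as fh:
        fh.write("sequence\tlabels\ttranscripts\n")
        for pep in sorted(annotations):
            ann = annotations[pep]
            for label in ann.labels:
                label_counts[label] += 1
            tids = sorted({t for ts in ann.supporters.values() for t in ts})
            fh.write(
                f"{pep}\t{','.join(sorted(ann.labels))}\t{','.join(tids)}\n"
            )
    summary["stages"].append({"stage": "annotate_features", **label_counts})

    # ORF scan + IR check on noncanonical peptide hits
    gene_spans = {g.gene_id: g.span for g in ref.genes}
    n_with_upstream = 0
    peptide_intervals: dict[str, list] = {}
    with open(out / "orf_scan.tsv", "w") as fh:
        fh.write("sequence\tcodon\tgenomic_position\tupstream_offset_nt\t"
                 "tis_score\ttis_positive\n")
        for r in noncanonical:
            pep = r.peptide.sequence
            any_hit = False
            for seg, aa_off in r.threeft_hits:
                iv = seg.to_genomic(aa_off, len(pep))
                peptide_intervals.setdefault(pep, []).append(iv)
                hits = orf_ir.scan_upstream(
                    ref, iv, bound=gene_spans.get(seg.gene_id)
                )
                for h in hits:
                    any_hit = True
                    win = orf_ir.tis_window(ref, h)
                    score, positive = orf_ir.score_tis(win)
                    fh.write(
                        f"{pep}\t{h.codon}\t{h.genomic_position}\t"
                        f"{h.upstream_offset_nt}\t{score:.4f}\t{positive}\n"
                    )
            n_with_upstream += any_hit
    summary["stages"].append(
        {"stage": "orf_scan", "peptides_with_upstream_start": n_with_upstream}
    )

    ir_results = orf_ir.ir_check(ref, peptide_intervals)
    with open(out / "ir_check.tsv", "w") as fh:
        fh.write("sequence\tintron\ttranscript\tin_frame\n")
        for r in ir_results:
            fh.write(
                f"{r.peptide}\t{r.intron.chrom}:{r.intron.start}-{r.intron.end}"
                f"\t{r.upstream_exon_record.transcript_id}\t{r.in_frame}\n"
            )
    summary["stages"].append(
        {"stage": "ir_check",
         "intronic_peptides": len({r.peptide for r in ir_results}),
         "in_frame": len({r.peptide for r in ir_results if r.in_frame})}
    )

    if config.vcf:
        variants = fs.read_variants_vcf(config.vcf, ref)
        mutants = fs.build_mutant_proteins(ref, variants)
        fs.write_mutant_fasta(mutants, out / "frameshift_proteins.fa")
        hits = fs.match_frameshift(
            [r.peptide.sequence for r in noncanonical], mutants
        )
        with open(out / "frameshift_hits.tsv", "w") as fh:
            fh.write("sequence\tmutant\toffset\n")
            for h in sorted(hits, key=lambda h: (h.peptide, h.mutant_id)):
                fh.write(f"{h.peptide}\t{h.mutant_id}\t{h.offset}\n")
        summary["stages"].append(
            {"stage": "frameshift_match", "variants": len(variants),
             "hits": len(hits),
             "peptides_explained": len({h.peptide for h in hits})}
        )
    else:
        summary["stages"].append({"stage": "frameshift_match",
                                  "skipped": "no VCF provided"})

    if config.expression and config.protein_evidence and config.peptide_genes:
        samples = sel.read_expression_samples(config.expression)
        expr = sel.tissue_percentile(samples)
        evidence = sel.read_protein_evidence(config.protein_evidence)
        panel: set[str] = set()
        if config.panel:
            panel = {
                ln.strip() for ln in open(config.panel) if ln.strip()
            }
        pg = pd.read_csv(config.peptide_genes, sep="\t")
        peptide_genes = {
            row["peptide"]: row["genes"].split(",") for _, row in pg.iterrows()
        }
        nc_seqs = {r.peptide.sequence for r in noncanonical}
        labels = sel.classify_selectivity_table(
            {p: g for p, g in peptide_genes.items() if p in nc_seqs},
            panel, expr, evidence, tpm_cutoff=config.tpm_cutoff,
        )
        with open(out / "selectivity.tsv", "w") as fh:
            fh.write("sequence\tlabel\n")
            for lab in labels:
                fh.write(f"{lab.peptide}\t{lab.label}\n")
        sel_counts: dict[str, int] = {}
        for lab in labels:
            sel_counts[lab.label] = sel_counts.get(lab.label, 0) + 1
        summary["stages"].append({"stage": "selectivity", **sel_counts})
    else:
        summary["stages"].append({"stage": "selectivity",
                                  "skipped": "expression tables not provided"})

    summary_file.write_text(json.dumps(summary, indent=2, sort_keys=True))
    hash_file.write_text(run_hash)
    return summary
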