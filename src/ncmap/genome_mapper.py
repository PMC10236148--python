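"""Project noncanonical peptides onto the genome and label them by feature.

Feature labels follow the four gene-feature categories relevant to
noncanonical peptide origins: 5'UTR, exonic-in-alternative-frame, intronic
and 3'UTR.  Labels are assigned per transcript and unioned — categories are
not mutually exclusive, since transcripts of a gene overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome_model import GenomicInterval, ReferenceModel, TranscriptModel
from .threeft import TranslatedSegment
from .classify import ClassificationResult

FEATURE_LABELS = ("five_prime_utr", "exonic_alt_frame", "intronic", "three_prime_utr")


@dataclass
class FeatureAnnotation:
    labels: set[str] = field(default_factory=set)
    supporters: dict[str, set[str]] = field(default_factory=dict)

    def add(self, label: str, transcript_id: str) -> None:
        self.labels.add(label)
        self.supporters.setdefault(label, set()).add(transcript_id)


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    def line(self) -> str:
        return (
            f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t"
            f"{self.score}\t{self.strand}"
        )


def peptides_to_bed(results: list[ClassificationResult]) -> list[BedRecord]:
    """One BED6 line per (noncanonical peptide, 3FT hit), sorted by
    (chrom, start, name)."""
    records = []
    for res in results:
        if res.category != "noncanonical":
            continue
        pep = res.peptide.sequence
        for seg, aa_offset in res.threeft_hits:
            iv = seg.to_genomic(aa_offset, len(pep))
            records.append(
                BedRecord(iv.chrom, iv.start, iv.end, pep, 0, iv.strand)
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.name))
    return records


def write_bed(records: list[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.line() + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                BedRecord(
                    f[0], int(f[1]), int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    int(f[4]) if len(f) > 4 and f[4] != "." else 0,
                    f[5] if len(f) > 5 else "+",
                )
            )
    return out


def transcript_utrs(
    t: TranscriptModel,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """(5'UTR, 3'UTR) intervals derived from CDS extent, strand-aware.

    Exonic regions 5' of the CDS start are 5'UTR; exonic regions 3' of the
    CDS end are 3'UTR.  Transcripts without CDS have no UTRs.
    """
    if not t.cds:
        return [], []
    cds_lo = min(c.start for c in t.cds)
    cds_hi = max(c.end for c in t.cds)
    before, after = [], []
    for e in t.exons:
        if e.start < cds_lo:
            before.append(
                GenomicInterval(e.chrom, e.start, min(e.end, cds_lo), e.strand)
            )
        if e.end > cds_hi:
            after.append(
                GenomicInterval(e.chrom, max(e.start, cds_hi), e.end, e.strand)
            )
    if t.strand == "+":
        return before, after
    return after, before


def cds_frame_class(t: TranscriptModel) -> dict[int, int]:
    """Per CDS exon: congruence class (mod 3) of genomic codon-start bases.

    The class is the residue mod 3 of the transcription-direction first base
    of in-frame codons within that CDS interval, accounting for the phase
    accumulated over upstream CDS intervals after splicing.  Keyed by
    ``id`` order: returns {index into cds_in_transcription_order(): class}.
    """
    classes: dict[int, int] = {}
    consumed = 0
    for i, c in enumerate(t.cds_in_transcription_order()):
        phase = (3 - consumed % 3) % 3  # bases completing the upstream codon
        if t.strand == "+":
            first_codon_start = c.start + phase
            classes[i] = first_codon_start % 3
        else:
            first_codon_start = (c.end - 1) - phase
            classes[i] = first_codon_start % 3
        consumed += len(c)
    return classes


def peptide_frame_class(seg: TranslatedSegment, aa_offset: int) -> int:
    """Congruence class (mod 3) of the peptide's codon-start bases."""
    iv = seg.to_genomic(aa_offset, 1)
    start = iv.start if seg.strand == "+" else iv.end - 1
    return start % 3


def annotate_features(
    interval: GenomicInterval,
    ref: ReferenceModel,
    frame_class: int | None = None,
) -> FeatureAnnotation:
    """Label ``interval`` against every same-strand transcript it touches.

    ``frame_class`` is the peptide's codon-start congruence class mod 3
    (from :func:`peptide_frame_class`); without it the exonic_alt_frame
    label cannot be assessed and is never assigned.
    """
    ann = FeatureAnnotation()
    for gene in ref.genes:
        if gene.chrom != interval.chrom or gene.strand != interval.strand:
            continue
        if gene.span.overlap(interval) == 0:
            continue
        for t in gene.transcripts:
            tid = t.transcript_id
            for intron in t.introns:
                if intron.overlap(interval) > 0:
                    ann.add("intronic", tid)
            utr5, utr3 = transcript_utrs(t)
            if any(u.overlap(interval) > 0 for u in utr5):
                ann.add("five_prime_utr", tid)
            if any(u.overlap(interval) > 0 for u in utr3):
                ann.add("three_prime_utr", tid)
            if frame_class is not None and t.cds:
                classes = cds_frame_class(t)
                for i, c in enumerate(t.cds_in_transcription_order()):
                    if c.overlap(interval) > 0 and classes[i] != frame_class:
                        ann.add("exonic_alt_frame", tid)
    return ann


def annotate_results(
    results: list[ClassificationResult], ref: ReferenceModel
) -> dict[str, FeatureAnnotation]:
    """Union feature annotation per noncanonical peptide over all its hits."""
    out: dict[str, FeatureAnnotation] = {}
    for res in results:
        if res.category != "noncanonical":
            continue
        pep = res.peptide.sequence
        ann = out.setdefault(pep, FeatureAnnotation())
        for seg, aa_offset in res.threeft_hits:
            iv = seg.to_genomic(aa_offset, len(pep))
            sub = annotate_features(iv, ref, peptide_frame_class(seg, aa_offset))
            for label, tids in sub.supporters.items():
                for tid in tids:
                    ann.add(label, tid)
    return out
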