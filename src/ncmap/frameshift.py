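"""Mutant protein construction from coding frameshift indels.

A frameshifting indel applied to a transcript's spliced CDS shifts the
reading frame from the edited codon onward; translation then runs through a
novel amino-acid *tail* until the first stop codon in the shifted frame.
Peptides supported by a frameshift must match the mutant protein exactly
(I/L distinguished) AND overlap at least one tail residue — prefix-only
matches are canonical sequence and carry no frameshift evidence.

Downstream sequence for the tail is read through the spliced transcript
(3'UTR exons) first and then the genomic continuation past the transcript
end (``mode="spliced"``, default), or straight through the unspliced genome
after the edit (``mode="genomic"``); both are exposed because annotation
toolkits differ on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_model import (
    GenomicInterval,
    ReferenceModel,
    TranscriptModel,
    reverse_complement,
    translate,
)


@dataclass(frozen=True)
class FrameshiftVariant:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    transcript_id: str

    def __post_init__(self) -> None:
        if abs(len(self.ref) - len(self.alt)) % 3 == 0:
            raise ValueError(
                f"variant {self.chrom}:{self.pos} {self.ref}>{self.alt} is "
                "not frameshifting (indel length is a multiple of 3)"
            )

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class MutantProtein:
    id: str
    prefix: str
    tail: str
    variant: FrameshiftVariant
    no_stop_found: bool = False

    @property
    def full_seq(self) -> str:
        return self.prefix + self.tail


def _spliced_cds_plus_downstream(
    ref: ReferenceModel,
    gene_strand: str,
    t: TranscriptModel,
    mode: str,
    downstream_pad: int = 3000,
) -> tuple[str, list[int]]:
    """Coding-strand sequence starting at the CDS start, plus downstream
    context, together with the genomic coordinate of each base.

    Returns (sequence, genomic_positions) where positions are 0-based
    coordinates of each base (useful to locate the variant).
    """
    if not t.cds:
        raise ValueError(f"transcript {t.transcript_id} has no CDS")
    chrom = t.cds[0].chrom
    chrom_len = len(ref.chromosomes[chrom])
    positions: list[int] = []
    cds_lo = min(c.start for c in t.cds)
    cds_hi = max(c.end for c in t.cds)
    if mode == "spliced":
        # exonic bases from the CDS start onward (plus-strand order), i.e.
        # spliced CDS + spliced 3'UTR, then genomic continuation past the
        # transcript end
        for e in t.exons:
            if gene_strand == "+":
                if e.end <= cds_lo:
                    continue
                positions.extend(range(max(e.start, cds_lo), e.end))
            else:
                if e.start >= cds_hi:
                    continue
                positions.extend(range(e.start, min(e.end, cds_hi)))
        if gene_strand == "+":
            t_end = max(e.end for e in t.exons)
            positions.extend(range(t_end, min(chrom_len, t_end + downstream_pad)))
        else:
            t_start = min(e.start for e in t.exons)
            positions = list(range(max(0, t_start - downstream_pad), t_start)) + positions
    elif mode == "genomic":
        # spliced CDS, then unspliced genomic read-through past the CDS end
        # (3'UTR introns retained)
        for c in t.cds:
            positions.extend(range(c.start, c.end))
        if gene_strand == "+":
            positions.extend(range(cds_hi, min(chrom_len, cds_hi + downstream_pad)))
        else:
            positions = list(range(max(0, cds_lo - downstream_pad), cds_lo)) + positions
    else:
        raise ValueError(f"unknown downstream mode {mode!r}")
    seq = "".join(ref.chromosomes[chrom][p] for p in positions)
    if gene_strand == "-":
        seq = reverse_complement(seq)
        positions = list(reversed(positions))
    return seq, positions


def apply_frameshift(cds_plus_downstream: str, variant: FrameshiftVariant,
                     cds_offset: int, ref_on_coding: str, alt_on_coding: str) -> str:
    """Replace ref by alt at ``cds_offset`` (0-based within the coding-strand
    sequence).  Hard error on reference mismatch."""
    found = cds_plus_downstream[cds_offset : cds_offset + len(ref_on_coding)]
    if found != ref_on_coding:
        raise ValueError(
            f"reference mismatch at CDS offset {cds_offset} for variant "
            f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}: "
            f"expected {ref_on_coding!r}, found {found!r}"
        )
    return (
        cds_plus_downstream[:cds_offset]
        + alt_on_coding
        + cds_plus_downstream[cds_offset + len(ref_on_coding) :]
    )


def _first_diff(ref: str, alt: str) -> int:
    for i, (a, b) in enumerate(zip(ref, alt)):
        if a != b:
            return i
    return min(len(ref), len(alt))


def mutant_protein(mutant_nt: str, variant: FrameshiftVariant,
                   cds_offset: int, ref_on_coding: str, alt_on_coding: str,
                   protein_id: str | None = None) -> MutantProtein:
    """Translate the edited coding sequence into prefix + novel tail.

    ``prefix`` holds residues whose codons lie fully 5' of the first edited
    base; ``tail`` holds everything from the first affected codon to (and
    excluding) the first stop in the shifted frame.  If no stop occurs
    within the available downstream sequence the record is truncated and
    flagged ``no_stop_found``.
    """
    first_changed = cds_offset + _first_diff(ref_on_coding, alt_on_coding)
    prefix_codons = first_changed // 3
    aa = translate(mutant_nt, 0)
    stop_at = aa.find("*", prefix_codons)
    no_stop = stop_at < 0
    if no_stop:
        stop_at = len(aa)
    prefix = aa[:prefix_codons]
    tail = aa[prefix_codons:stop_at]
    if "*" in prefix:
        raise ValueError(
            "stop codon upstream of the edit: CDS/variant pairing is corrupt"
        )
    return MutantProtein(
        id=protein_id or f"{variant.transcript_id}:{variant.pos}{variant.ref}>{variant.alt}",
        prefix=prefix, tail=tail, variant=variant, no_stop_found=no_stop,
    )


def build_mutant_proteins(
    ref: ReferenceModel,
    variants: list[FrameshiftVariant],
    mode: str = "spliced",
) -> list[MutantProtein]:
    """Construct one mutant protein per (variant, transcript)."""
    tx_index: dict[str, tuple[str, TranscriptModel]] = {}
    for g in ref.genes:
        for t in g.transcripts:
            tx_index[t.transcript_id] = (g.strand, t)
    out = []
    for v in variants:
        if v.transcript_id not in tx_index:
            raise KeyError(f"variant references unknown transcript {v.transcript_id}")
        strand, t = tx_index[v.transcript_id]
        seq, positions = _spliced_cds_plus_downstream(ref, strand, t, mode)
        pos_to_offset = {p: i for i, p in enumerate(positions)}
        if strand == "+":
            ref_c, alt_c = v.ref, v.alt
            anchor = v.pos0
        else:
            ref_c, alt_c = reverse_complement(v.ref), reverse_complement(v.alt)
            anchor = v.pos0 + len(v.ref) - 1  # coding-strand first base of ref
        if anchor not in pos_to_offset:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} does not fall in the coding "
                f"sequence of {v.transcript_id}"
            )
        cds_offset = pos_to_offset[anchor]
        mutant_nt = apply_frameshift(seq, v, cds_offset, ref_c, alt_c)
        out.append(mutant_protein(mutant_nt, v, cds_offset, ref_c, alt_c))
    return out


@dataclass(frozen=True)
class FrameshiftHit:
    peptide: str
    mutant_id: str
    offset: int  # position of the match within full_seq
    variant: FrameshiftVariant


def match_frameshift(
    peptides: list[str], mutants: list[MutantProtein]
) -> list[FrameshiftHit]:
    """Exact substring hits (I/L distinguished) overlapping >= 1 tail
    residue."""
    hits = []
    for m in mutants:
        full = m.full_seq
        tail_start = len(m.prefix)
        for pep in peptides:
            start = 0
            while True:
                pos = full.find(pep, start)
                if pos < 0:
                    break
                if pos + len(pep) > tail_start:  # overlaps the novel tail
                    hits.append(
                        FrameshiftHit(
                            peptide=pep, mutant_id=m.id, offset=pos,
                            variant=m.variant,
                        )
                    )
                start = pos + 1
    return hits


def read_variants_vcf(path: str | Path, ref: ReferenceModel | None = None
                      ) -> list[FrameshiftVariant]:
    """Read frameshifting indels from a VCF (CHROM POS REF ALT plus a
    ``TRANSCRIPT`` INFO key naming the affected transcript).

    Only frameshifting indels are returned; in-frame indels and SNVs are
    skipped.  When ``ref`` is given, the REF allele is checked against the
    reference sequence (hard error on mismatch).
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tid = rec.info.get("TRANSCRIPT")
            if tid is None:
                raise ValueError(
                    f"VCF record {rec.chrom}:{rec.pos} lacks a TRANSCRIPT "
                    "INFO key"
                )
            vref = rec.ref
            for alt in rec.alts or ():
                if abs(len(vref) - len(alt)) % 3 == 0:
                    continue
                if ref is not None:
                    found = ref.chromosomes[rec.chrom][
                        rec.pos - 1 : rec.pos - 1 + len(vref)
                    ]
                    if found != vref:
                        raise ValueError(
                            f"VCF REF mismatch at {rec.chrom}:{rec.pos}: VCF "
                            f"says {vref!r}, reference has {found!r}"
                        )
                out.append(
                    FrameshiftVariant(
                        chrom=rec.chrom, pos=rec.pos, ref=vref, alt=alt,
                        transcript_id=str(tid),
                    )
                )
    return out


def write_mutant_fasta(mutants: list[MutantProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mutants:
            flag = " no_stop_found" if m.no_stop_found else ""
            fh.write(f">{m.id}{flag}\n{m.full_seq}\n")
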