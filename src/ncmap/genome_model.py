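"""Genome + annotation model with explicit coordinate conventions.

All internal coordinates are 0-based half-open ``[start, end)``.  GTF input
(1-based closed) and BED output (0-based half-open) are converted exactly at
the I/O boundary and nowhere else.

The model is deliberately small: chromosomes are plain uppercase strings
(alphabet ACGTN), genes carry one genomic span each, transcripts carry
ascending non-overlapping exon intervals from which introns are derived as
the gaps.  Only the ENSEMBL GTF dialect subset needed here is read
(features ``gene``/``transcript``/``exon``/``CDS``; attributes ``gene_id``,
``transcript_id``, ``gene_biotype``, optionally ``gene_name``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class AnnotationError(ValueError):
    """Raised when a reference/annotation pair is inconsistent."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` starting at offset ``frame`` (0/1/2).

    One letter per complete codon; stop codons emit ``*``; codons containing
    ``N`` emit ``X``; a trailing partial codon is dropped.  Too-short input
    yields the empty string.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def five_prime(self) -> int:
        """Transcription-direction first base (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


def gtf_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GTF 1-based closed -> internal 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GTF 1-based closed."""
    return start + 1, end


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        if self.cds is not None:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            for c in self.cds:
                if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                    raise AnnotationError(
                        f"CDS interval {c} of {self.transcript_id} not contained "
                        "in any exon"
                    )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, ascending genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_in_transcription_order(self) -> list[GenomicInterval]:
        if not self.cds:
            return []
        return self.cds if self.strand == "+" else list(reversed(self.cds))


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    span: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass
class ReferenceModel:
    chromosomes: dict[str, str]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        for name, seq in self.chromosomes.items():
            if not _VALID_SEQ.match(seq):
                raise AnnotationError(
                    f"chromosome {name} contains characters outside ACGTN"
                )
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise AnnotationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom!r}"
                )
            clen = len(self.chromosomes[g.chrom])
            for t in g.transcripts:
                for e in t.exons:
                    if e.end > clen:
                        raise AnnotationError(
                            f"exon {e} of {t.transcript_id} exceeds chromosome "
                            f"{g.chrom} length {clen}"
                        )

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def premrna_sequence(self, gene_id: str) -> str:
        """Sense-strand unspliced (pre-mRNA) sequence of the full gene span.

        Minus-strand genes return the reverse complement of the genomic
        slice, so the returned string always reads 5'->3' in transcription
        direction.
        """
        g = self.gene(gene_id)
        raw = self.chromosomes[g.chrom][g.span.start : g.span.end]
        return raw if g.strand == "+" else reverse_complement(raw)

    def slice(self, chrom: str, start: int, end: int, pad: bool = False) -> str:
        """Genomic slice; with ``pad`` out-of-range flanks become N."""
        seq = self.chromosomes[chrom]
        if not pad:
            return seq[start:end]
        left = "N" * max(0, -start)
        right = "N" * max(0, end - len(seq))
        return left + seq[max(0, start) : min(len(seq), end)] + right


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_reference(genome: str | Path, annotation: str | Path) -> ReferenceModel:
    """Load a FASTA genome + ENSEMBL-style GTF into a :class:`ReferenceModel`.

    Chromosome names in the GTF are resolved against the FASTA after an
    optional ``chr`` prefix normalization.  Unknown chromosomes and exons
    outside chromosome bounds are hard errors.  Genes of non-protein-coding
    biotype are retained (flagged via ``biotype``) but are ignored by the
    three-frame-translation builder.
    """
    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    chromosomes = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()

    def resolve_chrom(name: str) -> str:
        if name in chromosomes:
            return name
        alt = name[3:] if name.startswith("chr") else "chr" + name
        if alt in chromosomes:
            return alt
        raise AnnotationError(
            f"annotation chromosome {name!r} absent from genome FASTA"
        )

    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}

    with open(annotation) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationError(f"malformed GTF line: {line.rstrip()}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            chrom = resolve_chrom(chrom)
            s, e = gtf_to_internal(int(start), int(end))
            a = _parse_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise AnnotationError(f"GTF {feature} record without gene_id")
            if feature == "gene":
                if gid in genes:
                    raise AnnotationError(
                        f"gene {gid} has multiple spans; one span per gene_id"
                    )
                genes[gid] = {
                    "gene_id": gid,
                    "gene_name": a.get("gene_name", gid),
                    "biotype": a.get("gene_biotype", a.get("gene_type", "")),
                    "chrom": chrom,
                    "strand": strand,
                    "start": s,
                    "end": e,
                    "transcripts": [],
                }
                continue
            tid = a.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"GTF {feature} record without transcript_id")
            t = transcripts.setdefault(
                tid,
                {"transcript_id": tid, "gene_id": gid, "strand": strand,
                 "exons": [], "cds": []},
            )
            if feature == "exon":
                t["exons"].append(GenomicInterval(chrom, s, e, strand))
            elif feature == "CDS":
                t["cds"].append(GenomicInterval(chrom, s, e, strand))

    gene_models: list[GeneModel] = []
    for tid, t in transcripts.items():
        gid = t["gene_id"]
        if gid not in genes:
            # tolerate GTFs without explicit gene lines: synthesize the span
            exs = t["exons"]
            if not exs:
                raise AnnotationError(f"transcript {tid} has no exons")
            genes[gid] = {
                "gene_id": gid, "gene_name": gid, "biotype": "",
                "chrom": exs[0].chrom, "strand": t["strand"],
                "start": min(e.start for e in exs),
                "end": max(e.end for e in exs), "transcripts": [],
            }
    for tid, t in transcripts.items():
        genes[t["gene_id"]]["transcripts"].append(
            TranscriptModel(
                transcript_id=tid,
                exons=t["exons"],
                cds=t["cds"] or None,
                strand=t["strand"],
            )
        )
    for gid, g in genes.items():
        tms = sorted(g["transcripts"], key=lambda x: x.transcript_id)
        span = GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"])
        for tm in tms:
            for e in tm.exons:
                if e.start < span.start or e.end > span.end:
                    raise AnnotationError(
                        f"exon {e} of {tm.transcript_id} outside gene span of {gid}"
                    )
        gene_models.append(
            GeneModel(
                gene_id=gid,
                gene_name=g["gene_name"],
                biotype=g["biotype"],
                chrom=g["chrom"],
                strand=g["strand"],
                span=span,
                transcripts=tms,
            )
        )
    gene_models.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return ReferenceModel(chromosomes=chromosomes, genes=gene_models)
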