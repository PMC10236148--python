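"""Pre-mRNA three-frame-translation (3FT) search space.

For every protein-coding gene the unspliced sense pre-mRNA is translated in
frames 0/1/2, split at stop codons (and at X from ambiguous bases) into
maximal stop-free segments, and each segment is emitted with a genomic
anchor so peptide matches can be projected back onto the genome.

Anchor convention: the genomic coordinate (0-based) of the first base of the
segment's first codon; for minus-strand genes this is the genomically
*highest* base of that codon (transcription-direction 5' base).

FASTA header grammar (bit-exact, parse(write(x)) == x)::

    >3FT|{gene_id}|{chrom}|{strand}|{frame}|{anchor}|{segment_index}
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .genome_model import (
    GenomicInterval,
    ReferenceModel,
    reverse_complement,
    translate,
)

DEFAULT_MIN_LEN = 7  # shortest peptide the downstream search considers

_SEGMENT_SPLIT = re.compile(r"[*X]+")


@dataclass(frozen=True)
class TranslatedSegment:
    gene_id: str
    chrom: str
    strand: str
    frame: int
    aa_seq: str
    anchor: int
    segment_index: int

    def __post_init__(self) -> None:
        if "*" in self.aa_seq or "X" in self.aa_seq:
            raise ValueError("segment must be stop- and X-free")

    def header(self) -> str:
        return (
            f"3FT|{self.gene_id}|{self.chrom}|{self.strand}|{self.frame}|"
            f"{self.anchor}|{self.segment_index}"
        )

    def to_genomic(self, aa_start: int, aa_len: int) -> GenomicInterval:
        """Genomic interval of the aa window [aa_start, aa_start+aa_len)."""
        if aa_start < 0 or aa_len <= 0 or aa_start + aa_len > len(self.aa_seq):
            raise ValueError(
                f"aa window [{aa_start}, {aa_start + aa_len}) outside segment "
                f"of length {len(self.aa_seq)}"
            )
        if self.strand == "+":
            start = self.anchor + 3 * aa_start
            end = self.anchor + 3 * (aa_start + aa_len)
        else:
            start = self.anchor - 3 * (aa_start + aa_len) + 1
            end = self.anchor - 3 * aa_start + 1
        return GenomicInterval(self.chrom, start, end, self.strand)


def segment_to_genomic(
    seg: TranslatedSegment, aa_start: int, aa_len: int
) -> GenomicInterval:
    return seg.to_genomic(aa_start, aa_len)


def build_3ft(
    ref: ReferenceModel, min_len: int = DEFAULT_MIN_LEN
) -> list[TranslatedSegment]:
    """Build all stop-free 3FT segments of length >= ``min_len``.

    Only genes with a ``protein_coding`` biotype enter the search space.
    Overlapping genes yield independent (possibly duplicate-sequence)
    segments under distinct headers, keeping coordinate recovery
    gene-resolved.
    """
    segments: list[TranslatedSegment] = []
    for gene in ref.genes:
        if not gene.is_protein_coding:
            continue
        premrna = ref.premrna_sequence(gene.gene_id)
        for frame in (0, 1, 2):
            aa = translate(premrna, frame)
            idx = 0
            pos = 0
            for m in _SEGMENT_SPLIT.finditer(aa + "*"):
                chunk = aa[pos : m.start()]
                if len(chunk) >= min_len:
                    aa_offset = pos  # codon index within this frame
                    if gene.strand == "+":
                        anchor = gene.span.start + frame + 3 * aa_offset
                    else:
                        anchor = gene.span.end - 1 - frame - 3 * aa_offset
                    segments.append(
                        TranslatedSegment(
                            gene_id=gene.gene_id,
                            chrom=gene.chrom,
                            strand=gene.strand,
                            frame=frame,
                            aa_seq=chunk,
                            anchor=anchor,
                            segment_index=idx,
                        )
                    )
                    idx += 1
                pos = m.end()
    return segments


def write_3ft_fasta(segments: Iterable[TranslatedSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.header()}\n{seg.aa_seq}\n")


def parse_3ft_header(header: str, aa_seq: str = "") -> TranslatedSegment:
    """Parse a 3FT FASTA header (leading '>' optional) back into a segment."""
    h = header[1:] if header.startswith(">") else header
    fields = h.split("|")
    if len(fields) != 7:
        raise ValueError(
            f"3FT header must have 7 '|'-separated fields, got {len(fields)}: {h!r}"
        )
    tag, gene_id, chrom, strand, frame, anchor, seg_idx = fields
    if tag != "3FT":
        raise ValueError(f"3FT header must start with '3FT', got {tag!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand field {strand!r} in 3FT header")
    try:
        frame_i = int(frame)
        anchor_i = int(anchor)
        idx_i = int(seg_idx)
    except ValueError as exc:
        raise ValueError(f"non-integer numeric field in 3FT header {h!r}") from exc
    if frame_i not in (0, 1, 2):
        raise ValueError(f"frame field must be 0/1/2, got {frame_i}")
    return TranslatedSegment(
        gene_id=gene_id, chrom=chrom, strand=strand, frame=frame_i,
        aa_seq=aa_seq, anchor=anchor_i, segment_index=idx_i,
    )


def read_3ft_fasta(path: str | Path) -> list[TranslatedSegment]:
    segments = []
    header = None
    seq_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    segments.append(parse_3ft_header(header, "".join(seq_parts)))
                header = line
                seq_parts = []
            elif line:
                seq_parts.append(line)
    if header is not None:
        segments.append(parse_3ft_header(header, "".join(seq_parts)))
    return segments


def retranslate(seg: TranslatedSegment, ref: ReferenceModel) -> str:
    """Re-translate the genomic slice implied by the segment (identity check)."""
    iv = seg.to_genomic(0, len(seg.aa_seq))
    raw = ref.slice(iv.chrom, iv.start, iv.end)
    if seg.strand == "-":
        raw = reverse_complement(raw)
    return translate(raw, 0)


class ThreeFTIndex:
    """Exact-substring index over 3FT segments.

    Segments are concatenated with ``#`` sentinels; lookups return
    ``(segment, aa_offset)`` pairs.  An optional Xle-tolerant mode allows at
    most one isobaric I/L interchange (used only when comparing against
    peptide sets from other studies).
    """

    def __init__(self, segments: list[TranslatedSegment]):
        self.segments = list(segments)
        self._offsets: list[int] = []
        parts = []
        pos = 0
        for seg in self.segments:
            self._offsets.append(pos)
            parts.append(seg.aa_seq)
            pos += len(seg.aa_seq) + 1
        self._blob = "#".join(parts)
        self._blob_xle = self._blob.replace("I", "L")

    def _locate(self, pos: int) -> tuple[TranslatedSegment, int]:
        i = bisect.bisect_right(self._offsets, pos) - 1
        return self.segments[i], pos - self._offsets[i]

    def _scan(self, blob: str, query: str) -> Iterator[int]:
        start = 0
        while True:
            pos = blob.find(query, start)
            if pos < 0:
                return
            yield pos
            start = pos + 1

    def lookup(
        self, peptide: str, xle_tolerant: bool = False
    ) -> list[tuple[TranslatedSegment, int]]:
        """All exact hits of ``peptide``; I and L are distinguished unless
        ``xle_tolerant`` (then at most one I/L interchange is allowed)."""
        hits: list[tuple[TranslatedSegment, int]] = []
        if not xle_tolerant:
            for pos in self._scan(self._blob, peptide):
                hits.append(self._locate(pos))
            return hits
        seen = set()
        for pos in self._scan(self._blob_xle, peptide.replace("I", "L")):
            window = self._blob[pos : pos + len(peptide)]
            xle_mismatches = sum(1 for a, b in zip(peptide, window) if a != b)
            if xle_mismatches <= 1 and pos not in seen:
                seen.add(pos)
                hits.append(self._locate(pos))
        return hits
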