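"""Mechanistic explanation of noncanonical peptides.

Two analyses:

* **Upstream ORF scan** — walk 5'-ward from a peptide's first codon in
  steps of 3 (the peptide's own reading frame), reporting every canonical
  or near-cognate start codon (ATG, CTG, TTG, GTG, ACG) until the first
  stop codon or the gene boundary.  Candidate starts are scored for
  translation-initiation potential on a 203-nt window (100 nt of flank on
  each side of the codon) by a pluggable scorer; a score > 0.5 is called
  positive.  The bundled default scorer is a Kozak-context position-weight
  heuristic — it is NOT a trained initiation-site network and is labeled
  as such.

* **Intron-retention frame test** — per transcript, propagate the reading
  frame across exons in transcription order to obtain, for each exon with
  a downstream intron, a genomic coordinate on the codon grid that
  continues into the retained intron.  An intronic peptide is "in frame"
  when its transcription-direction start coordinate lies on that grid.

Frame-table convention: the emitted ``inframe_coordinate`` is the codon-grid
representative shifted at most 2 nt 5' of the exon's 5' start, which is
congruent mod 3 to the first in-frame codon fully contained in the exon.
The raw published recursion (which shifts by the complementary residue and
lands on a different grid for exons with non-zero phase) is available via
``literal=True`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .genome_model import (
    GenomicInterval,
    ReferenceModel,
    STOP_CODONS,
    reverse_complement,
)

START_CODONS = ("ATG", "CTG", "TTG", "GTG", "ACG")

TIS_WINDOW_FLANK = 100
TIS_POSITIVE_THRESHOLD = 0.5


@dataclass(frozen=True)
class StartCodonHit:
    codon: str
    genomic_position: int  # transcription-direction 5' base of the codon
    upstream_offset_nt: int  # distance 5' of the peptide start, multiple of 3
    strand: str
    chrom: str
    tis_score: float | None = None


@dataclass(frozen=True)
class TISWindow:
    sequence: str  # 203 nt on the coding strand, N-padded at reference edges
    center_codon: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * TIS_WINDOW_FLANK + 3:
            raise ValueError(
                f"TIS window must be {2 * TIS_WINDOW_FLANK + 3} nt, "
                f"got {len(self.sequence)}"
            )
        if self.sequence[TIS_WINDOW_FLANK : TIS_WINDOW_FLANK + 3] != self.center_codon:
            raise ValueError("window center does not equal center_codon")


@dataclass(frozen=True)
class ExonFrameRecord:
    transcript_id: str
    chrom: str
    strand: str
    exon: GenomicInterval
    inframe_coordinate: int
    downstream_intron: GenomicInterval


@dataclass(frozen=True)
class IRResult:
    peptide: str
    intron: GenomicInterval
    upstream_exon_record: ExonFrameRecord
    in_frame: bool


def _codon_at(ref: ReferenceModel, chrom: str, pos5: int, strand: str) -> str:
    """Codon whose transcription-direction 5' base is at ``pos5``."""
    if strand == "+":
        raw = ref.slice(chrom, pos5, pos5 + 3, pad=True)
        return raw
    raw = ref.slice(chrom, pos5 - 2, pos5 + 1, pad=True)
    return reverse_complement(raw)


def scan_upstream(
    ref: ReferenceModel,
    peptide_interval: GenomicInterval,
    bound: GenomicInterval | None = None,
) -> list[StartCodonHit]:
    """Report in-frame start codons strictly 5' of the peptide, nearest
    first, stopping at (and excluding) the first stop codon, the reference
    edge, or ``bound`` (typically the host gene span)."""
    strand = peptide_interval.strand
    chrom = peptide_interval.chrom
    pos = peptide_interval.five_prime()
    chrom_len = len(ref.chromosomes[chrom])
    offset = 0
    hits: list[StartCodonHit] = []
    while True:
        offset += 3
        pos = pos - 3 if strand == "+" else pos + 3
        if strand == "+":
            if pos < 0 or (bound is not None and pos < bound.start):
                break
        else:
            if pos >= chrom_len or (bound is not None and pos >= bound.end):
                break
        codon = _codon_at(ref, chrom, pos, strand)
        if codon in STOP_CODONS:
            break
        if "N" in codon:
            break
        if codon in START_CODONS:
            hits.append(
                StartCodonHit(
                    codon=codon, genomic_position=pos,
                    upstream_offset_nt=offset, strand=strand, chrom=chrom,
                )
            )
    return hits


def tis_window(ref: ReferenceModel, hit: StartCodonHit) -> TISWindow:
    """203-nt coding-strand window centered on the start codon."""
    if hit.strand == "+":
        lo = hit.genomic_position - TIS_WINDOW_FLANK
        hi = hit.genomic_position + 3 + TIS_WINDOW_FLANK
        seq = ref.slice(hit.chrom, lo, hi, pad=True)
    else:
        lo = hit.genomic_position - 2 - TIS_WINDOW_FLANK
        hi = hit.genomic_position + 1 + TIS_WINDOW_FLANK
        seq = reverse_complement(ref.slice(hit.chrom, lo, hi, pad=True))
    return TISWindow(sequence=seq, center_codon=hit.codon)


# --- TIS scoring -----------------------------------------------------------

# Kozak-context position weights for the -6..-1 and +4 positions around the
# start codon (gccRccATGG consensus).  Purines at -3 and G at +4 dominate.
_KOZAK_WEIGHTS: dict[int, dict[str, float]] = {
    -6: {"G": 1.0, "C": 0.5},
    -5: {"C": 1.0},
    -4: {"C": 1.0},
    -3: {"A": 3.0, "G": 2.5},
    -2: {"C": 1.0},
    -1: {"C": 1.0},
    +3: {"G": 2.0},  # first base after the codon
}
_KOZAK_MAX = sum(max(w.values()) for w in _KOZAK_WEIGHTS.values())


def kozak_score(window: TISWindow | str) -> float:
    """Position-weight Kozak-context heuristic scaled to [0, 1].

    A deliberately simple, deterministic stand-in scorer: it rewards the
    classical Kozak consensus around the start codon.  It is not a trained
    initiation-site predictor; plug in a real one via the ``scorer``
    argument of :func:`score_tis` for production use.
    """
    seq = window.sequence if isinstance(window, TISWindow) else window
    center = TIS_WINDOW_FLANK
    score = 0.0
    for rel, weights in _KOZAK_WEIGHTS.items():
        pos = center + rel if rel < 0 else center + 3 + (rel - 3)
        base = seq[pos] if 0 <= pos < len(seq) else "N"
        score += weights.get(base, 0.0)
    return score / _KOZAK_MAX


TISScorer = Callable[[str], float]


def score_tis(window: TISWindow, scorer: TISScorer = kozak_score) -> tuple[float, bool]:
    """Delegate to ``scorer``; positive iff score is strictly > 0.5."""
    score = float(scorer(window.sequence if not isinstance(window, str) else window))
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"TIS scorer returned {score}, outside [0, 1]")
    return score, score > TIS_POSITIVE_THRESHOLD


# --- Intron-retention frame analysis ---------------------------------------


def exon_frame_table(
    ref: ReferenceModel, literal: bool = False
) -> list[ExonFrameRecord]:
    """Per exon with a downstream intron: the genomic codon-grid coordinate
    in frame with the upstream (spliced) coding sequence.

    Frame is anchored at the transcript 5' start (remainder 0 entering the
    first exon) and propagated across exons in transcription order.

    Default mode emits the grid representative shifted 5' of the exon start
    by ``consumed_length mod 3`` nt — congruent mod 3 to the first in-frame
    codon fully inside the exon, validated against a splice-and-translate
    oracle.  ``literal=True`` reproduces the raw published recursion
    (5' shift by the complementary residue), which lands on a different
    codon grid whenever the exon phase is non-zero; it is provided for
    comparison only.
    """
    records: list[ExonFrameRecord] = []
    for gene in ref.genes:
        for t in gene.transcripts:
            exons = t.exons_in_transcription_order()
            if len(exons) < 2:
                continue
            introns = t.introns
            if t.strand == "-":
                introns = list(reversed(introns))
            remainder = 0  # bases of the straddling codon taken by this exon
            for i, exon in enumerate(exons):
                has_downstream_intron = i < len(exons) - 1
                leftover = (len(exon) - remainder) % 3
                if has_downstream_intron:
                    if literal:
                        shift = remainder
                    else:
                        # consumed % 3 == (3 - remainder) % 3
                        shift = (3 - remainder) % 3
                    if t.strand == "+":
                        coord = exon.start - shift
                    else:
                        coord = (exon.end - 1) + shift
                    records.append(
                        ExonFrameRecord(
                            transcript_id=t.transcript_id,
                            chrom=exon.chrom,
                            strand=t.strand,
                            exon=exon,
                            inframe_coordinate=coord,
                            downstream_intron=introns[i],
                        )
                    )
                remainder = (3 - leftover) % 3
    return records


def intron_inframe(
    peptide_interval: GenomicInterval, record: ExonFrameRecord
) -> bool:
    """True iff the peptide's transcription-direction start coordinate lies
    on the codon grid continuing from the upstream exon into the retained
    intron."""
    if peptide_interval.overlap(record.downstream_intron) == 0:
        raise ValueError(
            f"peptide {peptide_interval} does not intersect intron "
            f"{record.downstream_intron}"
        )
    pep5 = peptide_interval.five_prime()
    if record.strand == "+":
        return (pep5 - record.inframe_coordinate) % 3 == 0
    return (record.inframe_coordinate - pep5) % 3 == 0


def ir_check(
    ref: ReferenceModel,
    peptide_intervals: dict[str, list[GenomicInterval]],
    literal: bool = False,
) -> list[IRResult]:
    """For every (peptide, intron it intersects), evaluate the in-frame test
    against the upstream exon of each transcript owning that intron."""
    table = exon_frame_table(ref, literal=literal)
    results: list[IRResult] = []
    for pep, intervals in peptide_intervals.items():
        for iv in intervals:
            for rec in table:
                if rec.strand != iv.strand or rec.chrom != iv.chrom:
                    continue
                if iv.overlap(rec.downstream_intron) == 0:
                    continue
                results.append(
                    IRResult(
                        peptide=pep,
                        intron=rec.downstream_intron,
                        upstream_exon_record=rec,
                        in_frame=intron_inframe(iv, rec),
                    )
                )
    return results
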