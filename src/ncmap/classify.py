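"""Sequential canonical / noncanonical / unmapped peptide annotation.

The decision procedure applied to every de novo peptide:

1. *canonical* — the best proteome window has zero hard mismatches and at
   most one isobaric leucine/isoleucine (Xle) interchange;
2. else *noncanonical* — the peptide occurs verbatim in the pre-mRNA 3FT
   search space (I and L distinguished) AND its best proteome window has at
   least ``min_mismatch`` (default 3) total mismatches;
3. else *unmapped* (includes the buffer zone of peptides 2 mismatches away
   from a protein that also occur in the 3FT).

The proteome scan is an exhaustive substitution-only (Hamming) comparison of
the peptide against every length-matched window of every protein — exact and
deterministic; insertions/deletions are deliberately out of contract since a
7-25-mer either sits in the search space or does not.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .threeft import ThreeFTIndex, TranslatedSegment

DEFAULT_MIN_MISMATCH = 3

_XLE = frozenset("IL")


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    sample_id: str | None = None
    score: float | None = None


@dataclass(frozen=True)
class MismatchProfile:
    hard: int
    li: int

    @property
    def total(self) -> int:
        return self.hard + self.li

    def sort_key(self) -> tuple[int, int]:
        return (self.total, self.hard)


@dataclass
class ClassificationResult:
    peptide: PeptideRecord
    category: str  # canonical | noncanonical | unmapped
    best_proteome_profile: MismatchProfile
    proteome_hits: list[tuple[str, int]] = field(default_factory=list)
    threeft_hits: list[tuple[TranslatedSegment, int]] = field(default_factory=list)


def mismatch_profile(peptide: str, window: str) -> MismatchProfile:
    """Positionwise comparison; I<->L differences counted separately."""
    if len(peptide) != len(window):
        raise ValueError(
            f"length mismatch: {len(peptide)} vs {len(window)}"
        )
    hard = li = 0
    for a, b in zip(peptide, window):
        if a == b:
            continue
        if a in _XLE and b in _XLE:
            li += 1
        else:
            hard += 1
    return MismatchProfile(hard=hard, li=li)


class ProteomeScanner:
    """Vectorized exhaustive Hamming window scan over a proteome.

    Proteins are concatenated into a byte array with sentinel separators;
    windows spanning a protein boundary are masked out.  For each peptide
    the minimum (total, hard) profile over all valid windows is exact.
    """

    _SENTINEL = ord("#")

    def __init__(self, proteome: dict[str, str]):
        if not proteome:
            raise ValueError("proteome must be non-empty")
        self.ids = list(proteome.keys())
        self.seqs = [proteome[i] for i in self.ids]
        blob = "#".join(self.seqs)
        self._arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
        self._arr_xle = np.frombuffer(
            blob.replace("I", "L").encode("ascii"), dtype=np.uint8
        )
        # protein index + local offset per blob position
        self._starts = []
        pos = 0
        for s in self.seqs:
            self._starts.append(pos)
            pos += len(s) + 1
        self._max_len = max(len(s) for s in self.seqs)

    def _locate(self, pos: int) -> tuple[str, int]:
        import bisect

        i = bisect.bisect_right(self._starts, pos) - 1
        return self.ids[i], pos - self._starts[i]

    def min_distance(
        self, peptide: str
    ) -> tuple[MismatchProfile, list[tuple[str, int]]]:
        """Minimum mismatch profile over every length-matched window,
        ordered lexicographically by (hard+li, hard); all argmin windows
        reported as (protein_id, offset)."""
        L = len(peptide)
        if L > self._max_len:
            return MismatchProfile(hard=L, li=0), []
        pep = np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)
        pep_xle = np.frombuffer(
            peptide.replace("I", "L").encode("ascii"), dtype=np.uint8
        )
        n = len(self._arr) - L + 1
        if n <= 0:
            return MismatchProfile(hard=L, li=0), []
        win = np.lib.stride_tricks.sliding_window_view(self._arr, L)
        win_x = np.lib.stride_tricks.sliding_window_view(self._arr_xle, L)
        valid = ~(win == self._SENTINEL).any(axis=1)
        diff = (win != pep).sum(axis=1)           # hard + li
        hard = (win_x != pep_xle).sum(axis=1)     # hard only
        li = diff - hard
        total = hard + li
        if not valid.any():
            return MismatchProfile(hard=L, li=0), []
        # lexicographic (total, hard) minimum over valid windows
        big = np.iinfo(np.int64).max
        key = np.where(valid, total.astype(np.int64) * (L + 1) + hard, big)
        best = key.min()
        idxs = np.nonzero(key == best)[0]
        profile = MismatchProfile(
            hard=int(hard[idxs[0]]), li=int(li[idxs[0]])
        )
        hits = [self._locate(int(i)) for i in idxs]
        return profile, hits


def min_proteome_distance(
    peptide: str, proteome: dict[str, str]
) -> tuple[MismatchProfile, list[tuple[str, int]]]:
    """One-shot convenience wrapper around :class:`ProteomeScanner`."""
    return ProteomeScanner(proteome).min_distance(peptide)


def classify(
    peptide: PeptideRecord | str,
    scanner: ProteomeScanner,
    threeft_index: ThreeFTIndex,
    min_mismatch: int = DEFAULT_MIN_MISMATCH,
    xle_tolerant_3ft: bool = False,
) -> ClassificationResult:
    """Apply the sequential canonical -> noncanonical -> unmapped rule."""
    rec = PeptideRecord(peptide) if isinstance(peptide, str) else peptide
    profile, prot_hits = scanner.min_distance(rec.sequence)
    if profile.hard == 0 and profile.li <= 1:
        return ClassificationResult(
            peptide=rec, category="canonical",
            best_proteome_profile=profile, proteome_hits=prot_hits,
        )
    threeft_hits = threeft_index.lookup(rec.sequence, xle_tolerant=xle_tolerant_3ft)
    if threeft_hits and profile.total >= min_mismatch:
        return ClassificationResult(
            peptide=rec, category="noncanonical",
            best_proteome_profile=profile, proteome_hits=prot_hits,
            threeft_hits=threeft_hits,
        )
    return ClassificationResult(
        peptide=rec, category="unmapped",
        best_proteome_profile=profile, proteome_hits=prot_hits,
        threeft_hits=threeft_hits,
    )


def classify_all(
    peptides: list[PeptideRecord | str],
    proteome: dict[str, str],
    threeft_index: ThreeFTIndex,
    min_mismatch: int = DEFAULT_MIN_MISMATCH,
    xle_tolerant_3ft: bool = False,
) -> list[ClassificationResult]:
    scanner = ProteomeScanner(proteome)
    return [
        classify(p, scanner, threeft_index, min_mismatch, xle_tolerant_3ft)
        for p in peptides
    ]


def export_second_round_db(
    noncanonical: list[str],
    proteome: dict[str, str],
    path: str | Path,
) -> None:
    """Custom second-round database: proteome entries (input order) followed
    by unique noncanonical peptides in lexicographic order, each under a
    deterministic ``NC|{sha1-prefix}|{length}`` header."""
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n{seq}\n")
        for pep in sorted(set(noncanonical)):
            digest = hashlib.sha1(pep.encode("ascii")).hexdigest()[:8]
            fh.write(f">NC|{digest}|{len(pep)}\n{pep}\n")


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read peptides from plain text (one per line) or TSV with a header
    containing at least ``sequence`` (optionally ``sample_id``, ``score``)."""
    records: list[PeptideRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return records
    header = lines[0].split("\t")
    if "sequence" in header:
        idx = {name: i for i, name in enumerate(header)}
        for ln in lines[1:]:
            parts = ln.split("\t")
            records.append(
                PeptideRecord(
                    sequence=parts[idx["sequence"]].upper(),
                    sample_id=(
                        parts[idx["sample_id"]] if "sample_id" in idx else None
                    ),
                    score=(
                        float(parts[idx["score"]])
                        if "score" in idx and parts[idx["score"]] != ""
                        else None
                    ),
                )
            )
    else:
        for ln in lines:
            records.append(PeptideRecord(sequence=ln.split("\t")[0].upper()))
    return records


def read_fasta_proteome(path: str | Path) -> dict[str, str]:
    """Plain FASTA -> {id: sequence}; decoy/contaminant entries (ids starting
    with ``rev_``, ``decoy_`` or ``CON_``) are dropped — they exist only for
    MS FDR control and must not influence proteome distances."""
    out: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line.upper())
    if name is not None:
        out[name] = "".join(parts)
    return {
        k: v
        for k, v in out.items()
        if not k.startswith(("rev_", "decoy_", "CON_"))
    }
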