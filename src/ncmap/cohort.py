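"""Genomic-coordinate overlap of peptide sets between cohorts.

Two peptides from different studies are considered the same event when
their genomic footprints overlap by at least ``min_overlap`` nucleotides
(default 21 nt = 7 amino acids) on the same strand, which tolerates
longer/shorter/partially matching sequences that exact string comparison
would miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome_model import GenomicInterval

DEFAULT_MIN_OVERLAP = 21  # nt == 7 amino acids


@dataclass
class OverlapReport:
    total_a: int
    total_b: int
    shared_a: int
    shared_b: int
    links: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exclusive_a(self) -> int:
        return self.total_a - self.shared_a

    @property
    def exclusive_b(self) -> int:
        return self.total_b - self.shared_b


def overlap_sets(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    ignore_strand: bool = False,
) -> OverlapReport:
    """Count peptides of each set sharing >= ``min_overlap`` nt with any
    peptide of the other set.  ``links`` holds every qualifying (index in A,
    index in B) pair, sorted, making the relation symmetric by construction.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for j, iv in enumerate(set_b):
        key = (iv.chrom, "." if ignore_strand else iv.strand)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, j)
    links: list[tuple[int, int]] = []
    for i, iv in enumerate(set_a):
        key = (iv.chrom, "." if ignore_strand else iv.strand)
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov >= min_overlap:
                links.append((i, hit.data))
    links.sort()
    shared_a = len({i for i, _ in links})
    shared_b = len({j for _, j in links})
    return OverlapReport(
        total_a=len(set_a), total_b=len(set_b),
        shared_a=shared_a, shared_b=shared_b, links=links,
    )


def multiset_overlap(
    sets: dict[str, list[GenomicInterval]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    mode: str = "any",
    ignore_strand: bool = False,
) -> dict[str, dict[str, int]]:
    """Shared/exclusive counts for each named set against all others.

    ``mode="any"``: a peptide is shared if it overlaps a peptide of at
    least one other set; ``mode="all"``: it must overlap every other set.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    names = sorted(sets)
    pair_shared: dict[str, dict[str, set[int]]] = {
        a: {} for a in names
    }
    for ai, a in enumerate(names):
        for b in names[ai + 1 :]:
            rep = overlap_sets(
                sets[a], sets[b], min_overlap=min_overlap,
                ignore_strand=ignore_strand,
            )
            pair_shared[a][b] = {i for i, _ in rep.links}
            pair_shared.setdefault(b, {})[a] = {j for _, j in rep.links}
    out: dict[str, dict[str, int]] = {}
    for a in names:
        others = [pair_shared[a].get(b, set()) for b in names if b != a]
        if mode == "any":
            shared = set().union(*others) if others else set()
        else:
            shared = set.intersection(*others) if others else set()
        out[a] = {
            "total": len(sets[a]),
            "shared": len(shared),
            "exclusive": len(sets[a]) - len(shared),
        }
    return out
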