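"""Deterministic synthetic references with planted ground truth.

Generates toy genomes, annotations, proteomes, peptide sets, frameshift
variants and expression tables in which every planted peptide has a known
category, gene-feature label, intron-retention verdict, upstream start
codon and cancer-selectivity outcome *by construction*.  Every stochastic
choice is drawn from a single seeded generator, so a given seed yields
byte-identical outputs.

Planted categories per gene (three exons, two introns, 5'/3' UTRs):

* canonical peptides — substrings of the gene's protein;
* intronic peptides — one on the retained-intron codon grid of intron 1
  (in frame with the upstream exon) and one off-grid in intron 2;
* a 5'UTR peptide with a single engineered in-frame upstream start codon
  and a stop-free path to it;
* a 3'UTR peptide;
* an exonic peptide planted in an alternative reading frame inside the CDS;
* on alternating genes, a 1-bp coding deletion whose shifted-frame tail
  donates a peptide (frameshift evidence).

Noncanonical plants are verified at generation time by exhaustive scans:
each occurs exactly once across all genes' three-frame pre-mRNA
translations and sits at Hamming distance >= 3 (I/L interchanges counted)
from every length-matched window of every protein; violations trigger
resampling of the planted residues.

The expression generator draws log-normal TPMs whose designed per-tissue
90th percentiles sit well clear of the 1-TPM selectivity cutoff on the
intended side, and asserts the realized percentiles before writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import (
    CODON_TABLE,
    GeneModel,
    GenomicInterval,
    ReferenceModel,
    TranscriptModel,
    reverse_complement,
    translate,
)
from .frameshift import FrameshiftVariant, build_mutant_proteins

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR = {}
for codon, aa in CODON_TABLE.items():
    if aa != "*":
        _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

# filler codons for engineered uORF context: not start, not stop codons
_FILLER_CODONS = ("GCA", "GAA", "AAA", "CCA", "TGG")

SELECTIVITY_DESIGNS = (
    "cancer_selective",
    "expressed_above_cutoff",
    "protein_expressed",
    "panel_detected",
    "testis_only",  # high in testis only -> cancer selective under exclusion
)


@dataclass
class FixtureSpec:
    seed: int = 42
    n_genes: int = 24
    canonical_per_gene: int = 4
    peptide_len: int = 9
    exon_len_range: tuple[int, int] = (120, 180)
    intron_len_range: tuple[int, int] = (90, 150)
    utr5_len: int = 60  # multiple of 3 so transcript and CDS grids agree
    utr3_len: int = 45
    intergenic_gap: int = 300
    n_chroms: int = 2
    tissues: tuple[str, ...] = (
        "brain", "lung", "liver", "colon", "skin", "kidney", "testis",
    )
    samples_per_tissue: int = 10
    protein_evidence_denominator: int = 56
    low_tpm_p90: float = 0.2
    high_tpm_p90: float = 20.0
    testis_tpm_p90: float = 30.0
    tpm_sigma: float = 0.4


@dataclass
class PlantedPeptide:
    sequence: str
    gene_id: str
    category: str  # canonical | noncanonical
    source: str  # canonical | intronic_inframe | intronic_outframe |
    #              utr5 | utr3 | alt_frame | frameshift_tail
    labels: frozenset[str] = frozenset()
    interval: GenomicInterval | None = None
    ir_inframe: bool | None = None
    upstream_start: tuple[str, int] | None = None  # (codon, offset nt)
    selectivity: str | None = None
    variant: FrameshiftVariant | None = None


@dataclass
class Fixture:
    spec: FixtureSpec
    reference: ReferenceModel
    proteome: dict[str, str]
    planted: list[PlantedPeptide]
    variants: list[FrameshiftVariant]
    panel: set[str]
    expression_samples: "object" = None  # pandas DataFrame
    protein_evidence: dict[str, int] = field(default_factory=dict)
    gene_design: dict[str, str] = field(default_factory=dict)

    def peptides(self) -> list[str]:
        return [p.sequence for p in self.planted]

    def peptide_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.planted:
            out.setdefault(p.sequence, []).append(p.gene_id)
        return out


class _GeneLayout:
    """Transcription-local coordinate bookkeeping for one synthetic gene."""

    def __init__(self, rng: np.random.Generator, spec: FixtureSpec):
        self.exon_lens = [
            int(rng.integers(*spec.exon_len_range)) for _ in range(3)
        ]
        self.intron_lens = [
            int(rng.integers(*spec.intron_len_range)) for _ in range(2)
        ]
        self.utr5 = spec.utr5_len
        cds_total = sum(self.exon_lens) - self.utr5 - spec.utr3_len
        self.utr3 = spec.utr3_len + cds_total % 3
        self.length = sum(self.exon_lens) + sum(self.intron_lens)
        # local starts, transcription direction
        self.exon_local = []
        pos = 0
        for i, el in enumerate(self.exon_lens):
            self.exon_local.append((pos, pos + el))
            pos += el
            if i < 2:
                pos += self.intron_lens[i]
        self.intron_local = [
            (self.exon_local[0][1], self.exon_local[1][0]),
            (self.exon_local[1][1], self.exon_local[2][0]),
        ]
        self.cds_local = [
            (self.exon_local[0][0] + self.utr5, self.exon_local[0][1]),
            self.exon_local[1],
            (self.exon_local[2][0], self.exon_local[2][1] - self.utr3),
        ]
        self.cds_len = sum(b - a for a, b in self.cds_local)


def _encode(rng: np.random.Generator, aa_seq: str) -> str:
    return "".join(
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))] for aa in aa_seq
    )


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[int(i)] for i in rng.integers(0, len(AA20), n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, n))


def _hamming_ok(peptide: str, proteome: dict[str, str], min_mismatch: int = 3
                ) -> bool:
    """Exhaustive window scan: total mismatches (I/L counted) >= min."""
    L = len(peptide)
    for seq in proteome.values():
        for off in range(len(seq) - L + 1):
            if sum(a != b for a, b in zip(peptide, seq[off : off + L])) < min_mismatch:
                return False
    return True


def _count_3ft_occurrences(peptide: str, premrna_translations: list[str]) -> int:
    n = 0
    for aa in premrna_translations:
        start = 0
        while True:
            pos = aa.find(peptide, start)
            if pos < 0:
                break
            n += 1
            start = pos + 1
    return n


def make_reference(spec: FixtureSpec | None = None) -> Fixture:
    """Build the full fixture: reference, proteome, plants, variants,
    expression tables, with all construction-time guarantees verified."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    k = spec.peptide_len

    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(spec.n_chroms)
    }
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_parts}

    genes: list[GeneModel] = []
    proteome: dict[str, str] = {}
    planted: list[PlantedPeptide] = []
    variants: list[FrameshiftVariant] = []
    gene_design: dict[str, str] = {}
    # local-layout record per gene, needed for frameshift planting later
    layouts: dict[str, tuple[_GeneLayout, str, int, str]] = {}

    pending: list[dict] = []  # per-gene noncanonical plants awaiting checks

    for gi in range(spec.n_genes):
        gene_id = f"G{gi + 1:03d}"
        lay = _GeneLayout(rng, spec)
        strand = "+" if gi % 2 == 0 else "-"
        chrom = f"chr{(gi % spec.n_chroms) + 1}"

        seq = list(_random_nt(rng, lay.length))

        # --- CDS fill: ATG + random codons + TAA, spliced across exons
        n_codons = lay.cds_len // 3
        protein_aa = _random_peptide(rng, n_codons - 2)
        cds_nt = "ATG" + _encode(rng, protein_aa) + "TAA"
        pos = 0
        for a, b in lay.cds_local:
            seq[a:b] = cds_nt[pos : pos + (b - a)]
            pos += b - a

        plants: dict[str, dict] = {}

        # --- 5'UTR peptide + engineered upstream start codon
        p5 = lay.utr5 - 3 * k - 3  # leave one spare codon before CDS
        p5 -= p5 % 3  # keep a clean codon strip upstream
        if p5 < 9:
            raise ValueError("utr5_len too small for the 5'UTR plant")
        n_up = p5 // 3
        start_slot = int(rng.integers(1, n_up))  # not the very first codon
        for s in range(n_up):
            codon = "CTG" if s == start_slot else _FILLER_CODONS[
                int(rng.integers(len(_FILLER_CODONS)))
            ]
            seq[3 * s : 3 * s + 3] = codon
        plants["utr5"] = {
            "local": p5,
            "labels": frozenset({"five_prime_utr"}),
            "upstream_start": ("CTG", p5 - 3 * start_slot),
        }

        # --- 3'UTR peptide
        e3a, e3b = lay.exon_local[2]
        p3 = e3b - lay.utr3 + 3  # margin past the stop codon
        if p3 + 3 * k > e3b - 3:
            raise ValueError("utr3 too small for the 3'UTR plant")
        plants["utr3"] = {
            "local": p3, "labels": frozenset({"three_prime_utr"}),
        }

        # --- intronic peptides: intron 1 on-grid, intron 2 off-grid
        for which, (ia, ib), inframe in (
            (0, lay.intron_local[0], True),
            (1, lay.intron_local[1], False),
        ):
            consumed = sum(
                lay.exon_lens[j] for j in range(which + 1)
            )  # spliced length upstream of this intron
            # retained-intron codon grid: local p with (p - ia + consumed) % 3 == 0
            base = ia + 6
            aligned = base + (-(base - ia + consumed)) % 3
            p = aligned if inframe else aligned + 1
            if p + 3 * k > ib - 6:
                raise ValueError("intron too small for the intronic plant")
            plants[f"intron{which}"] = {
                "local": p, "labels": frozenset({"intronic"}),
                "ir_inframe": inframe,
            }

        # --- exonic alternative-frame peptide (inside exon 2 = pure CDS)
        e2a, e2b = lay.exon_local[1]
        consumed1 = lay.exon_lens[0] - lay.utr5  # CDS bases in exon 1
        phase2 = (3 - consumed1 % 3) % 3
        cds_class = (e2a + phase2) % 3
        p_alt = e2a + 9
        p_alt += (cds_class + 1 - p_alt) % 3  # a different congruence class
        if p_alt + 3 * k > e2b - 9:
            raise ValueError("exon 2 too small for the alt-frame plant")
        plants["alt_frame"] = {
            "local": p_alt, "labels": frozenset({"exonic_alt_frame"}),
        }

        # encode noncanonical plants (resampled later if scans object)
        for name, info in plants.items():
            info["gene_id"] = gene_id
            info["sequence"] = None  # assigned in the verification loop

        genomic_off = chrom_pos[chrom]
        layouts[gene_id] = (lay, strand, genomic_off, chrom)
        pending.append({"gene_id": gene_id, "plants": plants, "seq": seq})

        # gene placement bookkeeping (sequence text appended after plants
        # are finalized, below)
        chrom_pos[chrom] += lay.length + spec.intergenic_gap
        gene_design[gene_id] = SELECTIVITY_DESIGNS[gi % len(SELECTIVITY_DESIGNS)]

    # ---- plant + verify loop ------------------------------------------------
    # First pass: encode every noncanonical plant; then verify Hamming and
    # 3FT-uniqueness against the fully assembled toy genome, resampling
    # offending plants until clean.
    def encode_plant(entry: dict, info: dict) -> None:
        pep = _random_peptide(rng, k)
        nt = _encode(rng, pep)
        p = info["local"]
        entry["seq"][p : p + 3 * k] = nt
        info["sequence"] = pep

    def cds_is_clean(entry: dict, gene_id: str) -> bool:
        lay = layouts[gene_id][0]
        s = "".join(entry["seq"])
        cds = "".join(s[a:b] for a, b in lay.cds_local)
        aa = translate(cds, 0)
        return "*" not in aa[:-1] and aa[-1] == "*" and aa[0] == "M"

    for entry in pending:
        for name, info in entry["plants"].items():
            encode_plant(entry, info)
            if name == "alt_frame":
                tries = 0
                while not cds_is_clean(entry, entry["gene_id"]):
                    tries += 1
                    if tries > 200:
                        raise RuntimeError("could not plant alt-frame peptide")
                    encode_plant(entry, info)

    def assemble() -> tuple[dict[str, str], dict[str, str]]:
        parts = {c: [] for c in chrom_parts}
        fill_pos = {c: 0 for c in chrom_parts}
        gap_rng = np.random.default_rng(spec.seed + 1)
        for entry in pending:
            gene_id = entry["gene_id"]
            lay, strand, off, chrom = layouts[gene_id]
            local = "".join(entry["seq"])
            block = local if strand == "+" else reverse_complement(local)
            parts[chrom].append(block)
            parts[chrom].append(_random_nt(gap_rng, spec.intergenic_gap))
            fill_pos[chrom] += lay.length + spec.intergenic_gap
        chroms = {c: "".join(p) for c, p in parts.items()}
        prots = {}
        for entry in pending:
            gene_id = entry["gene_id"]
            lay = layouts[gene_id][0]
            s = "".join(entry["seq"])
            cds = "".join(s[a:b] for a, b in lay.cds_local)
            prots[f"P_{gene_id}"] = translate(cds, 0)[:-1]
        return chroms, prots

    def premrna_translations(chroms: dict[str, str]) -> list[str]:
        out = []
        for entry in pending:
            gene_id = entry["gene_id"]
            lay, strand, off, chrom = layouts[gene_id]
            raw = chroms[chrom][off : off + lay.length]
            pre = raw if strand == "+" else reverse_complement(raw)
            for f in (0, 1, 2):
                out.append(translate(pre, f))
        return out

    for _round in range(60):
        chroms, prots = assemble()
        translations = premrna_translations(chroms)
        dirty = False
        seen: set[str] = set()
        for entry in pending:
            for name, info in entry["plants"].items():
                pep = info["sequence"]
                ok = (
                    pep not in seen
                    and _hamming_ok(pep, prots)
                    and _count_3ft_occurrences(pep, translations) == 1
                )
                if ok:
                    seen.add(pep)
                    continue
                dirty = True
                encode_plant(entry, info)
                if name == "alt_frame":
                    while not cds_is_clean(entry, entry["gene_id"]):
                        encode_plant(entry, info)
        if not dirty:
            break
    else:
        raise RuntimeError("fixture generation failed to converge")

    # ---- build the reference model -----------------------------------------
    def local_to_genomic(gene_id: str, a: int, b: int) -> GenomicInterval:
        lay, strand, off, chrom = layouts[gene_id]
        if strand == "+":
            return GenomicInterval(chrom, off + a, off + b, strand)
        return GenomicInterval(
            chrom, off + lay.length - b, off + lay.length - a, strand
        )

    for entry in pending:
        gene_id = entry["gene_id"]
        lay, strand, off, chrom = layouts[gene_id]
        span = local_to_genomic(gene_id, 0, lay.length)
        exons = [local_to_genomic(gene_id, a, b) for a, b in lay.exon_local]
        cds = [local_to_genomic(gene_id, a, b) for a, b in lay.cds_local]
        t = TranscriptModel(
            transcript_id=f"T_{gene_id}", exons=exons, cds=cds, strand=strand
        )
        genes.append(
            GeneModel(
                gene_id=gene_id, gene_name=gene_id, biotype="protein_coding",
                chrom=chrom, strand=strand, span=span, transcripts=[t],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span.start))
    reference = ReferenceModel(chromosomes=chroms, genes=genes)
    proteome = prots

    # ---- planted records ----------------------------------------------------
    panel: set[str] = set()
    for entry in pending:
        gene_id = entry["gene_id"]
        design = gene_design[gene_id]
        sel = {
            "cancer_selective": "cancer_selective",
            "expressed_above_cutoff": "expressed_above_cutoff",
            "protein_expressed": "protein_expressed",
            "panel_detected": "non_cancer_selective_ms",
            "testis_only": "cancer_selective",
        }[design]
        for name, info in entry["plants"].items():
            p = info["local"]
            planted.append(
                PlantedPeptide(
                    sequence=info["sequence"],
                    gene_id=gene_id,
                    category="noncanonical",
                    source={"intron0": "intronic_inframe",
                            "intron1": "intronic_outframe"}.get(name, name),
                    labels=info["labels"],
                    interval=local_to_genomic(gene_id, p, p + 3 * k),
                    ir_inframe=info.get("ir_inframe"),
                    upstream_start=info.get("upstream_start"),
                    selectivity=sel,
                )
            )
            if design == "panel_detected":
                panel.add(info["sequence"])

    # canonical peptides: substrings of each protein
    for entry in pending:
        gene_id = entry["gene_id"]
        prot = proteome[f"P_{gene_id}"]
        offs = rng.choice(
            len(prot) - k, size=spec.canonical_per_gene, replace=False
        )
        for off in sorted(int(o) for o in offs):
            planted.append(
                PlantedPeptide(
                    sequence=prot[off : off + k],
                    gene_id=gene_id,
                    category="canonical",
                    source="canonical",
                )
            )

    # ---- frameshift variants on alternating genes ---------------------------
    translations = premrna_translations(chroms)
    for gi, entry in enumerate(pending):
        if gi % 2 != 0:
            continue
        gene_id = entry["gene_id"]
        lay, strand, off, chrom = layouts[gene_id]
        # spliced-CDS offsets covered by exon 2 (entirely coding)
        c2s = lay.exon_lens[0] - lay.utr5
        c2e = c2s + lay.exon_lens[1]
        placed = False
        for _try in range(40):
            o = c2s + 3 + int(rng.integers(0, lay.exon_lens[1] - 45))
            # genomic anchor of spliced CDS offset o (deletion of 1 base)
            local = lay.cds_local[1][0] + (o - c2s)
            iv = local_to_genomic(gene_id, local, local + 2)
            if strand == "+":
                vref = reference.chromosomes[chrom][iv.start : iv.start + 2]
                pos = iv.start + 1  # VCF 1-based
                valt = vref[0]
            else:
                vref = reference.chromosomes[chrom][iv.start : iv.start + 2]
                pos = iv.start + 1
                valt = vref[0]
            try:
                var = FrameshiftVariant(
                    chrom=chrom, pos=pos, ref=vref, alt=valt,
                    transcript_id=f"T_{gene_id}",
                )
                mut = build_mutant_proteins(reference, [var])[0]
            except (ValueError, KeyError):
                continue
            # peptide from tail codons mapping back inside exon 2
            tail_start_codon = len(mut.prefix)
            chosen = None
            for j in range(tail_start_codon + 2, tail_start_codon + len(mut.tail) - k):
                orig = 3 * j + 1  # original spliced-CDS position of codon j
                if orig < c2s or orig + 3 * k > c2e:
                    continue
                pep = mut.full_seq[j : j + k]
                if len(pep) < k:
                    break
                if (
                    _hamming_ok(pep, proteome)
                    and _count_3ft_occurrences(pep, translations) == 1
                    and pep not in {q.sequence for q in planted}
                ):
                    chosen = (pep, j)
                    break
            if chosen is None:
                continue
            pep, j = chosen
            orig = 3 * j + 1
            local_p = lay.cds_local[1][0] + (orig - c2s)
            variants.append(var)
            planted.append(
                PlantedPeptide(
                    sequence=pep,
                    gene_id=gene_id,
                    category="noncanonical",
                    source="frameshift_tail",
                    labels=frozenset({"exonic_alt_frame"}),
                    interval=local_to_genomic(gene_id, local_p, local_p + 3 * k),
                    selectivity={
                        "cancer_selective": "cancer_selective",
                        "expressed_above_cutoff": "expressed_above_cutoff",
                        "protein_expressed": "protein_expressed",
                        "panel_detected": "non_cancer_selective_ms",
                        "testis_only": "cancer_selective",
                    }[gene_design[gene_id]],
                    variant=var,
                )
            )
            if gene_design[gene_id] == "panel_detected":
                panel.add(pep)
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place frameshift plant in {gene_id}")

    fixture = Fixture(
        spec=spec, reference=reference, proteome=proteome, planted=planted,
        variants=variants, panel=panel, gene_design=gene_design,
    )
    make_expression(fixture, rng)
    return fixture


def make_expression(fixture: Fixture, rng: np.random.Generator) -> None:
    """Sample-level TPM draws with designed 90th percentiles, plus the
    protein-evidence table; realized percentiles are asserted against the
    design before acceptance."""
    import pandas as pd

    spec = fixture.spec
    z90 = 1.2815515655446004  # standard normal 90th percentile
    rows = []
    evidence: dict[str, int] = {}
    for gene_id, design in fixture.gene_design.items():
        if design == "expressed_above_cutoff":
            hot = spec.tissues[
                int(rng.integers(0, len(spec.tissues) - 1))
            ]  # never testis (last entry)
        else:
            hot = None
        for tissue in spec.tissues:
            if design == "testis_only" and tissue == "testis":
                target = spec.testis_tpm_p90
            elif hot is not None and tissue == hot:
                target = spec.high_tpm_p90
            else:
                target = spec.low_tpm_p90
            mu = np.log(target) - z90 * spec.tpm_sigma
            vals = np.exp(
                rng.normal(mu, spec.tpm_sigma, spec.samples_per_tissue)
            )
            realized = float(np.percentile(vals, 90))
            if (target > 1) != (realized > 1):
                raise RuntimeError(
                    f"expression design violated for {gene_id}/{tissue}: "
                    f"target p90 {target}, realized {realized:.3f}"
                )
            for si, v in enumerate(vals):
                rows.append(
                    {"gene": gene_id, "tissue": tissue,
                     "sample": f"{tissue}_{si}", "tpm": float(v)}
                )
        evidence[gene_id] = {
            "cancer_selective": 0,
            "expressed_above_cutoff": 0,
            "protein_expressed": 5,
            "panel_detected": 0,
            "testis_only": 0,
        }[design]
    fixture.expression_samples = pd.DataFrame(rows)
    fixture.protein_evidence = evidence


# ---- serialization ---------------------------------------------------------


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/GTF/TSV/VCF files consumed by the other modules."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "genome.fa"
    with open(p, "w") as fh:
        for name in sorted(fixture.reference.chromosomes):
            seq = fixture.reference.chromosomes[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = p
    for suffix in (".fai",):  # stale pyfaidx indexes break reloads
        idx = Path(str(p) + suffix)
        if idx.exists():
            idx.unlink()

    p = outdir / "annotation.gtf"
    with open(p, "w") as fh:
        for g in fixture.reference.genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tncmap\tgene\t{g.span.start + 1}\t{g.span.end}\t"
                f".\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\tncmap\ttranscript\t{t.exons[0].start + 1}\t"
                    f"{t.exons[-1].end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\tncmap\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                for c in t.cds or []:
                    fh.write(
                        f"{g.chrom}\tncmap\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
    paths["gtf"] = p

    p = outdir / "proteome.fa"
    with open(p, "w") as fh:
        for pid in sorted(fixture.proteome):
            fh.write(f">{pid}\n{fixture.proteome[pid]}\n")
    paths["proteome"] = p

    p = outdir / "peptides.tsv"
    with open(p, "w") as fh:
        fh.write("sequence\tsample_id\tscore\n")
        for pl in fixture.planted:
            fh.write(f"{pl.sequence}\tS1\t\n")
    paths["peptides"] = p

    p = outdir / "truth.tsv"
    with open(p, "w") as fh:
        fh.write(
            "sequence\tgene_id\tcategory\tsource\tlabels\tir_inframe\t"
            "upstream_start\tselectivity\n"
        )
        for pl in fixture.planted:
            labels = ",".join(sorted(pl.labels)) if pl.labels else ""
            ir = "" if pl.ir_inframe is None else str(pl.ir_inframe)
            ups = (
                f"{pl.upstream_start[0]}@{pl.upstream_start[1]}"
                if pl.upstream_start else ""
            )
            fh.write(
                f"{pl.sequence}\t{pl.gene_id}\t{pl.category}\t{pl.source}\t"
                f"{labels}\t{ir}\t{ups}\t{pl.selectivity or ''}\n"
            )
    paths["truth"] = p

    p = outdir / "variants.vcf"
    with open(p, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,'
            'Description="Affected transcript">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(fixture.variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"TRANSCRIPT={v.transcript_id}\n"
            )
    paths["vcf"] = p

    p = outdir / "expression_samples.tsv"
    fixture.expression_samples.to_csv(p, sep="\t", index=False)
    paths["expression"] = p

    p = outdir / "protein_evidence.tsv"
    with open(p, "w") as fh:
        fh.write("gene\ttissues_with_protein\tdenominator\n")
        for gene in sorted(fixture.protein_evidence):
            fh.write(
                f"{gene}\t{fixture.protein_evidence[gene]}\t"
                f"{fixture.spec.protein_evidence_denominator}\n"
            )
    paths["protein_evidence"] = p

    p = outdir / "panel.txt"
    with open(p, "w") as fh:
        for pep in sorted(fixture.panel):
            fh.write(pep + "\n")
    paths["panel"] = p

    p = outdir / "peptide_genes.tsv"
    with open(p, "w") as fh:
        fh.write("peptide\tgenes\n")
        for pep, gs in sorted(fixture.peptide_genes().items()):
            fh.write(f"{pep}\t{','.join(sorted(set(gs)))}\n")
    paths["peptide_genes"] = p

    return paths
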