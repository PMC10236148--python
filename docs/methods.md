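# Methods

This note documents the models, conventions and numerical choices behind
`ncmap`, and what the synthetic fixtures do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. GTF input
(1-based closed) and BED output (0-based half-open) are converted exactly
once, at the I/O boundary. This removes the ±1 ambiguity that plagues
frame arithmetic; the conversion is a bijection and is property-tested.
For minus-strand features, "5′ base" always means the transcription-
direction first base, i.e. the genomically highest coordinate (`end − 1`).

## Three-frame pre-mRNA translation (3FT)

The noncanonical search space is the *unspliced* sense pre-mRNA of every
gene with a `protein_coding` biotype, translated in frames 0/1/2 with the
standard codon table (stop → `*`, any codon containing `N` → `X`; no
selenocysteine handling). Translations are split at `*` and `X` into
maximal stop-free segments; segments shorter than `min_len` (default 7 aa,
the shortest peptide the downstream search considers) are dropped —
anything shorter is unmatchable, and splitting at `X` is required because
peptides cannot be matched through unknown residues. Antisense frames are
deliberately excluded: the search space is sense pre-mRNA only.

Each segment carries a genomic **anchor**: the coordinate of the first
base of its first codon (for minus-strand genes, the genomically highest
base of that codon). A peptide at amino-acid offset `a`, length `k` maps to
`[anchor + 3a, anchor + 3(a+k))` on the plus strand and
`[anchor − 3(a+k) + 1, anchor − 3a + 1)` on the minus strand; re-translating
the mapped slice reproduces the peptide exactly (round-trip tested on both
strands). Overlapping genes yield independent segments under distinct
headers so coordinate recovery stays gene-resolved.

## Peptide classification

Proteome matching is an exhaustive substitution-only (Hamming) scan over
every length-matched window of every protein, vectorized with numpy over a
sentinel-separated concatenation (windows spanning protein boundaries are
masked). Substitution-only scanning is exact and deterministic at 7–25-mer
scale; insertions/deletions are out of contract. Decoy (`rev_`, `decoy_`)
and contaminant (`CON_`) entries are excluded — they exist only for MS FDR
control.

Mismatches are counted in two classes: `li` for Leu/Ile interchanges
(isobaric, indistinguishable by standard tandem MS) and `hard` for
everything else; windows are ranked lexicographically by
`(hard + li, hard)`. The sequential rule is then:

1. **canonical** iff the best window has `hard == 0` and `li ≤ 1`;
2. else **noncanonical** iff the peptide occurs verbatim in the 3FT (I and
   L distinguished) and the best proteome window has `hard + li ≥ 3`;
3. else **unmapped** (including the buffer zone at distance 2).

Two readings of the mismatch rules coexist in the literature-facing
surface: whether the ≥ 3 rule counts Xle interchanges. Here it does
(`hard + li`), which together with the `li ≤ 1` canonical tolerance
reproduces both rules without contradiction; tightening the threshold can
only shrink the noncanonical set (monotonicity is tested). 3FT lookup is
exact by default; an `xle_tolerant` mode allowing a single I/L interchange
exists solely for comparing against peptide sets published by other
groups, which were mapped under that allowance.

## Gene-feature annotation

Noncanonical peptides are labeled per transcript and unioned — the
categories (5′UTR, intronic, 3′UTR, exonic-alternative-frame) are not
mutually exclusive because transcripts overlap. UTRs are derived from the
CDS extent when absent from the GTF (exonic sequence 5′/3′ of the CDS,
strand-aware). Exonic-alternative-frame requires ≥ 1 nt overlap with a CDS
interval *and* disagreement between the peptide's codon-start congruence
class (mod 3, from its 3FT anchor) and the CDS codon grid of that exon
(phase-propagated across splice junctions). A peptide on the CDS grid over
its whole span can never receive the label — it would be canonical
sequence, and this cross-check is asserted against the classifier on
fixtures. Any nonzero overlap counts; no minimum is imposed.

## Upstream ORF scan and TIS scoring

The scan walks 5′-ward from the peptide's first codon in steps of 3 —
only the peptide's own reading frame can produce it — reporting every
ATG/CTG/TTG/GTG/ACG codon, nearest first, and stops at the first stop
codon, the reference edge, or (by default) the gene-span boundary, since
3FT segments are gene-scoped; unbounded scanning is available. By
construction every reported start yields a stop-free ORF containing the
peptide.

Candidate starts are scored on a 203-nt window (100 nt flank each side of
the codon, on the coding strand, N-padded at reference edges) built from
the *genomic* (pre-mRNA) context, consistent with the unspliced search
space. Scoring is pluggable (any callable mapping the 203-nt string to
[0, 1]; > 0.5 is a positive call). The bundled default is a position-weight
Kozak-context heuristic — a deterministic stand-in that rewards the
`gccRccATGG` consensus (purine at −3 and G at +4 dominate); it is **not**
a trained initiation-site predictor, and production analyses should inject
one.

## Intron-retention frame test

For each transcript, the reading frame is anchored at the transcript 5′
start and propagated across exons in transcription order: entering an exon
with `remainder` bases owed to the previous codon, the exon leaves
`leftover = (exon_length − remainder) mod 3` dangling bases and passes
`remainder′ = (3 − leftover) mod 3` to the next exon. The same formula is
used on both strands (the strand enters only through transcription order
and the direction of the 5′ shift), and for each exon with a downstream
intron the emitted `inframe_coordinate` is the codon-grid representative
shifted at most 2 nt 5′ of the exon's 5′ start.

The representative is chosen to lie on the grid obtained by splicing the
upstream exons, translating from the transcript start, and continuing into
the retained intron — i.e. it is congruent mod 3 to the first in-frame
codon fully contained in the exon (`exon 5′ start + remainder`). A widely
circulated recursion instead shifts 5′ by `remainder` itself, which lands
on a different codon grid whenever the entering phase is nonzero; that
variant is kept behind `literal=True` for comparison but fails the
splice-and-translate oracle, which is the ground truth the default is
validated against (100 random transcripts, both strands, exact agreement).

An intronic peptide is *in frame* with its upstream exon iff its
transcription-direction start coordinate lies on the record's grid
(difference ≡ 0 mod 3). Peptides in introns shared by several transcripts
are evaluated per transcript and reported individually (any-true summary in
the pipeline), mirroring the multi-label philosophy.

## Frameshift proteome

Only simple single-indel frameshifts are modeled (|Δlen| mod 3 ≠ 0),
matching per-record VCF structure; the REF allele is verified against the
reference (hard error on mismatch — it indicates a corrupt VCF/reference
pairing). The edit is applied to the spliced CDS; translation from the CDS
start yields a canonical `prefix` (codons fully 5′ of the first changed
base) and a novel `tail` running to the first stop in the shifted frame
(stop excluded; records without a stop in the available sequence are
flagged `no_stop_found`). Downstream sequence is read through the spliced
transcript first and then the genomic continuation past the transcript end
(`mode="spliced"`, default); `mode="genomic"` instead reads straight
through the unspliced genome past the CDS end. Both are exposed because
published annotation toolkits do not document this choice.

Peptide evidence requires an exact match (I/L distinguished) overlapping
at least one tail residue: prefix-only matches are canonical sequence and
are excluded — the classifier already accounts for them.

## Cohort comparison

Peptide sets are intersected by genomic coordinates with a minimum overlap
of 21 nt (7 aa) on half-open intervals, same strand required by default —
peptides from opposite strands encode different sequences — with an
`ignore_strand` flag for replicating tools that do not record strand.
Counts are per-peptide (not merged clusters); the link relation is
symmetric by construction, and results are invariant under input
permutation. For 3 or more sets, "shared" is reported under an any-overlap
definition by default, with an all-overlap mode available. The interval
index is validated against an all-pairs oracle (exact, 1,000×1,000).

## Cancer-selectivity triage

Steps run strictly in order; the first failing step labels the peptide:

1. membership in the panel of normal immunopeptidomes (exact sequence
   equality) → `non_cancer_selective_ms`;
2. transcript expression: per (gene, tissue), the 90th percentile of
   sample-level TPM (linear interpolation by default; nearest-rank
   available) must be `< 1 TPM` in **every** non-excluded tissue for
   **every** parent gene (conservative AND over multi-gene peptides).
   Testis is excluded by default as an immune-privileged site; the
   exclusion applies to step 3 likewise. Empty cells are missing, never
   zero; missing genes are a hard error by default (`missing="fail"` to
   demote);
3. protein evidence: any parent gene with protein expression in > 0
   healthy tissues → `protein_expressed`; otherwise `cancer_selective`.

The per-tissue cutoff (not the mean) is the operative filter; published
candidate tables report a mean TPM as a display summary, and the bundled
shortlist is triaged through step 3 on its printed per-gene tissue counts.

HLA utilities binarize eluted-ligand percentile ranks at ≤ 0.5 % (strong
binders, inclusive) and compare alleles by cosine distance of binding
profiles; all-zero profiles are a named error since the distance is
undefined. Any 2-D embedding of the distance matrix is left to standard
libraries and is not part of the contract.

## De novo score calibration

Sequence-level accuracy (whole peptide, I≡L, PTM annotations stripped) is
the default; residue-level accuracy is available by flag. The calibrator
picks the smallest candidate threshold (over distinct scores) whose
retained set `{score ≥ t}` reaches the target accuracy (default 0.90),
breaking ties toward the larger retained set; if even the top-scored
subset fails, the result is flagged unattainable (threshold +∞). The
implementation is checked against a full cutoff scan up to n = 10⁴.

## Synthetic fixtures

The generator emulates the *structure* of the real problem at toy scale:
multi-exon genes on both strands (3 exons, 2 introns, 5′/3′ UTRs, CDS
with ATG…stop), peptides planted per category (canonical substrings;
intronic on/off the retained-intron grid; 5′UTR peptides with a single
engineered in-frame upstream CTG and stop-free path; 3′UTR; exonic
alternative-frame; frameshift tails from planted 1-bp coding deletions),
GTEx-style sample-level TPM tables (log-normal draws whose designed
per-tissue 90th percentiles sit well clear of 1 TPM on the intended side,
asserted before acceptance), HPA-style protein-evidence counts over a
56-tissue denominator, and a panel of normals. Defaults: 24 genes on 2
chromosomes (< 100 kb total), 9-mer peptides, 228 planted peptides, 7
tissues × 10 samples. All stochastic choices come from a single seeded
generator; a given seed reproduces byte-identical files.

Construction guarantees are verified at generation time by independent
exhaustive scans (every noncanonical plant is ≥ 3 mismatches from every
proteome window and occurs exactly once across all genes' three-frame
translations; violations trigger resampling of the planted residues), so
the planted truth is sound for any seed.

What passing fixture tests does **not** show: performance or correctness
at human-genome scale (toy chromosomes avoid overlapping genes, alternative
transcripts of one gene, and N runs), robustness to real de novo error
profiles (fixture peptides are error-free), PTM-bearing peptides, or the
behavior of a trained TIS model. Those belong to the upstream MS stages
and real-data runs, which are outside this package's scope.

## Problem sizes and tolerances

Tests and the acceptance script run the generator at its default scale
(24 genes, 228 planted peptides) and oracle comparisons at 50–10,000
items — sizes chosen so the full suite completes in well under a minute on
one core while exercising every code path; all oracle comparisons are
exact (no tolerance), and floating-point checks use standard relative
tolerances (`pytest.approx`).
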