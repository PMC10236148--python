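# ncmap

Proteogenomic annotation of **noncanonical MHC class I-associated peptides
(ncMAPs)** — peptides presented on the cell surface that originate outside
annotated protein-coding sequence (5′UTRs, introns, 3′UTRs, alternative
reading frames of exons, frameshift-mutant proteomes).

Tumor cells present such peptides at appreciable rates, and those whose
parent genes are silent in healthy tissues are attractive, shareable
immunotherapy targets. `ncmap` implements the post-identification half of
an immunopeptidomics workflow: it takes peptide sequences (from de novo
sequencing or database search) plus standard references, and answers *where
in the genome does this peptide come from, what mechanism could translate
it, and is it cancer-selective?*

## What it does

1. **Search space** — for every protein-coding gene, the unspliced
   pre-mRNA is translated in all three sense frames (3FT) and split into
   stop-free segments (default ≥ 7 aa). Each FASTA header encodes a
   genomic anchor, so any matched peptide is projected back to exact
   genomic coordinates (BED).
2. **Classification** — a sequential rule: a peptide is *canonical* if its
   best proteome window has zero mismatches apart from at most one
   isobaric Leu/Ile (Xle) interchange; otherwise *noncanonical* if it
   occurs verbatim in the 3FT **and** is ≥ 3 mismatches from every
   proteome window (an exhaustive, exact Hamming window scan); otherwise
   *unmapped*. The 2-mismatch "buffer zone" guards against de novo
   sequencing errors masquerading as novel peptides.
3. **Mechanism** — per noncanonical peptide: gene-feature labels (5′UTR /
   intronic / 3′UTR / exonic-alternative-frame; multi-label, unioned over
   transcripts); an in-frame upstream scan for canonical and near-cognate
   start codons (ATG, CTG, TTG, GTG, ACG) up to the first stop, with
   203-nt translation-initiation windows scored by a pluggable scorer; an
   intron-retention test asking whether an intronic peptide lies on the
   codon grid propagated from its upstream exons; and exact matching
   against mutant proteins built from coding frameshift indels (VCF),
   requiring overlap with the novel C-terminal tail.
4. **Cohorts and selectivity** — peptide sets from different studies are
   intersected by genomic coordinates (≥ 21 nt ≈ 7 aa overlap, same
   strand), tolerating partially matching sequences; cancer selectivity is
   a three-step triage: absent from a panel of healthy immunopeptidomes →
   every parent gene below 1 TPM (90th-percentile per healthy tissue,
   testis excluded as immune-privileged) → no parent protein expression in
   any healthy tissue.
5. **Calibration & HLA utilities** — per-sample de novo score thresholds
   controlling sequence-level accuracy (I≡L) at a target (default 90%),
   and allele-similarity analysis from binarized eluted-ligand ranks
   (strong binder ≤ 0.5%) via cosine distances.

A deterministic synthetic-fixture generator (`ncmap make-fixture`) builds
toy genomes with peptides planted in every category, with guarantees
(Hamming ≥ 3 from the proteome, unique 3FT occurrence, designed reading
frames and expression percentiles) verified at generation time — so the
entire pipeline is testable without downloads.

## Worked example

Build a search space and classify peptides on a bundled-style toy fixture:

```bash
ncmap make-fixture --seed 42 --out demo/
ncmap build-3ft --genome demo/genome.fa --gtf demo/annotation.gtf --out demo/3ft.fa
# 125 segments -> demo/3ft.fa
ncmap classify --peptides demo/peptides.tsv --proteome demo/proteome.fa \
    --threeft demo/3ft.fa --out demo/cls.tsv
# classified 57 peptides -> demo/cls.tsv
head -3 demo/cls.tsv
```

```
sequence	category	hard	li	proteome_hits	threeft_hits
VHFEFLCKV	noncanonical	5	0	P_G003@68;P_G004@23	3FT|G001|chr1|+|0|0|0@10
RWLCIKWWN	noncanonical	5	0	P_G001@41;P_G005@55	3FT|G001|chr1|+|0|636|3@1
```

`hard`/`li` are the best proteome window's non-Xle and Xle mismatch counts
(≥ 3 total required for a noncanonical call); the 3FT hit column gives the
segment header (gene, chromosome, strand, frame, genomic anchor) plus the
amino-acid offset, from which BED coordinates follow.

Triage the bundled published shortlist of candidate peptides (24 peptides
whose parent genes are below 1 TPM in healthy tissue) through the
protein-evidence step:

```python
>>> from ncmap.candidates import triage_candidates
>>> res = triage_candidates()
>>> res.head(4)
        peptide              label
0     AFAPFPTQF   cancer_selective
1     DYIHFVHHF   cancer_selective
2  EALSASQALYTR  protein_expressed
3      ELIKAFSK  protein_expressed
>>> (res["label"] == "cancer_selective").sum()
17
```

17 of the 24 candidates have no parent protein expression in any of 56
healthy tissues and are labeled cancer-selective; the rest (e.g. the
histone-derived `EALSASQALYTR`, protein-expressed in 43 of 56 tissues) are
rejected despite near-zero transcript levels.

The full pipeline (`ncmap run -c config.yaml`) chains all stages and
writes BED/TSV outputs plus a JSON summary with per-stage counts.

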