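"""Upstream ORF scanning, TIS windows, and intron-retention frame logic."""

import numpy as np
import pytest

from ncmap.genome_model import (
    GenomicInterval,
    reverse_complement,
    translate,
)
from ncmap.orf_ir import (
    ExonFrameRecord,
    StartCodonHit,
    TISWindow,
    exon_frame_table,
    intron_inframe,
    ir_check,
    kozak_score,
    scan_upstream,
    score_tis,
    tis_window,
)

from conftest import make_toy_reference


def ref_with_upstream(codons, pad=30):
    """Toy plus-strand gene: pad + upstream codons + peptide codons."""
    pep_nt = "GCCTTTGCACCTTTTCCTACTCAATTT"  # AFAPFPTQF
    seq = "G" * pad + "".join(codons) + pep_nt + "G" * pad
    start = pad + 3 * len(codons)
    ref = make_toy_reference(
        seq, [{"gene_id": "G", "exons": [(pad, len(seq) - pad)]}]
    )
    iv = GenomicInterval("chr1", start, start + len(pep_nt), "+")
    return ref, iv


class TestScanUpstream:
    def test_two_hits_nearest_first(self):
        # transcription order: CTG .. ACG .. peptide -> ACG reported first
        ref, iv = ref_with_upstream(["CTG", "GCA", "ACG", "GCA"])
        hits = scan_upstream(ref, iv)
        assert [(h.codon, h.upstream_offset_nt) for h in hits] == [
            ("ACG", 6), ("CTG", 12),
        ]

    def test_stop_immediately_upstream_terminates(self):
        ref, iv = ref_with_upstream(["ATG", "TAA"])
        assert scan_upstream(ref, iv) == []

    def test_stop_between_hits_hides_distal_codons(self):
        ref, iv = ref_with_upstream(["ATG", "TGA", "CTG", "GCA"])
        hits = scan_upstream(ref, iv)
        assert [h.codon for h in hits] == ["CTG"]

    def test_out_of_frame_start_codon_not_reported(self):
        # ATG exists at +1 offset inside the filler but never in frame
        ref, iv = ref_with_upstream(["GAT", "GGC", "GCA"])
        hits = scan_upstream(ref, iv)
        assert all(h.codon != "ATG" for h in hits)
        assert [h.codon for h in hits] == []

    def test_bound_limits_scan_to_gene_span(self):
        ref, iv = ref_with_upstream(["GCA", "GCA"])
        bound = ref.genes[0].span
        for h in scan_upstream(ref, iv, bound=bound):
            assert h.genomic_position >= bound.start

    def test_minus_strand_scan(self):
        pep_nt = "GCCTTTGCACCTTTTCCTACTCAATTT"
        sense = "G" * 30 + "CTG" + "GCA" + pep_nt + "G" * 30
        seq = reverse_complement(sense)
        n = len(seq)
        ref = make_toy_reference(
            seq, [{"gene_id": "G", "strand": "-", "exons": [(30, n - 30)]}]
        )
        # peptide local start 36 -> genomic 5' base at n-1-36
        iv = GenomicInterval("chr1", n - 36 - len(pep_nt), n - 36, "-")
        hits = scan_upstream(ref, iv)
        assert [(h.codon, h.upstream_offset_nt) for h in hits] == [("CTG", 6)]

    def test_hits_yield_stopfree_orf_containing_peptide(self, fixture42):
        """Translating from any reported hit reaches the peptide with no
        internal stop (by construction of the scan)."""
        ref = fixture42.reference
        spans = {g.gene_id: g.span for g in ref.genes}
        n_checked = 0
        for p in fixture42.planted:
            if p.upstream_start is None:
                continue
            for h in scan_upstream(ref, p.interval, bound=spans[p.gene_id]):
                if p.interval.strand == "+":
                    nt = ref.slice(
                        p.interval.chrom, h.genomic_position, p.interval.end
                    )
                else:
                    nt = reverse_complement(
                        ref.slice(
                            p.interval.chrom, p.interval.start,
                            h.genomic_position + 1,
                        )
                    )
                aa = translate(nt, 0)
                assert "*" not in aa
                assert aa.endswith(p.sequence)
                n_checked += 1
        assert n_checked > 0


class TestTISWindow:
    def test_interior_hit_window_geometry(self):
        seq = "ACGT" * 200
        ref = make_toy_reference(seq, [{"gene_id": "G", "exons": [(0, 800)]}])
        win = tis_window(ref, StartCodonHit(seq[400:403], 400, 9, "+", "chr1"))
        assert len(win.sequence) == 203
        assert win.sequence[100:103] == seq[400:403]

    def test_edge_padding(self):
        seq = "ATG" + "C" * 400
        ref = make_toy_reference(seq, [{"gene_id": "G", "exons": [(0, 400)]}])
        # 50 nt available upstream -> 50 leading N
        win = tis_window(ref, StartCodonHit(seq[50:53], 50, 9, "+", "chr1"))
        assert win.sequence[:50] == "N" * 50
        assert win.sequence[50] != "N"

    def test_minus_strand_window_matches_reextraction(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        ref = make_toy_reference(
            seq, [{"gene_id": "G", "strand": "-", "exons": [(0, 600)]}]
        )
        pos = 300
        codon = reverse_complement(seq[pos - 2 : pos + 1])
        win = tis_window(ref, StartCodonHit(codon, pos, 9, "-", "chr1"))
        assert win.center_codon == codon
        # independent oracle: revcomp the genomic slice around the codon
        expected = reverse_complement(seq[pos - 102 : pos + 101])
        assert win.sequence == expected

    def test_bad_window_length_rejected(self):
        with pytest.raises(ValueError):
            TISWindow(sequence="ATG", center_codon="ATG")


class TestScoreTIS:
    def test_constant_scorers_and_strict_boundary(self):
        win = TISWindow("N" * 100 + "ATG" + "N" * 100, "ATG")
        assert score_tis(win, lambda s: 1.0) == (1.0, True)
        assert score_tis(win, lambda s: 0.5) == (0.5, False)

    def test_scorer_out_of_range_rejected(self):
        win = TISWindow("N" * 100 + "ATG" + "N" * 100, "ATG")
        with pytest.raises(ValueError):
            score_tis(win, lambda s: 1.5)

    def test_kozak_ranks_strong_context_above_weak(self):
        strong = "N" * 94 + "GCCACC" + "ATG" + "G" + "N" * 99
        weak = "N" * 94 + "TTTTTT" + "ATG" + "T" + "N" * 99
        assert kozak_score(strong) > kozak_score(weak)
        assert 0.0 <= kozak_score(weak) <= 1.0


class TestExonFrameTable:
    def test_plus_strand_hand_trace(self):
        """Exons [100,110) and [200,210): exon 1 has a 1-base overhang, so
        the in-frame grid of exon 2 is 1 nt 5' of its start (base 199) —
        congruent to the first fully-contained codon at 202."""
        ref = make_toy_reference(
            "A" * 300,
            [{"gene_id": "G", "exons": [(100, 110), (200, 210)]}],
        )
        recs = exon_frame_table(ref)
        assert len(recs) == 1
        assert recs[0].inframe_coordinate == 100
        assert recs[0].downstream_intron == GenomicInterval("chr1", 110, 200, "+")
        # three-exon version exposes the propagated record for exon 2
        ref3 = make_toy_reference(
            "A" * 400,
            [{"gene_id": "G", "exons": [(100, 110), (200, 210), (300, 310)]}],
        )
        recs3 = exon_frame_table(ref3)
        assert [r.inframe_coordinate for r in recs3] == [100, 199]
        assert (202 - recs3[1].inframe_coordinate) % 3 == 0

    def test_literal_recursion_for_comparison(self):
        ref3 = make_toy_reference(
            "A" * 400,
            [{"gene_id": "G", "exons": [(100, 110), (200, 210), (300, 310)]}],
        )
        recs = exon_frame_table(ref3, literal=True)
        assert [r.inframe_coordinate for r in recs] == [100, 198]

    def test_zero_remainder_propagation(self):
        # exon length divisible by 3 -> next exon's grid starts at its start
        ref = make_toy_reference(
            "A" * 400,
            [{"gene_id": "G", "exons": [(100, 112), (200, 212), (300, 310)]}],
        )
        recs = exon_frame_table(ref)
        assert [r.inframe_coordinate for r in recs] == [100, 200]

    def test_minus_strand_mirror(self):
        ref = make_toy_reference(
            "A" * 400,
            [{"gene_id": "G", "strand": "-",
              "exons": [(100, 110), (200, 210), (300, 310)]}],
        )
        recs = exon_frame_table(ref)
        # transcription order: exon [300,310) first (5' base 309), then [200,210)
        assert [r.inframe_coordinate for r in recs] == [309, 210]
        assert recs[0].downstream_intron == GenomicInterval("chr1", 210, 300, "-")

    def test_single_exon_transcripts_emit_nothing(self):
        ref = make_toy_reference(
            "A" * 200, [{"gene_id": "G", "exons": [(10, 100)]}]
        )
        assert exon_frame_table(ref) == []

    def test_invariant_shift_within_two_bases(self, fixture42):
        for rec in exon_frame_table(fixture42.reference):
            if rec.strand == "+":
                assert rec.exon.start - rec.inframe_coordinate in (0, 1, 2)
            else:
                assert rec.inframe_coordinate - (rec.exon.end - 1) in (0, 1, 2)

    def test_agrees_with_splice_translate_oracle_random(self):
        """Random transcripts: the emitted grid must contain exactly the
        codon starts obtained by splicing, translating from the transcript
        start, and continuing into the retained intron."""
        rng = np.random.default_rng(11)
        for trial in range(100):
            n_exons = int(rng.integers(2, 5))
            exon_lens = [int(rng.integers(5, 40)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(10, 30)) for _ in range(n_exons - 1)]
            strand = "+" if trial % 2 == 0 else "-"
            length = sum(exon_lens) + sum(intron_lens)
            if strand == "+":
                exons, pos = [], 50
                for i, el in enumerate(exon_lens):
                    exons.append((pos, pos + el))
                    pos += el
                    if i < n_exons - 1:
                        pos += intron_lens[i]
            else:
                # transcription runs right-to-left: first exon is rightmost
                exons, pos = [], 50 + length
                for i, el in enumerate(exon_lens):
                    exons.append((pos - el, pos))
                    pos -= el
                    if i < n_exons - 1:
                        pos -= intron_lens[i]
                exons = sorted(exons)
            ref = make_toy_reference(
                "A" * (length + 100),
                [{"gene_id": "G", "strand": strand, "exons": exons}],
            )
            recs = exon_frame_table(ref)
            assert len(recs) == n_exons - 1
            span = ref.genes[0].span
            for idx, rec in enumerate(recs):
                # transcription-local coordinate of the grid representative
                if strand == "+":
                    local = rec.inframe_coordinate - span.start
                else:
                    local = span.end - 1 - rec.inframe_coordinate
                # oracle: a local position p in the retained intron is a
                # codon start iff (p - intron_local + consumed) % 3 == 0
                consumed = sum(exon_lens[: idx + 1])
                intron_local = consumed + sum(intron_lens[:idx])
                assert (local - intron_local + consumed) % 3 == 0


class TestIntronInframe:
    REC = ExonFrameRecord(
        transcript_id="T", chrom="chr1", strand="+",
        exon=GenomicInterval("chr1", 90, 100, "+"),
        inframe_coordinate=100,
        downstream_intron=GenomicInterval("chr1", 100, 200, "+"),
    )

    @pytest.mark.parametrize(
        "start,expected", [(130, True), (131, False), (100, True)]
    )
    def test_plus_strand_mod3_rule(self, start, expected):
        iv = GenomicInterval("chr1", start, start + 27, "+")
        assert intron_inframe(iv, self.REC) is expected

    def test_peptide_outside_intron_rejected(self):
        iv = GenomicInterval("chr1", 300, 327, "+")
        with pytest.raises(ValueError):
            intron_inframe(iv, self.REC)

    def test_fixture_ir_verdicts_match_planted_design(self, fixture42):
        intervals = {
            p.sequence: [p.interval]
            for p in fixture42.planted
            if p.ir_inframe is not None
        }
        verdicts = {}
        for r in ir_check(fixture42.reference, intervals):
            verdicts.setdefault(r.peptide, []).append(r.in_frame)
        for p in fixture42.planted:
            if p.ir_inframe is None:
                continue
            assert verdicts[p.sequence] == [p.ir_inframe], p.source

    def test_retained_intron_translation_oracle(self, fixture42):
        """Brute-force check: an in-frame verdict must agree with actually
        translating the retained-intron transcript and asking whether the
        peptide appears at a codon boundary."""
        ref = fixture42.reference
        planted = [p for p in fixture42.planted if p.ir_inframe is not None]
        n_checked = 0
        for p in planted[:12]:
            gene = ref.gene(p.gene_id)
            t = gene.transcripts[0]
            exons = t.exons_in_transcription_order()
            introns = t.introns
            if gene.strand == "-":
                introns = list(reversed(introns))
            for which, intron in enumerate(introns):
                if p.interval.overlap(intron) == 0:
                    continue
                # retained transcript: exons up to `which`, the intron, rest
                def seq_of(iv):
                    s = ref.slice(iv.chrom, iv.start, iv.end)
                    return reverse_complement(s) if gene.strand == "-" else s

                parts = [seq_of(e) for e in exons[: which + 1]]
                parts.append(seq_of(intron))
                retained = "".join(parts)
                aa = translate(retained, 0)
                present = p.sequence in aa
                assert present == p.ir_inframe, (p.sequence, p.source)
                n_checked += 1
        assert n_checked >= 10
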