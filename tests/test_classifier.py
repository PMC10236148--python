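"""Sequential peptide annotation: mismatch semantics, scan oracle, rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncmap.classify import (
    MismatchProfile,
    ProteomeScanner,
    classify,
    classify_all,
    export_second_round_db,
    min_proteome_distance,
    mismatch_profile,
    read_fasta_proteome,
    read_peptide_table,
)
from ncmap.threeft import ThreeFTIndex, TranslatedSegment


def brute_force_min(peptide, proteome):
    """Independent oracle: enumerate every window of every protein."""
    best = None
    hits = []
    for pid, seq in proteome.items():
        for off in range(len(seq) - len(peptide) + 1):
            window = seq[off : off + len(peptide)]
            hard = li = 0
            for a, b in zip(peptide, window):
                if a == b:
                    continue
                if {a, b} <= {"I", "L"}:
                    li += 1
                else:
                    hard += 1
            key = (hard + li, hard)
            if best is None or key < best:
                best, hits = key, [(pid, off)]
            elif key == best:
                hits.append((pid, off))
    if best is None:
        return MismatchProfile(len(peptide), 0), []
    # reconstruct the profile of the first argmin window
    pid, off = hits[0]
    window = proteome[pid][off : off + len(peptide)]
    prof = mismatch_profile(peptide, window)
    return prof, hits


class TestMismatchProfile:
    @pytest.mark.parametrize(
        "pep,win,hard,li",
        [
            ("KTAYLAKQ", "KTAYIAKQ", 0, 1),
            ("KTAWWWKQ", "KTAYIAKQ", 3, 0),
            ("AAAA", "AAAA", 0, 0),
            ("ILIL", "LILI", 0, 4),
        ],
    )
    def test_examples(self, pep, win, hard, li):
        assert mismatch_profile(pep, win) == MismatchProfile(hard, li)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_profile("AAA", "AAAA")


class TestMinProteomeDistance:
    def test_single_xle_interchange(self):
        prof, hits = min_proteome_distance("KTAYLAKQ", {"P1": "MKTAYIAKQR"})
        assert (prof.hard, prof.li) == (0, 1)
        assert hits == [("P1", 1)]

    def test_three_hard_mismatches(self):
        prof, _ = min_proteome_distance("KTAWWWKQ", {"P1": "MKTAYIAKQR"})
        assert (prof.hard, prof.li) == (3, 0)

    def test_peptide_equal_to_full_protein(self):
        prof, hits = min_proteome_distance("MKTAYIAKQR", {"P1": "MKTAYIAKQR"})
        assert (prof.hard, prof.li) == (0, 0)
        assert hits == [("P1", 0)]

    def test_peptide_longer_than_every_protein(self):
        prof, hits = min_proteome_distance("A" * 12, {"P1": "AAAA", "P2": "CCC"})
        assert (prof.hard, prof.li) == (12, 0)
        assert hits == []

    def test_all_argmin_windows_reported(self):
        prof, hits = min_proteome_distance("AAAA", {"P1": "AAAAA"})
        assert (prof.hard, prof.li) == (0, 0)
        assert hits == [("P1", 0), ("P1", 1)]

    @settings(max_examples=60, deadline=None)
    @given(
        pep=st.text(alphabet="ACDILKW", min_size=4, max_size=8),
        seqs=st.lists(
            st.text(alphabet="ACDILKW", min_size=3, max_size=30),
            min_size=1, max_size=4,
        ),
    )
    def test_agrees_with_brute_force_oracle(self, pep, seqs):
        proteome = {f"P{i}": s for i, s in enumerate(seqs)}
        prof, hits = min_proteome_distance(pep, proteome)
        oprof, ohits = brute_force_min(pep, proteome)
        assert (prof.hard, prof.li) == (oprof.hard, oprof.li)
        assert sorted(hits) == sorted(ohits)

    def test_oracle_equivalence_on_fixture_proteome(self, fixture42):
        """Exhaustive-scan equivalence on a realistic proteome (~tens of
        kaa) for a sample of planted peptides."""
        proteome = fixture42.proteome
        rng = np.random.default_rng(0)
        sample = rng.choice(len(fixture42.planted), size=15, replace=False)
        scanner = ProteomeScanner(proteome)
        for i in sample:
            pep = fixture42.planted[int(i)].sequence
            prof, hits = scanner.min_distance(pep)
            oprof, ohits = brute_force_min(pep, proteome)
            assert (prof.hard, prof.li) == (oprof.hard, oprof.li)
            assert sorted(hits) == sorted(ohits)


def _index_with(seq):
    return ThreeFTIndex(
        [TranslatedSegment("G", "chr1", "+", 0, seq, 1000, 0)]
    )


class TestClassifyRules:
    def test_planted_intronic_peptide_is_noncanonical(self):
        idx = _index_with("WWAFAPFPTQFWW")
        res = classify("AFAPFPTQF", ProteomeScanner({"P1": "MKTAYIAKQRDDD"}), idx)
        assert res.category == "noncanonical"
        assert res.best_proteome_profile.total >= 3
        assert res.threeft_hits and res.threeft_hits[0][1] == 2

    def test_canonical_precedence_over_3ft_hit(self):
        idx = _index_with("WWKTAYLAKQWW")
        res = classify("KTAYLAKQ", ProteomeScanner({"P1": "MKTAYIAKQR"}), idx)
        assert res.category == "canonical"

    def test_buffer_zone_two_mismatches_is_unmapped(self):
        # peptide 2 hard mismatches from the proteome but present in 3FT
        idx = _index_with("WWKTAWIAKWWW")
        res = classify("KTAWIAKW", ProteomeScanner({"P1": "MKTAYIAKQR"}), idx)
        assert res.best_proteome_profile.total == 2
        assert res.category == "unmapped"

    def test_categories_partition_fixture_peptides(self, fixture42):
        from ncmap.threeft import build_3ft

        idx = ThreeFTIndex(build_3ft(fixture42.reference))
        results = classify_all(
            fixture42.peptides(), fixture42.proteome, idx
        )
        assert len(results) == len(fixture42.planted)
        for r in results:
            assert r.category in ("canonical", "noncanonical", "unmapped")

    def test_raising_min_mismatch_never_increases_noncanonical(self, fixture42):
        from ncmap.threeft import build_3ft

        idx = ThreeFTIndex(build_3ft(fixture42.reference))
        peps = fixture42.peptides()
        n3 = sum(
            r.category == "noncanonical"
            for r in classify_all(peps, fixture42.proteome, idx, min_mismatch=3)
        )
        n4 = sum(
            r.category == "noncanonical"
            for r in classify_all(peps, fixture42.proteome, idx, min_mismatch=4)
        )
        assert n4 <= n3


class TestSecondRoundDb:
    def test_order_and_collapse(self, tmp_path):
        path = tmp_path / "db.fa"
        export_second_round_db(
            ["CCCCCCC", "AAAAAAA", "CCCCCCC"],
            {"P1": "MMM", "P2": "WWW"},
            path,
        )
        lines = path.read_text().splitlines()
        assert lines[0] == ">P1" and lines[2] == ">P2"
        assert lines[5] == "AAAAAAA" and lines[7] == "CCCCCCC"
        assert len(lines) == 8  # duplicates collapsed

    def test_empty_noncanonical_set_keeps_proteome_only(self, tmp_path):
        path = tmp_path / "db.fa"
        export_second_round_db([], {"P1": "MMM"}, path)
        assert path.read_text() == ">P1\nMMM\n"


class TestIO:
    def test_read_plain_and_tsv_peptides(self, tmp_path):
        plain = tmp_path / "p.txt"
        plain.write_text("aaaagggg\nCCCCWWWW\n")
        recs = read_peptide_table(plain)
        assert [r.sequence for r in recs] == ["AAAAGGGG", "CCCCWWWW"]
        tsv = tmp_path / "p.tsv"
        tsv.write_text("sequence\tsample_id\tscore\nAAAAGGGG\tS1\t0.5\n")
        recs = read_peptide_table(tsv)
        assert recs[0].sample_id == "S1" and recs[0].score == 0.5

    def test_proteome_reader_drops_decoys_and_contaminants(self, tmp_path):
        fa = tmp_path / "p.fa"
        fa.write_text(">P1\nMAAA\n>rev_P1\nAAAM\n>CON_trypsin\nKKKK\n")
        assert read_fasta_proteome(fa) == {"P1": "MAAA"}
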