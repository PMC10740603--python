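import random

import pytest
from hypothesis import given, settings, strategies as st

import oracles
from hostblock import (
    Primer,
    PrimerPair,
    RefSeq,
    TaxonomyPath,
    count_mismatches,
    expand_degenerate,
    extract_amplicons,
    find_primer_sites,
    iupac_match,
    reverse_complement,
)
from hostblock.refdb import RefDB

FWD = "CCAGCASCYGCGGTAATTCC"
REV = "ACTTTCGTTCTTGATYRA"
FWD_EXP = "CCAGCACCCGCGGTAATTCC"
REV_EXP = "ACTTTCGTTCTTGATCAA"


def primer(seq, role="forward"):
    return Primer("p", seq, role=role)


class TestIupacMatch:
    @pytest.mark.parametrize(
        "p,t,expected",
        [
            ("Y", "T", True),
            ("T", "Y", False),
            ("N", "G", True),
            ("G", "N", False),
            ("N", "N", True),
            ("R", "A", True),
            ("R", "C", False),
            ("S", "C", True),
        ],
    )
    def test_subset_rule(self, p, t, expected):
        assert iupac_match(p, t) is expected

    def test_non_iupac_symbol_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("X", "A")

    def test_agrees_with_oracle_on_all_pairs(self):
        for p in oracles.IUPAC:
            for t in oracles.IUPAC:
                assert iupac_match(p, t) == oracles.symbol_covers(p, t)


class TestCountMismatches:
    def test_identity(self):
        assert count_mismatches(primer("ACGTACGT"), "ACGTACGT") == (0, [])

    def test_reverse_decamer_vs_blocker_prefix(self):
        # the single snail-specific position within the primer overlap
        assert count_mismatches("TCTTGATYRA", "TCTTGACTAA") == (1, [6])

    def test_all_n_primer_matches_anything(self):
        assert count_mismatches("NNNN", "ACGT") == (0, [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_mismatches(primer("ACGTACGT"), "ACGT")


class TestFindPrimerSites:
    def test_planted_forward_site(self):
        ref = RefSeq("r", "AAAA" + FWD_EXP + "AAAA", TaxonomyPath(()))
        (site,) = find_primer_sites(ref, primer(FWD), max_mismatch=1)
        assert (site.start, site.strand, site.mismatches) == (4, "+", 0)

    def test_strand_symmetry_on_revcomp(self):
        seq = "AAAA" + FWD_EXP + "AAAA"
        ref_rc = RefSeq("r", reverse_complement(seq), TaxonomyPath(()))
        (site,) = find_primer_sites(ref_rc, primer(FWD), max_mismatch=1)
        assert site.strand == "-"
        assert site.mismatches == 0
        assert (site.start, site.end) == (4, 4 + len(FWD))

    def test_threshold_excludes_single_mismatch_site(self):
        mutated = FWD_EXP[:10] + "T" + FWD_EXP[11:]  # G->T inside the site
        assert mutated != FWD_EXP
        ref = RefSeq("r", "AAAA" + mutated + "AAAA", TaxonomyPath(()))
        assert find_primer_sites(ref, primer(FWD), max_mismatch=0) == []
        assert len(find_primer_sites(ref, primer(FWD), max_mismatch=1)) == 1

    def test_reference_shorter_than_primer(self):
        assert find_primer_sites(RefSeq("r", "ACGT"), primer("ACGTACGT")) == []

    @settings(max_examples=40, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=12, max_size=80),
        pseq=st.text(alphabet="ACGTRYSWKMN", min_size=8, max_size=14),
        k=st.integers(min_value=0, max_value=2),
    )
    def test_equivalence_with_naive_scan(self, seq, pseq, k):
        got = {
            (s.start, s.strand, s.mismatches)
            for s in find_primer_sites(RefSeq("r", seq), primer(pseq), k)
        }
        assert got == set(oracles.naive_sites(seq, pseq, k))

    @settings(max_examples=25, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=20, max_size=60),
        pseq=st.text(alphabet="ACGT", min_size=8, max_size=10),
    )
    def test_monotone_in_mismatch_allowance(self, seq, pseq):
        prev: set = set()
        for k in (0, 1, 2):
            cur = {
                (s.start, s.strand)
                for s in find_primer_sites(RefSeq("r", seq), primer(pseq), k)
            }
            assert prev <= cur
            prev = cur


def _pair():
    return PrimerPair(primer(FWD), primer(REV, role="reverse"), "18SV4")


class TestExtractAmplicons:
    def test_planted_amplicon_by_construction(self):
        insert = "ACGTACGTAC" * 6
        ref = RefSeq(
            "r",
            "GG" + FWD_EXP + insert + reverse_complement(REV_EXP) + "GG",
            TaxonomyPath(("Eukaryota",)),
        )
        (amp,) = extract_amplicons(
            RefDB([ref]), _pair(), max_mismatch=1, min_len=50, max_len=200
        )
        assert len(amp) == 20 + 60 + 18 == 98
        assert (amp.fwd_mismatches, amp.rev_mismatches) == (0, 0)
        assert amp.sequence == ref.sequence[amp.start : amp.end]
        assert amp.sequence.startswith(FWD_EXP)
        assert amp.sequence.endswith(reverse_complement(REV_EXP))

    def test_reverse_oriented_reference(self):
        insert = "ACGTACGTAC" * 6
        sense = "GG" + FWD_EXP + insert + reverse_complement(REV_EXP) + "GG"
        ref = RefSeq("r", reverse_complement(sense), TaxonomyPath(()))
        (amp,) = extract_amplicons(
            RefDB([ref]), _pair(), max_mismatch=1, min_len=50, max_len=200
        )
        assert amp.strand == "-"
        # amplicon is still written forward->reverse
        assert amp.sequence.startswith(FWD_EXP)
        assert len(amp) == 98

    def test_forward_site_alone_yields_nothing(self):
        ref = RefSeq("r", "GG" + FWD_EXP + "ACGT" * 30, TaxonomyPath(()))
        assert extract_amplicons(RefDB([ref]), _pair(), 1, 50, 300) == []

    def test_length_window_picks_in_range_reverse_site(self):
        insert = "ACGTACGTAC" * 6
        rc_rev = reverse_complement(REV_EXP)
        # two reverse sites: first gives length 98, second 216 (> max_len)
        seq = "GG" + FWD_EXP + insert + rc_rev + "A" * 100 + rc_rev + "GG"
        (amp,) = extract_amplicons(
            RefDB([RefSeq("r", seq, TaxonomyPath(()))]), _pair(), 1, 50, 200
        )
        assert len(amp) == 98

    def test_every_amplicon_within_length_bounds(self, small_sim, published):
        pair, _ = published
        _, db, _ = small_sim
        for amp in extract_amplicons(db, pair, 1, 200, 600):
            assert 200 <= len(amp) <= 600


class TestExpandDegenerate:
    @pytest.mark.parametrize(
        "seq,n", [(REV, 4), (FWD, 4), ("ACGTACGT", 1), ("NN" + "ACGTAC", 16)]
    )
    def test_expansion_counts(self, seq, n):
        exps = expand_degenerate(seq)
        assert len(exps) == len(set(exps)) == n
        assert exps == sorted(exps)

    def test_identity_expansion(self):
        assert expand_degenerate("ACGTACGT") == ["ACGTACGT"]

    def test_cap_exceeded(self):
        with pytest.raises(ValueError, match="cap"):
            expand_degenerate("N" * 8, cap=64)
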