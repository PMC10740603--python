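import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from hostblock import (
    DesignConstraints,
    Primer,
    TmModel,
    annotate_synthesis,
    build_terminal_block,
    compute_primer_overlap,
    enumerate_candidates,
    expand_degenerate,
    host_consensus,
    melting_temperature,
    reverse_complement,
    validate_candidate,
)
from hostblock.entropy_profile import HOST, NON_TARGET

WALLACE = TmModel(method="wallace")


class TestMeltingTemperature:
    def test_wallace_homopolymer(self):
        assert melting_temperature("AAAAAAAA", WALLACE) == 16.0

    def test_wallace_published_blocker(self):
        # 20 A/T + 8 G/C
        assert melting_temperature(
            "TCTTGACTAATGAAAACATTCTTGACAA", WALLACE
        ) == 72.0

    def test_wallace_degenerate_is_mean_over_expansions(self):
        seq = "ACTTTCGTTCTTGATYRA"
        per_exp = [oracles.wallace_tm(e) for e in expand_degenerate(seq)]
        assert sorted(per_exp) == [46, 48, 48, 50]
        assert melting_temperature(seq, WALLACE) == pytest.approx(
            sum(per_exp) / 4
        ) == 48.0

    def test_nearest_neighbor_finite_and_reasonable(self):
        tm = melting_temperature("TCTTGACTAATGAAAACATTCTTGACAA", TmModel())
        assert np.isfinite(tm) and 30 < tm < 80

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGT", WALLACE)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    def test_wallace_linear_in_base_counts(self, seq):
        assert melting_temperature(seq, WALLACE) == oracles.wallace_tm(seq)


class TestHostConsensus:
    def _block(self, rows):
        return build_terminal_block(rows, len(rows[0]), [HOST] * len(rows))

    def test_majority_base_and_conservation(self):
        rows = ["A"] * 9 + ["G"]
        cons = host_consensus(self._block(rows))
        assert cons.sequence == "A"
        assert cons.conservation[0] == pytest.approx(0.9)

    def test_tie_breaks_lexicographic_and_flagged(self):
        cons = host_consensus(self._block(["A", "C"]))
        assert cons.sequence == "A"
        assert cons.conservation[0] == pytest.approx(0.5)
        assert cons.ties == (True,)

    def test_identical_rows_fully_conserved(self):
        cons = host_consensus(self._block(["ACGT", "ACGT", "ACGT"]))
        assert cons.sequence == "ACGT"
        assert np.allclose(cons.conservation, 1.0)

    def test_all_gap_column(self):
        block = build_terminal_block(["ACG"], 5, [HOST])  # two gap columns
        cons = host_consensus(block)
        assert cons.sequence[:2] == "--"
        assert cons.conservation[0] == 0.0


class TestPrimerOverlap:
    def test_published_pair_overlap_is_ten(self):
        assert compute_primer_overlap(
            "TCTTGACTAATGAAAACATTCTTGACAA", "ACTTTCGTTCTTGATYRA", 1
        ) == 10

    def test_identical_sequences_full_length(self):
        assert compute_primer_overlap("ACGTACGTAA", "ACGTACGTAA", 0) == 10

    def test_unrelated_sequences_zero(self):
        assert compute_primer_overlap("G" * 20, "ACTTTCGTTCTTGATYRA", 0) == 0

    def test_orientation_is_asymmetric(self):
        blocker = "TCTTGACTAATGAAAACATTCTTGACAA"
        rev = "ACTTTCGTTCTTGATYRA"
        assert compute_primer_overlap(blocker, rev, 1) != compute_primer_overlap(
            rev, blocker, 1
        )


def _planted_design(n_host=12, n_nt=12, seed=0):
    """A block with a perfectly conserved host terminal region and maximally
    divergent non-targets, sharing only the reverse-primer site."""
    import random

    rng = random.Random(seed)
    rev_exp = "ACTTTCGTTCTTGATCAA"
    rev_site = reverse_complement(rev_exp)  # on the amplicon as written
    host_flank = "".join(rng.choice("ACGT") for _ in range(60))
    host_amp = "G" * 40 + host_flank + rev_site
    nt_amps = []
    for _ in range(n_nt):
        flank = "".join(rng.choice("ACGT") for _ in range(60))
        nt_amps.append("C" * 40 + flank + rev_site)
    from hostblock import PrimerPair

    pair = PrimerPair(
        Primer("f", "CCAGCASCYGCGGTAATTCC"),
        Primer("r", "ACTTTCGTTCTTGATYRA", role="reverse"),
    )
    host_rows = [host_amp] * n_host
    block = build_terminal_block(
        host_rows + nt_amps,
        40,
        [HOST] * n_host + [NON_TARGET] * n_nt,
    )
    return block, nt_amps, pair, host_amp


class TestEnumerateCandidates:
    def test_planted_window_is_recovered(self):
        block, nt_amps, pair, host_amp = _planted_design()
        result = enumerate_candidates(block, nt_amps, pair)
        top = result.top
        assert top is not None
        # the top candidate is the reverse complement of the host terminal
        # consensus window it was cut from
        window = host_amp[-40:][top.window_start : top.window_end]
        assert top.sequence == reverse_complement(window)
        assert top.host_blocked_fraction == 1.0
        assert top.off_target_blocked_fraction == 0.0
        assert top.mean_conservation == 1.0

    def test_every_candidate_passes_independent_validation(self):
        block, nt_amps, pair, _ = _planted_design()
        constraints = DesignConstraints()
        result = enumerate_candidates(block, nt_amps, pair, constraints)
        assert len(result) > 0
        for cand in result:
            assert validate_candidate(cand, constraints, pair) == []

    def test_impossible_tm_window_gives_diagnostics(self):
        block, nt_amps, pair, _ = _planted_design()
        constraints = DesignConstraints(tm_tolerance=0.0, tm_reference="reverse")
        result = enumerate_candidates(block, nt_amps, pair, constraints)
        assert len(result) == 0
        assert len(result.diagnostics) > 0
        assert (result.diagnostics["reason"] == "tm_outside_tolerance").any()

    def test_identical_hosts_give_full_conservation(self):
        block, nt_amps, pair, _ = _planted_design()
        result = enumerate_candidates(block, nt_amps, pair)
        assert all(c.mean_conservation == 1.0 for c in result)

    def test_window_shorter_than_reverse_primer_rejected(self):
        block, nt_amps, pair, _ = _planted_design()
        short = build_terminal_block(
            [r for r in block.rows], 10, [s for _, s in block.labels]
        )
        with pytest.raises(ValueError):
            enumerate_candidates(short, nt_amps, pair)


class TestSynthesisNote:
    def test_spacer_and_protocol_defaults(self):
        block, nt_amps, pair, _ = _planted_design()
        top = enumerate_candidates(block, nt_amps, pair).top
        note = annotate_synthesis(top)
        assert note["spacer_C3"] is True
        assert note["order_as"].endswith("/3SpC3/")
        assert note["blocking_to_target_ratio"] == "1.5:1"
        assert note["blocking_primer_concentration"] == "1.2 µM"
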