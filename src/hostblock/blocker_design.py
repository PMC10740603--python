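"""Constrained enumeration and ranking of candidate blocking primers.

A blocking primer is a non-extendable oligo (3' C3 spacer) that competes
with the reverse amplification primer on the host template: it anneals to
the amplicon's reverse-complement strand, its 5' prefix overlapping the
reverse primer's 3' suffix, and continues into the host-specific terminal
region. Candidates are therefore reverse complements of host-consensus
windows over the 3' terminal block, enumerated over a length range
(default 24-32 nt, targeting ~28) and an overlap range with the reverse
primer binding site (default 8-12 bp, targeting ~10), then filtered on host
conservation and on melting temperature similarity to the amplification
primer set, and ranked by predicted host blocking minus a weighted
off-target penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .alphabet import CONCRETE, GAP, reverse_complement
from .entropy_profile import TerminalBlock, HOST
from .insilico_pcr import (
    AmpliconRecord,
    Primer,
    PrimerPair,
    count_mismatches,
    expand_degenerate,
)
from . import specificity as _spec


@dataclass(frozen=True)
class TmModel:
    """Melting-temperature model.

    ``wallace``: Tm = 2(A+T) + 4(G+C) — the rule-of-thumb linear form, kept
    for transparency and as a closed-form test oracle. ``nearest_neighbor``:
    SantaLucia-1998 unified parameters at the given monovalent salt and
    primer concentration. Degenerate oligos are averaged over their concrete
    expansions (full expansion capped).
    """

    method: str = "nearest_neighbor"  # nearest_neighbor | wallace
    Na_mM: float = 50.0
    primer_uM: float = 0.25
    expansion_cap: int = 64

    def __post_init__(self) -> None:
        if self.method not in ("nearest_neighbor", "wallace"):
            raise ValueError(f"unknown Tm method {self.method!r}")
        if self.Na_mM <= 0 or self.primer_uM <= 0 or self.expansion_cap <= 0:
            raise ValueError("Tm model parameters must be positive")


def _tm_concrete(seq: str, model: TmModel) -> float:
    if model.method == "wallace":
        at = sum(seq.count(b) for b in "AT")
        gc = sum(seq.count(b) for b in "GC")
        return 2.0 * at + 4.0 * gc
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=model.Na_mM,
            dnac1=model.primer_uM * 1000.0,  # nM
            dnac2=0,
            saltcorr=5,
        )
    )


def melting_temperature(sequence: str | Primer, model: TmModel | None = None) -> float:
    """Tm in °C; degenerate oligos are averaged over their expansions."""
    model = model or TmModel()
    seq = sequence.sequence if isinstance(sequence, Primer) else sequence.upper()
    if len(seq) < 8:
        raise ValueError("Tm estimation needs length >= 8")
    expansions = expand_degenerate(seq, cap=model.expansion_cap)
    return float(np.mean([_tm_concrete(e, model) for e in expansions]))


@dataclass(frozen=True)
class DesignConstraints:
    """Geometric, conservation and thermodynamic constraints on candidates."""

    length_range: tuple[int, int] = (24, 32)
    overlap_range: tuple[int, int] = (8, 12)
    tm_tolerance: float = 3.0  # °C
    #: pair_range: Tm must fall within [min(Tm_f, Tm_r) − tol, max + tol],
    #: so the blocker stays annealed wherever the amplification primers do;
    #: pair_mean / reverse / forward: |Tm − reference| ≤ tol
    tm_reference: str = "pair_range"
    min_conservation: float = 0.90
    k_block: int = 0
    off_target_ceiling: float = 0.01
    score_lambda: float = 10.0
    overlap_max_mismatch: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        olo, ohi = self.overlap_range
        if lo > hi or olo > ohi:
            raise ValueError("empty length or overlap range")
        if lo < ohi + 1:
            raise ValueError("minimum length must exceed maximum overlap")
        if self.tm_reference not in ("pair_range", "pair_mean", "reverse", "forward"):
            raise ValueError(f"unknown tm_reference {self.tm_reference!r}")


@dataclass(frozen=True)
class BlockerCandidate:
    """A candidate blocking oligo with its placement and scores.

    ``sequence`` is the oligo 5'→3' (the reverse complement of the
    host-consensus window it was cut from); ``window_start``/``window_end``
    are 0-based half-open columns of that window in the terminal block.
    """

    sequence: str
    length: int
    overlap_with_reverse_primer: int
    tm: float
    host_blocked_fraction: float
    off_target_blocked_fraction: float
    mean_conservation: float
    score: float
    window_start: int
    window_end: int
    consensus_ties_in_window: int = 0


@dataclass
class DesignResult:
    """Ranked candidates plus a near-miss diagnostics table."""

    candidates: list[BlockerCandidate]
    diagnostics: pd.DataFrame
    reference_tm: float = float("nan")

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def top(self) -> BlockerCandidate | None:
        return self.candidates[0] if self.candidates else None


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    conservation: np.ndarray
    ties: tuple[bool, ...]


def host_consensus(block: TerminalBlock) -> ConsensusResult:
    """Per-column majority concrete base over the host rows of a block.

    Ties go to the lexicographically smallest tied base and are flagged.
    Conservation is the consensus base's frequency among non-gap symbols;
    an all-gap column yields a gap consensus with conservation 0.
    """
    rows = block.rows_for(HOST) or block.rows
    if not rows:
        raise ValueError("no host rows available for consensus")
    W = block.window_len
    consensus, conservation, ties = [], [], []
    for j in range(W):
        col = [r[j] for r in rows]
        nongap = sum(1 for s in col if s != GAP)
        counts = {b: col.count(b) for b in CONCRETE}
        best = max(counts.values())
        if nongap == 0 or best == 0:
            consensus.append(GAP)
            conservation.append(0.0)
            ties.append(False)
            continue
        tied = [b for b in CONCRETE if counts[b] == best]
        consensus.append(tied[0])
        conservation.append(best / nongap)
        ties.append(len(tied) > 1)
    return ConsensusResult(
        sequence="".join(consensus),
        conservation=np.array(conservation),
        ties=tuple(ties),
    )


def compute_primer_overlap(
    blocker: Primer | str,
    reverse_primer: Primer | str,
    max_mismatch: int = 1,
) -> int:
    """Maximal n with the reverse primer's 3' n-suffix matching the blocker's
    5' n-prefix under the IUPAC subset rule with ≤ ``max_mismatch``
    mismatches; 0 if no overlap qualifies.

    The orientation matters: the reverse primer side supplies the degenerate
    "primer" symbols, the blocker side the target symbols.
    """
    bseq = blocker.sequence if isinstance(blocker, Primer) else blocker.upper()
    rseq = (
        reverse_primer.sequence
        if isinstance(reverse_primer, Primer)
        else reverse_primer.upper()
    )
    best = 0
    for n in range(1, min(len(bseq), len(rseq)) + 1):
        mm, _ = count_mismatches(rseq[-n:], bseq[:n])
        if mm <= max_mismatch:
            best = n
    return best


def enumerate_candidates(
    host_block: TerminalBlock,
    non_target_amplicons: Sequence[AmpliconRecord],
    pair: PrimerPair,
    constraints: DesignConstraints | None = None,
    tm_model: TmModel | None = None,
) -> DesignResult:
    """Enumerate, filter, score and rank blocking-oligo candidates.

    For every (length L, overlap o) in range, the candidate footprint ends
    o columns into the reverse-primer binding site (which occupies the last
    ``len(reverse)`` columns of the terminal block) and extends L columns
    upstream; the oligo is the reverse complement of the host-consensus
    window there. Filters: no gap in the window, mean host conservation ≥ c
    over the non-primer-site columns, Tm inside the acceptance window set by
    ``tm_reference``/``tm_tolerance`` (default: the amplification pair's Tm
    range padded by the tolerance), off-target blocked fraction ≤ ceiling. Ranking: score = host_blocked − λ·
    off_target_blocked, ties by |ΔTm| then larger overlap then sequence.
    Rejected near-misses are returned as a diagnostics table.
    """
    constraints = constraints or DesignConstraints()
    tm_model = tm_model or TmModel()
    W = host_block.window_len
    rlen = len(pair.reverse)
    if W <= rlen:
        raise ValueError(
            f"terminal window ({W}) must exceed the reverse primer length ({rlen})"
        )
    cons = host_consensus(host_block)
    host_rows = [r.lstrip(GAP) for r in host_block.rows_for(HOST) or host_block.rows]

    tm_rev = melting_temperature(pair.reverse, tm_model)
    tm_fwd = melting_temperature(pair.forward, tm_model)
    tm_mid = 0.5 * (tm_fwd + tm_rev)
    tol = constraints.tm_tolerance
    if constraints.tm_reference == "reverse":
        tm_lo, tm_hi, tm_ref = tm_rev - tol, tm_rev + tol, tm_rev
    elif constraints.tm_reference == "forward":
        tm_lo, tm_hi, tm_ref = tm_fwd - tol, tm_fwd + tol, tm_fwd
    elif constraints.tm_reference == "pair_mean":
        tm_lo, tm_hi, tm_ref = tm_mid - tol, tm_mid + tol, tm_mid
    else:  # pair_range
        tm_lo = min(tm_fwd, tm_rev) - tol
        tm_hi = max(tm_fwd, tm_rev) + tol
        tm_ref = tm_mid

    primer_site_start = W - rlen
    lo_L, hi_L = constraints.length_range
    lo_o, hi_o = constraints.overlap_range
    candidates: list[BlockerCandidate] = []
    misses: list[dict] = []
    for o in range(lo_o, hi_o + 1):
        end = primer_site_start + o
        if end > W:
            continue
        for L in range(lo_L, hi_L + 1):
            start = end - L
            entry = {"length": L, "overlap": o, "window_start": start}
            if start < 0:
                misses.append({**entry, "reason": "window_outside_block"})
                continue
            window = cons.sequence[start:end]
            if GAP in window:
                misses.append({**entry, "reason": "gap_in_consensus_window"})
                continue
            nonprimer = cons.conservation[start:primer_site_start]
            mean_cons = float(nonprimer.mean()) if nonprimer.size else 1.0
            oligo = reverse_complement(window)
            tm = melting_temperature(oligo, tm_model)
            entry.update(sequence=oligo, tm=round(tm, 2), mean_conservation=round(mean_cons, 4))
            if mean_cons < constraints.min_conservation:
                misses.append({**entry, "reason": "conservation_below_threshold"})
                continue
            if not (tm_lo <= tm <= tm_hi):
                misses.append({**entry, "reason": "tm_outside_tolerance"})
                continue
            blocker = Primer(
                name=f"cand_L{L}_o{o}",
                sequence=oligo,
                role="blocking",
                modification_3prime="spacer_C3",
            )
            host_blocked = _fraction_blocked(host_rows, blocker, constraints.k_block)
            nt_seqs = [
                a.sequence if isinstance(a, AmpliconRecord) else str(a)
                for a in non_target_amplicons
            ]
            off_blocked = _fraction_blocked(nt_seqs, blocker, constraints.k_block)
            if off_blocked > constraints.off_target_ceiling:
                misses.append({**entry, "reason": "off_target_above_ceiling",
                               "off_target_blocked": round(off_blocked, 4)})
                continue
            score = host_blocked - constraints.score_lambda * off_blocked
            n_ties = sum(cons.ties[start:end])
            candidates.append(
                BlockerCandidate(
                    sequence=oligo,
                    length=L,
                    overlap_with_reverse_primer=o,
                    tm=tm,
                    host_blocked_fraction=host_blocked,
                    off_target_blocked_fraction=off_blocked,
                    mean_conservation=mean_cons,
                    score=score,
                    window_start=start,
                    window_end=end,
                    consensus_ties_in_window=n_ties,
                )
            )
    candidates.sort(
        key=lambda c: (
            -c.score,
            abs(c.tm - tm_ref),
            -c.overlap_with_reverse_primer,
            c.sequence,
        )
    )
    diag = pd.DataFrame(misses)
    return DesignResult(candidates=candidates, diagnostics=diag, reference_tm=tm_ref)


def _fraction_blocked(seqs: Sequence[str], blocker: Primer, k_block: int) -> float:
    if not seqs:
        return 0.0
    n = sum(1 for s in seqs if _spec.is_blocked(s, blocker, k_block))
    return n / len(seqs)


def validate_candidate(
    candidate: BlockerCandidate,
    constraints: DesignConstraints,
    pair: PrimerPair,
    tm_model: TmModel | None = None,
) -> list[str]:
    """Independent re-check of every constraint; returns violation messages."""
    tm_model = tm_model or TmModel()
    problems = []
    lo_L, hi_L = constraints.length_range
    if not (lo_L <= candidate.length <= hi_L):
        problems.append(f"length {candidate.length} outside {constraints.length_range}")
    if len(candidate.sequence) != candidate.length:
        problems.append("sequence length disagrees with length field")
    lo_o, hi_o = constraints.overlap_range
    if not (lo_o <= candidate.overlap_with_reverse_primer <= hi_o):
        problems.append(
            f"overlap {candidate.overlap_with_reverse_primer} outside "
            f"{constraints.overlap_range}"
        )
    measured = compute_primer_overlap(
        candidate.sequence, pair.reverse, constraints.overlap_max_mismatch
    )
    if measured < candidate.overlap_with_reverse_primer:
        problems.append(
            f"measured suffix-prefix overlap {measured} < declared "
            f"{candidate.overlap_with_reverse_primer}"
        )
    for frac in (
        candidate.host_blocked_fraction,
        candidate.off_target_blocked_fraction,
        candidate.mean_conservation,
    ):
        if not (0.0 <= frac <= 1.0):
            problems.append(f"fraction {frac} outside [0, 1]")
    if abs(melting_temperature(candidate.sequence, tm_model) - candidate.tm) > 1e-9:
        problems.append("Tm field disagrees with recomputation")
    return problems


#: wet-lab defaults carried as inert protocol metadata
PROTOCOL_DEFAULTS = {
    "blocking_to_target_ratio": "1.5:1",
    "blocking_primer_concentration": "1.2 µM",
}


def annotate_synthesis(candidate: BlockerCandidate) -> dict:
    """Ordering/protocol note: 3' C3 spacer plus standard blocking defaults."""
    return {
        "sequence": candidate.sequence,
        "spacer_C3": True,
        "order_as": candidate.sequence + "/3SpC3/",
        **PROTOCOL_DEFAULTS,
    }


def candidates_to_tsv(result: DesignResult) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "sequence": c.sequence,
            "length": c.length,
            "overlap": c.overlap_with_reverse_primer,
            "tm": round(c.tm, 2),
            "host_blocked": round(c.host_blocked_fraction, 4),
            "off_target_blocked": round(c.off_target_blocked_fraction, 4),
            "mean_conservation": round(c.mean_conservation, 4),
            "score": round(c.score, 4),
        }
        for i, c in enumerate(result.candidates)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "sequence",
            "length",
            "overlap",
            "tm",
            "host_blocked",
            "off_target_blocked",
            "mean_conservation",
            "score",
        ],
    )


def write_top_candidate_fasta(result: DesignResult, path: str | Path) -> None:
    top = result.top
    if top is None:
        raise ValueError("no candidate to write")
    with open(path, "w") as fh:
        fh.write(
            f">blocking_primer length={top.length} overlap="
            f"{top.overlap_with_reverse_primer} Tm={top.tm:.1f}C /3SpC3/\n"
        )
        fh.write(top.sequence + "\n")
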