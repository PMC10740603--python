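"""Mismatch-tolerant, IUPAC-aware in-silico PCR.

Finds degenerate-primer binding sites on both strands of reference sequences
and extracts one amplicon per reference (best forward site, then best
compatible reverse site within the length window). This is the filter that
builds a "primer-matched" working database from an SSU reference release: by
default one mismatch per primer is tolerated, because known host (snail)
sequences differ from the universal eukaryotic reverse primer at a single
position.

Matching is combinatorial (set-subset on IUPAC codes), not thermodynamic.
The scan is vectorized over 4-bit base masks; an O(n·m) naive scan over all
positions is the reference behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    BITMASK,
    IUPAC_SETS,
    encode,
    reverse_complement,
    validate_sequence,
)
from .refdb import RefDB, RefSeq, TaxonomyPath

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 1
#: default amplicon length window for an 18S V4 assay, nt
DEFAULT_MIN_LEN = 200
DEFAULT_MAX_LEN = 600


@dataclass(frozen=True)
class Primer:
    """A 5'→3' oligo. Blocking primers may carry a 3' C3-spacer flag."""

    name: str
    sequence: str
    role: str = "forward"  # forward | reverse | blocking
    modification_3prime: str = "none"  # none | spacer_C3

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.role not in ("forward", "reverse", "blocking"):
            raise ValueError(f"unknown primer role {self.role!r}")
        if self.modification_3prime not in ("none", "spacer_C3"):
            raise ValueError(
                f"unknown 3' modification {self.modification_3prime!r}"
            )
        if len(seq) < 8:
            raise ValueError(f"primer {self.name!r}: length < 8")
        validate_sequence(seq, context=f"primer {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        d = 1
        for s in self.sequence:
            d *= len(IUPAC_SETS[s])
        return d


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    marker_name: str = ""

    def __post_init__(self) -> None:
        if self.forward.role != "forward":
            raise ValueError("forward slot must hold a forward-role primer")
        if self.reverse.role != "reverse":
            raise ValueError("reverse slot must hold a reverse-role primer")


@dataclass(frozen=True)
class SiteMatch:
    """A primer binding site in sense-strand coordinates (0-based, half-open).

    ``strand`` '+' means the primer as written matches ``ref[start:end]``;
    '-' means its reverse complement does. ``mismatch_positions`` are
    primer-relative (5'-based on the primer as written).
    """

    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class AmpliconRecord:
    """One predicted amplicon, written forward-primer → reverse-primer.

    Coordinates are 0-based half-open on the reference's sense strand and
    include both primer-binding sites. For strand '-' the amplicon sequence
    is the reverse complement of ``reference[start:end]``.
    """

    ref_id: str
    taxonomy: TaxonomyPath
    start: int
    end: int
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"

    def __len__(self) -> int:
        return len(self.sequence)


def count_mismatches(primer: Primer | str, window: str) -> tuple[int, list[int]]:
    """Positionwise IUPAC subset comparison of a primer against a window."""
    pseq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    if len(pseq) != len(window):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pseq)}"
        )
    positions = []
    for i, (p, t) in enumerate(zip(pseq, window.upper())):
        if (BITMASK[t] & ~BITMASK[p]) & 0xF:
            positions.append(i)
    return len(positions), positions


def _primer_masks(seq: str) -> np.ndarray:
    return encode(seq)


def _scan(target_masks: np.ndarray, primer_masks: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every start position (vectorized)."""
    n, m = target_masks.size, primer_masks.size
    if n < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_masks, m)
    fail = (windows & ~primer_masks) & 0xF
    return (fail != 0).sum(axis=1)


def find_primer_sites(
    ref: RefSeq | str,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    search_revcomp: bool = True,
) -> list[SiteMatch]:
    """All binding sites with ≤ ``max_mismatch`` mismatches.

    Results are sorted by (mismatches, start, strand) and reported in
    sense-strand coordinates. A reference shorter than the primer yields an
    empty list.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if isinstance(ref, RefSeq):
        ref_id, seq = ref.id, ref.sequence
    else:
        ref_id, seq = "", ref.upper()
    m = len(primer)
    if len(seq) < m:
        return []
    target = encode(seq)
    pseq = primer.sequence
    sites: list[SiteMatch] = []
    patterns = [("+", _primer_masks(pseq))]
    if search_revcomp:
        patterns.append(("-", _primer_masks(reverse_complement(pseq))))
    for strand, pat in patterns:
        counts = _scan(target, pat)
        for start in np.nonzero(counts <= max_mismatch)[0]:
            start = int(start)
            window = seq[start : start + m]
            if strand == "+":
                _, pos = count_mismatches(pseq, window)
            else:
                # primer-relative positions: compare primer to the revcomp
                # of the sense window
                _, pos = count_mismatches(pseq, reverse_complement(window))
            sites.append(
                SiteMatch(
                    ref_id=ref_id,
                    start=start,
                    end=start + m,
                    strand=strand,
                    mismatches=len(pos),
                    mismatch_positions=tuple(pos),
                )
            )
    sites.sort(key=lambda s: (s.mismatches, s.start, s.strand))
    return sites


def _best_pair_on_strand(
    seq: str,
    target: np.ndarray,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int,
    min_len: int,
    max_len: int,
) -> tuple[int, int, int, int] | None:
    """Best (fwd_start, rev_site_start, fwd_mm, rev_mm) reading 5'→3' on seq.

    The forward primer binds as written; the reverse primer binds the
    opposite strand, i.e. its reverse complement appears downstream on this
    strand. Forward sites are tried in (mismatches, start) order; the first
    with a compatible reverse site wins, the reverse site chosen by
    (mismatches, start).
    """
    lf, lr = len(fwd), len(rev)
    fcounts = _scan(target, _primer_masks(fwd.sequence))
    if fcounts.size == 0:
        return None
    rcounts = _scan(target, _primer_masks(reverse_complement(rev.sequence)))
    fhits = [(int(fcounts[i]), int(i)) for i in np.nonzero(fcounts <= max_mismatch)[0]]
    rhits = [(int(rcounts[i]), int(i)) for i in np.nonzero(rcounts <= max_mismatch)[0]]
    if not fhits or not rhits:
        return None
    fhits.sort()
    rhits.sort()
    for fmm, fs in fhits:
        for rmm, rs in rhits:
            if rs < fs + lf:
                continue
            length = rs + lr - fs
            if min_len <= length <= max_len:
                return fs, rs, fmm, rmm
    return None


def extract_amplicons(
    db: RefDB | Iterable[RefSeq],
    pair: PrimerPair,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    search_revcomp: bool = True,
) -> list[AmpliconRecord]:
    """One best amplicon per reference, or none.

    Both reference orientations are considered by default; when both yield a
    pair the one with fewer total mismatches wins (tie → sense orientation).
    References without a valid site pair are skipped and counted in a log
    summary.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    amplicons: list[AmpliconRecord] = []
    n_skipped = 0
    for rec in db:
        seq = rec.sequence
        n = len(seq)
        target = encode(seq)
        best = None  # (total_mm, strand_rank, result, strand, oriented_seq)
        hit = _best_pair_on_strand(
            seq, target, pair.forward, pair.reverse, max_mismatch, min_len, max_len
        )
        if hit is not None:
            best = (hit[2] + hit[3], 0, hit, "+", seq)
        if search_revcomp:
            rc = reverse_complement(seq)
            hit_rc = _best_pair_on_strand(
                rc,
                _primer_masks(rc),
                pair.forward,
                pair.reverse,
                max_mismatch,
                min_len,
                max_len,
            )
            if hit_rc is not None:
                cand = (hit_rc[2] + hit_rc[3], 1, hit_rc, "-", rc)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            n_skipped += 1
            continue
        _, _, (fs, rs, fmm, rmm), strand, oriented = best
        a_start, a_end = fs, rs + len(pair.reverse)
        amp_seq = oriented[a_start:a_end]
        if strand == "-":
            # map back to sense-strand coordinates
            a_start, a_end = n - a_end, n - a_start
        amplicons.append(
            AmpliconRecord(
                ref_id=rec.id,
                taxonomy=rec.taxonomy,
                start=a_start,
                end=a_end,
                sequence=amp_seq,
                fwd_mismatches=fmm,
                rev_mismatches=rmm,
                strand=strand,
            )
        )
    total = len(amplicons) + n_skipped
    logger.info(
        "extract_amplicons: %d/%d references yielded an amplicon "
        "(%d skipped: no compatible %s site pair at <=%d mismatches)",
        len(amplicons),
        total,
        n_skipped,
        pair.marker_name or "primer",
        max_mismatch,
    )
    return amplicons


def expand_degenerate(primer: Primer | str, cap: int = 64) -> list[str]:
    """All concrete ACGT expansions of a degenerate oligo, lexicographic."""
    seq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    validate_sequence(seq, context="oligo")
    deg = 1
    for s in seq:
        deg *= len(IUPAC_SETS[s])
    if deg > cap:
        raise ValueError(
            f"degeneracy {deg} exceeds cap {cap}; use a consensus "
            "representation instead of full expansion"
        )
    choices = [sorted(IUPAC_SETS[s]) for s in seq]
    return ["".join(p) for p in product(*choices)]


def amplicons_to_tsv(amplicons: Sequence[AmpliconRecord]) -> pd.DataFrame:
    """Human-readable sidecar table (coordinates 1-based inclusive)."""
    rows = [
        {
            "ref_id": a.ref_id,
            "lineage": str(a.taxonomy),
            "start": a.start + 1,
            "end": a.end,
            "strand": a.strand,
            "fwd_mismatches": a.fwd_mismatches,
            "rev_mismatches": a.rev_mismatches,
            "length": len(a),
        }
        for a in amplicons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_id",
            "lineage",
            "start",
            "end",
            "strand",
            "fwd_mismatches",
            "rev_mismatches",
            "length",
        ],
    )


def write_amplicons_fasta(
    amplicons: Sequence[AmpliconRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.ref_id}/{a.start}-{a.end} {a.taxonomy}\n")
            fh.write(a.sequence + "\n")
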