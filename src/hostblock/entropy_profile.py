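"""Per-column Shannon entropy over the anchored 3' terminal amplicon region.

The last W nucleotides of each amplicon (default 40, covering the reverse
primer binding site plus its upstream flank) are stacked right-anchored at
the amplicon 3' terminus — a positional alignment justified by the shared
primer anchor, in place of a multiple sequence alignment. Host and
non-target entropy profiles computed column-by-column locate the design
window: columns conserved in the host but variable among microeukaryotes.

Entropy is reported in bits by default (configurable base); gap symbols are
excluded from column frequencies, and an all-gap column is reported as
missing (NaN), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import CONCRETE, GAP
from .insilico_pcr import AmpliconRecord

DEFAULT_WINDOW = 40

#: column count classes: four concrete bases, pooled ambiguity codes, gap
SYMBOL_CLASSES = ("A", "C", "G", "T", "other", "gap")

HOST = "host"
NON_TARGET = "non_target"


@dataclass
class TerminalBlock:
    """Right-anchored matrix of 3'-terminal amplicon windows.

    Every row has exactly ``window_len`` columns; amplicons shorter than the
    window are left-padded with the gap symbol. Column ``window_len - 1`` is
    each amplicon's final base.
    """

    window_len: int
    rows: list[str]
    labels: list[tuple[str, str]]  # (ref_id, set label)

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.labels):
            raise ValueError("rows and labels length mismatch")
        for r in self.rows:
            if len(r) != self.window_len:
                raise ValueError(
                    f"row length {len(r)} != window length {self.window_len}"
                )

    def rows_for(self, set_label: str) -> list[str]:
        return [r for r, (_, s) in zip(self.rows, self.labels) if s == set_label]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class EntropyProfile:
    """Per-column symbol-class counts and Shannon entropy for one set."""

    set_label: str
    counts: pd.DataFrame  # index 0..W-1, columns SYMBOL_CLASSES
    entropy: np.ndarray  # bits (or the configured base); NaN = all-gap

    def __len__(self) -> int:
        return len(self.entropy)


def _classify(symbol: str) -> str:
    if symbol in CONCRETE:
        return symbol
    if symbol == GAP:
        return "gap"
    return "other"


def build_terminal_block(
    amplicons: Sequence[AmpliconRecord | str],
    window_len: int = DEFAULT_WINDOW,
    set_labels: Mapping[str, str] | Sequence[str] | str = HOST,
) -> TerminalBlock:
    """Stack the last ``window_len`` symbols of each amplicon, right-justified.

    ``set_labels`` assigns each row to a set: a single label for all rows, a
    parallel sequence, or a mapping from ref_id. Accepts plain strings (e.g.
    a user-supplied pre-aligned region) as well as amplicon records.
    """
    if window_len < 1:
        raise ValueError("window length must be >= 1")
    if len(amplicons) == 0:
        raise ValueError("cannot build a terminal block from zero amplicons")
    rows, labels = [], []
    for i, amp in enumerate(amplicons):
        if isinstance(amp, AmpliconRecord):
            ref_id, seq = amp.ref_id, amp.sequence
        else:
            ref_id, seq = f"row{i}", str(amp).upper()
        tail = seq[-window_len:]
        row = GAP * (window_len - len(tail)) + tail
        if isinstance(set_labels, str):
            label = set_labels
        elif isinstance(set_labels, Mapping):
            label = set_labels[ref_id]
        else:
            label = set_labels[i]
        rows.append(row)
        labels.append((ref_id, label))
    return TerminalBlock(window_len=window_len, rows=rows, labels=labels)


def column_entropy(counts: Mapping[str, int], base: float = 2.0) -> float:
    """Shannon entropy of one column; gaps excluded; all-gap → NaN."""
    total = 0
    vals = []
    for sym, c in counts.items():
        if c < 0:
            raise ValueError("negative count")
        if sym == "gap" or sym == GAP or c == 0:
            continue
        vals.append(c)
        total += c
    if total == 0:
        return float("nan")
    f = np.asarray(vals, dtype=float) / total
    return float(-(f * (np.log(f) / np.log(base))).sum())


def _profile_for(rows: list[str], set_label: str, base: float) -> EntropyProfile:
    W = len(rows[0])
    counts = pd.DataFrame(
        0, index=range(W), columns=list(SYMBOL_CLASSES), dtype=int
    )
    for row in rows:
        for j, sym in enumerate(row):
            counts.loc[j, _classify(sym)] += 1
    ent = np.array(
        [
            column_entropy(counts.loc[j].to_dict(), base=base)
            for j in range(W)
        ]
    )
    return EntropyProfile(set_label=set_label, counts=counts, entropy=ent)


def entropy_profiles(
    block: TerminalBlock, base: float = 2.0
) -> tuple[EntropyProfile, EntropyProfile]:
    """Independent host and non-target per-column entropy vectors."""
    host_rows = block.rows_for(HOST)
    nt_rows = block.rows_for(NON_TARGET)
    if not host_rows:
        raise ValueError("terminal block contains no host rows")
    if not nt_rows:
        raise ValueError("terminal block contains no non_target rows")
    return (
        _profile_for(host_rows, HOST, base),
        _profile_for(nt_rows, NON_TARGET, base),
    )


def design_window_report(
    host_profile: EntropyProfile,
    non_target_profile: EntropyProfile,
    primer_site_len: int,
) -> pd.DataFrame:
    """Column table for eyeballing the design window.

    ΔH = non-target entropy − host entropy; columns falling inside the
    reverse-primer binding site (the last ``primer_site_len`` positions) are
    flagged. Columns are reported 1-based.
    """
    if len(host_profile) != len(non_target_profile):
        raise ValueError("profiles have unequal length")
    W = len(host_profile)
    return pd.DataFrame(
        {
            "column": np.arange(1, W + 1),
            "host_H": host_profile.entropy,
            "non_target_H": non_target_profile.entropy,
            "delta_H": non_target_profile.entropy - host_profile.entropy,
            "inside_reverse_primer_site": np.arange(W) >= W - primer_site_len,
        }
    )


def profiles_to_tsv(*profiles: EntropyProfile) -> pd.DataFrame:
    """Long-form per-column table (column, set, class counts, entropy)."""
    frames = []
    for p in profiles:
        df = p.counts.copy()
        df.insert(0, "column", np.arange(1, len(p) + 1))
        df.insert(1, "set", p.set_label)
        df["H"] = p.entropy
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def read_prealigned_region(path: str | Path, set_labels: Mapping[str, str]) -> TerminalBlock:
    """Load a user-supplied pre-aligned terminal region (FASTA, may contain gaps).

    All rows must share one alignment length, which becomes the window.
    """
    from Bio import SeqIO

    rows, labels = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append(str(rec.seq).upper().replace("U", "T").replace(".", GAP))
        labels.append((rec.id, set_labels[rec.id]))
    if not rows:
        raise ValueError(f"no records in {path}")
    W = len(rows[0])
    return TerminalBlock(window_len=W, rows=rows, labels=labels)


def plot_entropy_profiles(
    host_profile: EntropyProfile,
    non_target_profile: EntropyProfile,
    primer_site_len: int,
    path: str | Path,
) -> None:
    """Simple two-line entropy figure with the primer site shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    W = len(host_profile)
    x = np.arange(1, W + 1)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(x, host_profile.entropy, label="host", color="tab:blue")
    ax.plot(
        x, non_target_profile.entropy, label="non-target", color="tab:red"
    )
    ax.axvspan(W - primer_site_len + 0.5, W + 0.5, alpha=0.15, color="grey",
               label="reverse primer site")
    ax.set_xlabel("terminal-window column (3' end at right)")
    ax.set_ylabel("Shannon entropy (bits)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
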