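"""IUPAC nucleotide alphabet: degeneracy sets, bitmask encoding, complements.

Primer matching throughout the package uses the *set-subset* rule: a primer
symbol covers a target symbol iff the target's base set is a subset of the
primer's. Under this rule an ``N`` in a reference sequence matches only a
primer ``N`` — a deliberately conservative treatment of low-quality
reference positions.
"""

from __future__ import annotations

import numpy as np

# Base sets of the 15 IUPAC nucleotide symbols (DNA alphabet, U folded into T
# on input by the readers).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_SYMBOLS = frozenset(IUPAC_SETS)
CONCRETE = "ACGT"
GAP = "-"

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

#: symbol -> 4-bit mask of the bases it denotes
BITMASK: dict[str, int] = {
    sym: sum(_BITS[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}

_MASK_TO_SYM = {m: s for s, m in BITMASK.items()}

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

COMPLEMENT: dict[str, str] = {
    sym: _MASK_TO_SYM[sum(_BITS[_COMPLEMENT_BASE[b]] for b in bases)]
    for sym, bases in IUPAC_SETS.items()
}

# uint8 lookup table from ASCII code to bitmask; 0 marks a non-IUPAC byte.
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _mask in BITMASK.items():
    _ENCODE_LUT[ord(_sym)] = _mask


def is_iupac(symbol: str) -> bool:
    return symbol in IUPAC_SYMBOLS


def validate_sequence(seq: str, *, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending symbol, if any."""
    bad = set(seq) - IUPAC_SYMBOLS
    if bad:
        raise ValueError(
            f"{context} contains non-IUPAC symbol(s): {sorted(bad)!r}"
        )


def normalize(seq: str) -> str:
    """Uppercase and fold RNA U into T (Silva ships RNA-alphabet sequences)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[s] for s in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol {exc.args[0]!r} in sequence") from exc


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask vector.

    Raises ``ValueError`` on non-IUPAC symbols.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _ENCODE_LUT[arr]
    if (masks == 0).any():
        idx = int(np.argmax(masks == 0))
        raise ValueError(f"non-IUPAC symbol {seq[idx]!r} at position {idx}")
    return masks


def iupac_match(primer_symbol: str, target_symbol: str) -> bool:
    """True iff the target symbol's base set is a subset of the primer's."""
    try:
        p = BITMASK[primer_symbol]
    except KeyError:
        raise ValueError(f"non-IUPAC primer symbol {primer_symbol!r}") from None
    try:
        t = BITMASK[target_symbol]
    except KeyError:
        raise ValueError(f"non-IUPAC target symbol {target_symbol!r}") from None
    return (t & ~p) == 0
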