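"""Independent brute-force oracles used by the tests.

Deliberately re-derived from first principles (own IUPAC table, naive
all-positions scans, closed-form entropy/Tm) so they share no code with the
implementation they check.
"""

import math

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    out = []
    for s in reversed(seq):
        bases = IUPAC[s]
        comp = "".join(sorted(_COMP[b] for b in bases))
        out.append(next(k for k, v in IUPAC.items() if "".join(sorted(v)) == comp))
    return "".join(out)


def symbol_covers(primer_sym, target_sym):
    return set(IUPAC[target_sym]) <= set(IUPAC[primer_sym])


def mismatches(primer, window):
    return sum(
        0 if symbol_covers(p, t) else 1 for p, t in zip(primer, window)
    )


def naive_sites(seq, primer, k, search_revcomp=True):
    """All (start, strand, mismatches) with count <= k, unsorted."""
    m = len(primer)
    hits = []
    for start in range(len(seq) - m + 1):
        window = seq[start : start + m]
        mm = mismatches(primer, window)
        if mm <= k:
            hits.append((start, "+", mm))
        if search_revcomp:
            mm = mismatches(primer, revcomp(window))
            if mm <= k:
                hits.append((start, "-", mm))
    return hits


def naive_is_blocked(amplicon, blocker, k):
    """Full-length blocker match on the reverse-complement strand."""
    rc = revcomp(amplicon)
    m = len(blocker)
    if m > len(rc):
        return False
    return any(
        mismatches(blocker, rc[i : i + m]) <= k
        for i in range(len(rc) - m + 1)
    )


def shannon_entropy(counts, base=2.0):
    total = sum(counts)
    return -sum(
        (c / total) * math.log(c / total, base) for c in counts if c > 0
    )


def wallace_tm(seq):
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2 * at + 4 * gc
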