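"""Seeded generator of Silva-like reference databases with known truth.

The generator emulates the structure the design method relies on: a single
ancestral SSU-like sequence carries one concrete expansion of each
amplification-primer site at fixed offsets; host records descend from it
with low divergence, an (optionally) conserved 3'-terminal region, and a
host-specific mismatch injected inside the reverse-primer binding site —
the single-position difference that motivates the one-mismatch matching
allowance and that a consensus blocker can exploit. Non-target records
diverge strongly outside the (protected) primer sites; decoys are unrelated
random sequences without primer sites. Substitutions are i.i.d. uniform
over the three alternative bases (Jukes–Cantor-like); no indels.

Same config (including seed) → byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import random

import pandas as pd

from .alphabet import COMPLEMENT, IUPAC_SETS, reverse_complement
from .insilico_pcr import Primer, PrimerPair, expand_degenerate
from .refdb import RefDB, RefSeq, TaxonomyPath

# ---------------------------------------------------------------------------
# published 18S V4 assay oligos (Silva-wide snail-blocking design)

FORWARD_18SV4 = "CCAGCASCYGCGGTAATTCC"
REVERSE_18SV4 = "ACTTTCGTTCTTGATYRA"
BLOCKER_18SV4 = "TCTTGACTAATGAAAACATTCTTGACAA"

HOST_TAXONOMY = (
    "Eukaryota;Opisthokonta;Metazoa;Mollusca;Gastropoda;Heterobranchia;Biomphalaria"
)

NON_TARGET_TAXONOMIES = (
    "Eukaryota;SAR;Alveolata;Ciliophora;Oligohymenophorea",
    "Eukaryota;Amoebozoa;Lobosa;Tubulinea;Arcellinida",
    "Eukaryota;Opisthokonta;Holozoa;Ichthyosporea;Ichthyophonida",
    "Eukaryota;SAR;Stramenopiles;Ochrophyta;Chrysophyceae",
    "Eukaryota;Archaeplastida;Chloroplastida;Chlorophyta;Chlorophyceae",
)

DECOY_TAXONOMY = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Escherichia"
)


def published_primer_set() -> tuple[PrimerPair, Primer]:
    """The 18S V4 amplification pair and the snail blocking primer."""
    pair = PrimerPair(
        forward=Primer("18SV4_fwd", FORWARD_18SV4, role="forward"),
        reverse=Primer("18SV4_rev", REVERSE_18SV4, role="reverse"),
        marker_name="18SV4",
    )
    blocker = Primer(
        "18SV4BP", BLOCKER_18SV4, role="blocking", modification_3prime="spacer_C3"
    )
    return pair, blocker


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated reference database.

    ``d_host``/``d_nt`` are per-site substitution probabilities from the
    common ancestor. ``host_primer_mismatch_rate`` is the per-host-record
    probability of carrying the host-specific mismatch at reverse-primer
    position ``host_mismatch_rev_offset`` (0-based from the primer 5' end;
    the default sits in the primer's 3' suffix, inside the blocker-overlap
    region). With ``conserve_host_terminal`` the last ``terminal_window``
    nucleotides of the host amplicon evolve like primer sites (protected).
    """

    seed: int = 0
    n_host: int = 100
    n_non_target: int = 100
    n_decoy: int = 10
    ancestor_len: int = 1800
    d_host: float = 0.005
    d_nt: float = 0.15
    conserve_host_terminal: bool = True
    terminal_window: int = 40
    host_primer_mismatch_rate: float = 1.0
    host_mismatch_rev_offset: int = 14
    protect_nt_primer_sites: bool = True
    fwd_offset: int = 400
    insert_len: int = 342
    host_taxonomy: str = HOST_TAXONOMY
    non_target_taxonomies: tuple[str, ...] = NON_TARGET_TAXONOMIES
    decoy_taxonomy: str = DECOY_TAXONOMY

    def __post_init__(self) -> None:
        if not (0 <= self.d_host < 1 and 0 <= self.d_nt < 1):
            raise ValueError("divergences must lie in [0, 1)")
        if min(self.n_host, self.n_non_target, self.n_decoy) < 0:
            raise ValueError("record counts must be >= 0")
        if not (0 <= self.host_primer_mismatch_rate <= 1):
            raise ValueError("host_primer_mismatch_rate must lie in [0, 1]")


def _mutate(
    seq: list[str],
    rate: float,
    protected: set[int],
    rng: random.Random,
) -> int:
    """In-place i.i.d. substitution outside protected sites; returns count."""
    n = 0
    if rate <= 0:
        return 0
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = rng.choice(alternatives)
            n += 1
    return n


def simulate_refdb_with_truth(
    config: SimConfig, pair: PrimerPair
) -> tuple[RefDB, pd.DataFrame]:
    """Simulate a database plus a truth table.

    Truth columns: id, set (host/non_target/decoy), has_primer_mismatch,
    mismatch_genome_pos (0-based, -1 if none), n_substitutions.
    """
    rng = random.Random(config.seed)
    fwd_exp = expand_degenerate(pair.forward)[0]
    rev_exp = expand_degenerate(pair.reverse)[0]
    lf, lr = len(fwd_exp), len(rev_exp)
    fwd_start = config.fwd_offset
    rev_start = fwd_start + lf + config.insert_len
    amp_end = rev_start + lr
    if amp_end + 10 > config.ancestor_len:
        raise ValueError(
            "ancestor too short for both primer sites plus the configured insert"
        )
    if config.host_mismatch_rev_offset >= lr:
        raise ValueError("host mismatch offset beyond reverse primer length")

    ancestor = [rng.choice("ACGT") for _ in range(config.ancestor_len)]
    ancestor[fwd_start : fwd_start + lf] = list(fwd_exp)
    ancestor[rev_start:amp_end] = list(reverse_complement(rev_exp))

    primer_sites = set(range(fwd_start, fwd_start + lf)) | set(
        range(rev_start, amp_end)
    )
    host_protected = set(primer_sites)
    if config.conserve_host_terminal:
        host_protected |= set(range(amp_end - config.terminal_window, amp_end))
    nt_protected = set(primer_sites) if config.protect_nt_primer_sites else set()

    # host-specific mismatch: a base outside the reverse primer's IUPAC set
    # at the chosen primer position (on the strand the primer anneals to)
    p = config.host_mismatch_rev_offset
    genome_pos = rev_start + (lr - 1 - p)
    allowed = IUPAC_SETS[pair.reverse.sequence[p]]
    mm_base_primer_strand = next(b for b in "ACGT" if b not in allowed)
    mm_base_genome = COMPLEMENT[mm_base_primer_strand]

    records: list[RefSeq] = []
    truth_rows: list[dict] = []

    def add(rec_id: str, seq: str, lineage: str, set_label: str,
            has_mm: bool, mm_pos: int, n_sub: int) -> None:
        records.append(
            RefSeq(rec_id, seq, TaxonomyPath.from_string(lineage))
        )
        truth_rows.append(
            {
                "id": rec_id,
                "set": set_label,
                "has_primer_mismatch": has_mm,
                "mismatch_genome_pos": mm_pos,
                "n_substitutions": n_sub,
            }
        )

    for i in range(config.n_host):
        seq = list(ancestor)
        has_mm = rng.random() < config.host_primer_mismatch_rate
        if has_mm:
            seq[genome_pos] = mm_base_genome
        n_sub = _mutate(seq, config.d_host, host_protected, rng)
        add(
            f"HOST{i + 1:04d}",
            "".join(seq),
            config.host_taxonomy,
            "host",
            has_mm,
            genome_pos if has_mm else -1,
            n_sub,
        )

    for i in range(config.n_non_target):
        seq = list(ancestor)
        n_sub = _mutate(seq, config.d_nt, nt_protected, rng)
        lineage = config.non_target_taxonomies[
            i % len(config.non_target_taxonomies)
        ]
        add(f"NT{i + 1:04d}", "".join(seq), lineage, "non_target", False, -1, n_sub)

    for i in range(config.n_decoy):
        seq = "".join(rng.choice("ACGT") for _ in range(config.ancestor_len))
        add(f"DECOY{i + 1:03d}", seq, config.decoy_taxonomy, "decoy", False, -1, 0)

    db = RefDB(records, source_label=f"simulated(seed={config.seed})")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "id",
            "set",
            "has_primer_mismatch",
            "mismatch_genome_pos",
            "n_substitutions",
        ],
    )
    return db, truth


def simulate_refdb(config: SimConfig, pair: PrimerPair) -> RefDB:
    """Simulate a Silva-like database (see :func:`simulate_refdb_with_truth`)."""
    db, _ = simulate_refdb_with_truth(config, pair)
    return db


def reference_fixture() -> tuple[RefDB, PrimerPair, Primer]:
    """A small bundled database plus the published primer set.

    Handy for overlap/Tm/length checks and round-trip tests without any
    external download: 6 host snails, 10 microeukaryotes, 2 decoys under
    the default study conditions at a fixed seed.
    """
    pair, blocker = published_primer_set()
    cfg = SimConfig(seed=128, n_host=6, n_non_target=10, n_decoy=2)
    return simulate_refdb(cfg, pair), pair, blocker
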