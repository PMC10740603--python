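"""In-silico specificity of a blocking primer.

A record is called *blocked* when the blocker, full length, matches
somewhere on the amplicon with at most ``k_block`` mismatches under the
IUPAC subset rule. The blocker competes with the reverse primer, so by
default it is matched against the amplicon's reverse-complement strand
(where the reverse primer itself anneals); a ``both_strands`` flag adds the
written-orientation scan for safety audits. Binary match calls only — no
elongation-arrest biochemistry is modelled.

The report mirrors the published style of evaluation: fraction of host
amplicons predicted removed, fraction of non-target (microeukaryote)
amplicons collaterally targeted, and a per-clade breakdown of the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import encode, reverse_complement
from .insilico_pcr import AmpliconRecord, Primer, _scan

logger = logging.getLogger(__name__)


def _seq_of(record: AmpliconRecord | str) -> str:
    return record.sequence if isinstance(record, AmpliconRecord) else str(record).upper()


def is_blocked(
    amplicon: AmpliconRecord | str,
    blocker: Primer | str,
    k_block: int = 0,
    both_strands: bool = False,
) -> bool:
    """Whether the blocker is predicted to anneal to this amplicon.

    A blocker longer than the amplicon cannot anneal full-length and yields
    ``False`` (logged at debug level).
    """
    if k_block < 0:
        raise ValueError("k_block must be >= 0")
    bseq = blocker.sequence if isinstance(blocker, Primer) else str(blocker).upper()
    aseq = _seq_of(amplicon)
    if len(bseq) > len(aseq):
        logger.debug(
            "blocker (%d nt) longer than amplicon (%d nt); skipped",
            len(bseq),
            len(aseq),
        )
        return False
    target = encode(aseq)
    # annealing strand: the blocker as written matches revcomp(amplicon),
    # i.e. revcomp(blocker) appears on the amplicon as written
    counts = _scan(target, encode(reverse_complement(bseq)))
    if counts.size and counts.min() <= k_block:
        return True
    if both_strands:
        counts = _scan(target, encode(bseq))
        if counts.size and counts.min() <= k_block:
            return True
    return False


@dataclass
class SpecificityReport:
    blocker_sequence: str
    k_block: int
    host_total: int
    host_blocked: int
    non_target_total: int
    non_target_blocked: int
    clade_table: pd.DataFrame  # clade, n_blocked, n_total (blocked clades only)
    blocked_non_target_ids: list[str]

    @property
    def host_fraction(self) -> float:
        return self.host_blocked / self.host_total

    @property
    def non_target_fraction(self) -> float:
        return self.non_target_blocked / self.non_target_total


def evaluate(
    blocker: Primer | str,
    host_amplicons: Sequence[AmpliconRecord],
    non_target_amplicons: Sequence[AmpliconRecord],
    k_block: int = 0,
    clade_rank_for_breakdown: int = 2,
    both_strands: bool = False,
) -> SpecificityReport:
    """Predicted-blocked fractions per set plus a per-clade breakdown.

    ``clade_rank_for_breakdown`` is the 0-based lineage depth used to label
    blocked non-targets (clamped to each record's lineage tip).
    """
    if len(host_amplicons) == 0:
        raise ValueError("host amplicon set is empty")
    if len(non_target_amplicons) == 0:
        raise ValueError("non-target amplicon set is empty")
    bseq = blocker.sequence if isinstance(blocker, Primer) else str(blocker).upper()

    host_hits = sum(
        1 for a in host_amplicons if is_blocked(a, bseq, k_block, both_strands)
    )
    blocked_ids: list[str] = []
    clade_blocked: dict[str, int] = {}
    clade_total: dict[str, int] = {}
    for a in non_target_amplicons:
        if isinstance(a, AmpliconRecord):
            clade = a.taxonomy.rank_at(clade_rank_for_breakdown)
            rid = a.ref_id
        else:
            clade, rid = "unclassified", ""
        clade_total[clade] = clade_total.get(clade, 0) + 1
        if is_blocked(a, bseq, k_block, both_strands):
            clade_blocked[clade] = clade_blocked.get(clade, 0) + 1
            blocked_ids.append(rid)
    clade_table = pd.DataFrame(
        [
            {"clade": c, "n_blocked": nb, "n_total": clade_total[c]}
            for c, nb in sorted(clade_blocked.items())
        ],
        columns=["clade", "n_blocked", "n_total"],
    )
    return SpecificityReport(
        blocker_sequence=bseq,
        k_block=k_block,
        host_total=len(host_amplicons),
        host_blocked=host_hits,
        non_target_total=len(non_target_amplicons),
        non_target_blocked=len(blocked_ids),
        clade_table=clade_table,
        blocked_non_target_ids=blocked_ids,
    )


def report_to_text(report: SpecificityReport) -> str:
    lines = [
        f"blocking primer: {report.blocker_sequence}",
        f"mismatch allowance (k_block): {report.k_block}",
        f"host amplicons predicted blocked: {report.host_blocked}/"
        f"{report.host_total} ({100 * report.host_fraction:.1f}%)",
        f"non-target amplicons predicted blocked: {report.non_target_blocked}/"
        f"{report.non_target_total} ({100 * report.non_target_fraction:.2f}%)",
    ]
    if len(report.clade_table):
        lines.append("blocked non-targets by clade:")
        for _, row in report.clade_table.iterrows():
            lines.append(
                f"  {row['clade']}: {row['n_blocked']}/{row['n_total']}"
            )
    else:
        lines.append("no non-target amplicon is predicted to be blocked")
    return "\n".join(lines) + "\n"


def report_to_tsv(report: SpecificityReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": "host",
                "n_total": report.host_total,
                "n_blocked": report.host_blocked,
                "fraction": report.host_fraction,
            },
            {
                "set": "non_target",
                "n_total": report.non_target_total,
                "n_blocked": report.non_target_blocked,
                "fraction": report.non_target_fraction,
            },
        ]
    )


def coamplification_summary(sample_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample read proportions with an across-sample mean ± sd footer.

    ``sample_counts`` has one row per sample and one column per read class
    (e.g. host, microeukaryote, other). Proportions sum to 1 per sample.
    The dispersion is the sample standard deviation (n−1), the convention
    suited to the small sample counts of read-partition tables.
    """
    counts = sample_counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("read counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"sample(s) with zero total reads: {bad}")
    props = counts.div(totals, axis=0)
    summary = pd.DataFrame(
        [props.mean(axis=0), props.std(axis=0, ddof=1)],
        index=["mean", "sd"],
    )
    return pd.concat([props, summary])
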