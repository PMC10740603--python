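"""Taxonomically annotated rRNA reference databases.

Reads and writes Silva-style FASTA (``>accession Domain;...;Genus``) and
partitions a database into host, non-target and excluded sets by clade name —
the construction behind a snail-host database and a "metazoa-free"
microeukaryote database drawn from one SSU reference release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .alphabet import normalize, validate_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered lineage from root to tip, Silva-style (free rank count).

    Rank matching is exact whole-rank string equality, case-insensitive —
    "Metazoa" never matches "Metazoan-like".
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(r == "" for r in self.ranks):
            raise ValueError("empty rank name in taxonomy path")

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonomyPath":
        parts = [p.strip() for p in lineage.strip().strip(";").split(";")]
        return cls(tuple(p for p in parts if p))

    def contains(self, clade: str) -> bool:
        clade_l = clade.lower()
        return any(r.lower() == clade_l for r in self.ranks)

    def rank_at(self, depth: int) -> str:
        """Clade name at a 0-based depth, clamped to the tip."""
        if not self.ranks:
            return "unclassified"
        return self.ranks[min(depth, len(self.ranks) - 1)]

    def __str__(self) -> str:
        return ";".join(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class RefSeq:
    """One reference sequence: accession, IUPAC nucleotides, lineage."""

    id: str
    sequence: str
    taxonomy: TaxonomyPath = TaxonomyPath(())

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty record id")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        validate_sequence(self.sequence, context=f"record {self.id}")


@dataclass
class RefDB:
    """An ordered collection of :class:`RefSeq` with unique ids."""

    records: list[RefSeq] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[RefSeq]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta_with_taxonomy(
    path: str | Path, header_dialect: str = "silva"
) -> RefDB:
    """Read a FASTA reference database.

    ``silva`` dialect: header is ``>id<sep>rank1;rank2;...`` with the lineage
    after the first whitespace (space or tab). ``plain`` dialect: no lineage.
    U→T and case normalization are applied to sequences.
    """
    if header_dialect not in ("silva", "plain"):
        raise ValueError(f"unknown header dialect {header_dialect!r}")
    path = Path(path)
    _check_fasta_shape(path)
    records: list[RefSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if header_dialect == "silva":
            # description = "id lineage"; strip the id token
            rest = rec.description[len(rec.id):].strip()
            tax = TaxonomyPath.from_string(rest) if rest else TaxonomyPath(())
        else:
            tax = TaxonomyPath(())
        seq = normalize(str(rec.seq))
        records.append(RefSeq(id=rec.id, sequence=seq, taxonomy=tax))
    return RefDB(records=records, source_label=str(path))


def _check_fasta_shape(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header.

    Biopython's parser silently yields nothing on such files; a named parse
    error is friendlier.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno} is not a FASTA header "
                    f"(expected '>'): {line.strip()[:40]!r}"
                )
            return


def write_fasta_with_taxonomy(db: RefDB, path: str | Path) -> None:
    """Write Silva-dialect FASTA (id, one space, semicolon lineage)."""
    with open(path, "w") as fh:
        for rec in db:
            lineage = str(rec.taxonomy)
            header = f">{rec.id} {lineage}" if lineage else f">{rec.id}"
            fh.write(header + "\n")
            fh.write(rec.sequence + "\n")


def partition_by_taxonomy(
    db: RefDB, host_clade: str, exclude_clades: Iterable[str]
) -> tuple[RefDB, RefDB, RefDB]:
    """Split a database into (host, non_target, excluded) by clade labels.

    A record carrying the host clade goes to the host set even when it also
    carries an excluded clade (a Heterobranchia snail is host although
    Heterobranchia sits inside Metazoa). Remaining records carrying any
    excluded clade are excluded; the rest are non-targets. The three sets
    partition the input exactly.
    """
    if not host_clade:
        raise ValueError("empty host clade name")
    exclude = [c for c in exclude_clades]
    if any(not c for c in exclude):
        raise ValueError("empty exclude clade name")
    host, non_target, excluded = [], [], []
    for rec in db:
        if rec.taxonomy.contains(host_clade):
            host.append(rec)
        elif any(rec.taxonomy.contains(c) for c in exclude):
            excluded.append(rec)
        else:
            non_target.append(rec)
    if not host:
        logger.warning(
            "host clade %r not found in any lineage of %s",
            host_clade,
            db.source_label or "database",
        )
    label = db.source_label
    return (
        RefDB(host, source_label=f"{label}[host={host_clade}]"),
        RefDB(non_target, source_label=f"{label}[non_target]"),
        RefDB(excluded, source_label=f"{label}[excluded]"),
    )


def subset_to_clade(db: RefDB, clade: str) -> RefDB:
    """Records whose lineage contains ``clade``, in input order."""
    kept = [rec for rec in db if rec.taxonomy.contains(clade)]
    return RefDB(kept, source_label=f"{db.source_label}[{clade}]")


def partition_table(
    host: RefDB, non_target: RefDB, excluded: RefDB
) -> pd.DataFrame:
    """TSV-ready table of (id, lineage, partition label)."""
    rows = []
    for label, part in (
        ("host", host),
        ("non_target", non_target),
        ("excluded", excluded),
    ):
        for rec in part:
            rows.append(
                {"id": rec.id, "lineage": str(rec.taxonomy), "partition": label}
            )
    return pd.DataFrame(rows, columns=["id", "lineage", "partition"])
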