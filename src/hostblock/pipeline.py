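"""End-to-end blocker design: partition → in-silico PCR → entropy → design →
in-silico specificity. One call mirrors the full published workflow on any
taxonomically annotated reference database."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import entropy_profile as ep
from .blocker_design import (
    DesignConstraints,
    DesignResult,
    TmModel,
    enumerate_candidates,
)
from .insilico_pcr import (
    AmpliconRecord,
    PrimerPair,
    extract_amplicons,
)
from .refdb import RefDB, partition_by_taxonomy, subset_to_clade
from .specificity import SpecificityReport, evaluate

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    host_amplicons: list[AmpliconRecord]
    non_target_amplicons: list[AmpliconRecord]
    block: ep.TerminalBlock
    host_profile: ep.EntropyProfile
    non_target_profile: ep.EntropyProfile
    design: DesignResult
    report: SpecificityReport | None
    window_report: pd.DataFrame


def design_blocker(
    db: RefDB,
    pair: PrimerPair,
    host_clade: str,
    exclude_clades: list[str],
    design_clade: str = "",
    max_mismatch: int = 1,
    min_len: int = 200,
    max_len: int = 600,
    window: int = ep.DEFAULT_WINDOW,
    entropy_base: float = 2.0,
    constraints: DesignConstraints | None = None,
    tm_model: TmModel | None = None,
    clade_rank: int = 2,
) -> PipelineResult:
    """Design and evaluate a blocking primer against one reference database.

    ``host_clade`` selects the host set (e.g. the snail sub-class), with
    ``design_clade`` optionally narrowing the consensus to a genus within
    it; ``exclude_clades`` (e.g. the host's phylum or kingdom) are removed
    from the non-target set so the off-target evaluation covers only the
    community of interest.
    """
    constraints = constraints or DesignConstraints()
    tm_model = tm_model or TmModel()

    host_db, non_target_db, excluded_db = partition_by_taxonomy(
        db, host_clade, exclude_clades
    )
    logger.info(
        "partition: %d host / %d non-target / %d excluded records",
        len(host_db), len(non_target_db), len(excluded_db),
    )
    design_db = subset_to_clade(host_db, design_clade) if design_clade else host_db
    if len(design_db) == 0:
        raise ValueError(
            f"no host records for clade {design_clade or host_clade!r}"
        )

    host_amps = extract_amplicons(design_db, pair, max_mismatch, min_len, max_len)
    nt_amps = extract_amplicons(non_target_db, pair, max_mismatch, min_len, max_len)
    if not host_amps:
        raise ValueError("no host amplicon matched the primer pair")
    if not nt_amps:
        raise ValueError("no non-target amplicon matched the primer pair")

    labels = {a.ref_id: ep.HOST for a in host_amps}
    labels.update({a.ref_id: ep.NON_TARGET for a in nt_amps})
    block = ep.build_terminal_block(host_amps + nt_amps, window, labels)
    host_prof, nt_prof = ep.entropy_profiles(block, base=entropy_base)
    window_report = ep.design_window_report(host_prof, nt_prof, len(pair.reverse))

    design = enumerate_candidates(block, nt_amps, pair, constraints, tm_model)
    report = None
    if design.top is not None:
        report = evaluate(
            design.top.sequence,
            host_amps,
            nt_amps,
            k_block=constraints.k_block,
            clade_rank_for_breakdown=clade_rank,
        )
    else:
        logger.warning(
            "no candidate satisfied the design constraints "
            "(%d near-misses recorded)", len(design.diagnostics)
        )
    return PipelineResult(
        host_amplicons=host_amps,
        non_target_amplicons=nt_amps,
        block=block,
        host_profile=host_prof,
        non_target_profile=nt_prof,
        design=design,
        report=report,
        window_report=window_report,
    )
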