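"""Up/down regulation summaries of candidate genes per tissue.

For each (candidate gene, tissue) pair the per-group directions are
tallied and reconciled by majority vote: "up" when up-groups outnumber
down-groups, "down" symmetrically, "mixed" on a non-zero tie, "flat"
when no group moved. By default every measuring group votes; a switch
restricts the vote to groups where the gene reached significance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import GeneTestResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectionSummary:
    gene_id: str
    tissue: str
    n_up: int
    n_down: int
    n_flat: int
    call: str  # {"up", "down", "mixed", "flat"}


def _call(n_up: int, n_down: int) -> str:
    if n_up > n_down and n_up > 0:
        return "up"
    if n_down > n_up and n_down > 0:
        return "down"
    if n_up == n_down and n_up > 0:
        return "mixed"
    return "flat"


def summarize_directions(gene_results: Sequence[GeneTestResult],
                         group_tissues: Mapping[str, str],
                         candidate_genes: Sequence[str],
                         significant_only: bool = False,
                         p_threshold: float = 0.05) -> list[DirectionSummary]:
    """Tally per-tissue direction votes for each candidate gene.

    ``group_tissues`` maps group_id -> tissue. Output is ordered by
    (gene, tissue); a candidate absent from every group yields a warning
    and no rows.
    """
    wanted = set(candidate_genes)
    tallies: dict[tuple[str, str], list[int]] = {}
    seen_genes: set[str] = set()
    for r in gene_results:
        if r.gene_id not in wanted:
            continue
        seen_genes.add(r.gene_id)
        if significant_only and r.p_value > p_threshold:
            continue
        tissue = group_tissues[r.group_id]
        t = tallies.setdefault((r.gene_id, tissue), [0, 0, 0])
        t[{"up": 0, "down": 1, "flat": 2}[r.direction]] += 1
    for gene in sorted(wanted - seen_genes):
        logger.warning("summarize_directions: candidate %r measured in no group", gene)
    return [
        DirectionSummary(gene_id=g, tissue=t, n_up=u, n_down=d, n_flat=f,
                         call=_call(u, d))
        for (g, t), (u, d, f) in sorted(tallies.items())
    ]
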