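"""The cis SNP-window screen: genes within ±1 Mb of susceptibility SNPs,
re-ranked by differential-expression percentage.

A gene qualifies for a SNP when its whole genomic interval (1-based,
inclusive) intersects the closed window [pos - radius, pos + radius] on
the same chromosome — any overlap counts, not the midpoint or TSS
(``mode`` exposes those stricter alternatives). Boundaries are closed: a
gene ending exactly radius bp from the SNP qualifies. Strand plays no
role. SNP panels and expression percentages are matched within one
disease arm only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigError
from .ranking import RankingConfig, passes_threshold
from .types import GeneInterval, PercentageRecord, SnpRecord, normalize_chrom

DEFAULT_RADIUS = 1_000_000

MODE_INTERVAL = "interval"
MODE_MIDPOINT = "midpoint"
MODE_TSS = "tss"  # 5' end approximated by interval start (strand ignored)


@dataclass(frozen=True)
class GeneSnpAssignment:
    """A gene together with every SNP whose window it falls in."""

    gene_id: str
    rsids: tuple[str, ...]
    min_distance: int  # 0 when some SNP lies inside the gene interval


def _effective_interval(gene: GeneInterval, mode: str) -> tuple[int, int]:
    if mode == MODE_INTERVAL:
        return gene.start, gene.end
    if mode == MODE_MIDPOINT:
        mid = (gene.start + gene.end) // 2
        return mid, mid
    if mode == MODE_TSS:
        return gene.start, gene.start
    raise ConfigError(f"unknown window mode {mode!r}")


def window_membership(gene: GeneInterval, snp: SnpRecord,
                      radius: int = DEFAULT_RADIUS,
                      mode: str = MODE_INTERVAL) -> tuple[bool, Optional[int]]:
    """Decide whether a gene lies within ``radius`` of a SNP.

    Returns ``(member, distance)``; distance is 0 when the SNP position
    falls inside the gene extent, otherwise the gap to the nearer gene
    end, and None when the chromosomes differ.
    """
    if radius < 0:
        raise ConfigError(f"radius must be non-negative, got {radius}")
    if normalize_chrom(gene.chromosome) != normalize_chrom(snp.chromosome):
        return False, None
    start, end = _effective_interval(gene, mode)
    if start <= snp.position <= end:
        return True, 0
    distance = min(abs(snp.position - start), abs(snp.position - end))
    return distance <= radius, distance


def genes_near_snps(genes: Sequence[GeneInterval], snps: Sequence[SnpRecord],
                    radius: int = DEFAULT_RADIUS,
                    mode: str = MODE_INTERVAL) -> list[GeneSnpAssignment]:
    """Assign every qualifying SNP to every gene, sorted by gene id.

    Simple all-pairs sweep: panels hold tens to hundreds of SNPs, so no
    interval index is warranted.
    """
    out: list[GeneSnpAssignment] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        rsids: list[str] = []
        dists: list[int] = []
        for snp in snps:
            member, dist = window_membership(gene, snp, radius, mode)
            if member:
                rsids.append(snp.rsid)
                dists.append(dist)
        if rsids:
            out.append(GeneSnpAssignment(gene_id=gene.gene_id,
                                         rsids=tuple(rsids),
                                         min_distance=min(dists)))
    return out


@dataclass(frozen=True)
class ScreenedCandidate:
    gene_id: str
    percentage: float
    n_significant: int
    n_measured: int
    rank: Optional[int]
    rsids: tuple[str, ...]
    min_distance: int


def screen_candidates(assignments: Sequence[GeneSnpAssignment],
                      percentage_records: Sequence[PercentageRecord],
                      config: RankingConfig
                      ) -> tuple[list[ScreenedCandidate], list[GeneSnpAssignment]]:
    """Intersect SNP-proximal genes with ranked percentages and re-select.

    Returns ``(candidates, unranked)``: candidates are assigned genes
    whose percentage passes the screen threshold (strictly-greater by
    convention for this screen) and min_groups filter, ordered by the
    percentage ranking; ``unranked`` lists assigned genes with no
    expression record — reported, never candidates.
    """
    by_gene = {r.gene_id: r for r in percentage_records}
    candidates: list[ScreenedCandidate] = []
    unranked: list[GeneSnpAssignment] = []
    for a in assignments:
        rec = by_gene.get(a.gene_id)
        if rec is None:
            unranked.append(a)
            continue
        if rec.n_measured < config.min_groups:
            continue
        if passes_threshold(rec.percentage, config.candidate_threshold_pct,
                            config.threshold_mode):
            candidates.append(ScreenedCandidate(
                gene_id=a.gene_id, percentage=rec.percentage,
                n_significant=rec.n_significant, n_measured=rec.n_measured,
                rank=rec.rank, rsids=a.rsids, min_distance=a.min_distance))
    candidates.sort(key=lambda c: (-c.percentage, -c.n_measured, c.gene_id))
    return candidates, unranked
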