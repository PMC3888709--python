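"""Cross-study vote counting: the differential-expression-percentage
statistic, ranking, candidate selection, and the multiplicity comparison.

Per gene, the statistic is 100 * k / n where n counts the groups in
which the gene is measured (has at least one retained probe) and k the
groups with gene-level P <= ``p_threshold`` (boundary inclusive). The
denominator is per-gene, not the total number of groups: genes absent
from some platforms are scored only where they were measurable.

Candidate selection applies a percentage threshold — inclusive
(``at_least``) for the genome-wide selection, exclusive
(``strictly_greater``) for the SNP-window re-ranking — and, for the
smaller obesity arm, a minimum number of available P values.

Multiple-testing adjustment (Bonferroni, Benjamini-Hochberg) is provided
as a reporting side-channel comparing per-group significant counts; the
vote count itself always uses raw P values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .types import GeneTestResult, PercentageRecord

THRESHOLD_AT_LEAST = "at_least"
THRESHOLD_STRICTLY_GREATER = "strictly_greater"


@dataclass(frozen=True)
class RankingConfig:
    """Thresholds for the vote count and candidate selection.

    ``min_groups`` excludes genes with fewer available per-group P
    values (0 for the T2DM arm, 10 for the obesity arm).
    """

    p_threshold: float = 0.05
    min_groups: int = 0
    candidate_threshold_pct: float = 50.0
    threshold_mode: str = THRESHOLD_AT_LEAST

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError(f"p_threshold {self.p_threshold} outside (0, 1)")
        if not 0 <= self.candidate_threshold_pct <= 100:
            raise ConfigError(
                f"candidate_threshold_pct {self.candidate_threshold_pct} outside [0, 100]")
        if self.min_groups < 0:
            raise ConfigError("min_groups must be non-negative")
        if self.threshold_mode not in (THRESHOLD_AT_LEAST, THRESHOLD_STRICTLY_GREATER):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")


def de_percentage(gene_results_across_groups: Sequence[GeneTestResult],
                  config: RankingConfig = RankingConfig()) -> PercentageRecord:
    """Vote-count one gene's results across groups into a PercentageRecord."""
    results = list(gene_results_across_groups)
    if not results:
        raise ValidationError("gene measured in zero groups")
    gene_ids = {r.gene_id for r in results}
    if len(gene_ids) != 1:
        raise ValidationError(f"mixed gene ids in one vote count: {sorted(gene_ids)}")
    group_ids = [r.group_id for r in results]
    if len(set(group_ids)) != len(group_ids):
        raise ValidationError(
            f"gene {results[0].gene_id!r}: duplicate group in vote count")
    k = sum(1 for r in results if r.p_value <= config.p_threshold)
    return PercentageRecord(gene_id=results[0].gene_id,
                            n_measured=len(results), n_significant=k)


def percentages_from_results(all_results: Iterable[GeneTestResult],
                             config: RankingConfig = RankingConfig()
                             ) -> list[PercentageRecord]:
    """Vote-count every gene appearing in a pooled per-group result stream."""
    by_gene: dict[str, list[GeneTestResult]] = {}
    for r in all_results:
        by_gene.setdefault(r.gene_id, []).append(r)
    return [de_percentage(rs, config) for _, rs in sorted(by_gene.items())]


def rank_genes(records: Sequence[PercentageRecord]) -> list[PercentageRecord]:
    """Order records and assign ranks 1..N.

    Descending percentage; ties broken by larger ``n_measured`` (more
    evidence first), then lexicographic gene id — so the order is a
    deterministic function of the record set, independent of input order.
    """
    ordered = sorted(records,
                     key=lambda r: (-r.percentage, -r.n_measured, r.gene_id))
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
    return ordered


def passes_threshold(percentage: float, threshold_pct: float, mode: str) -> bool:
    if mode == THRESHOLD_AT_LEAST:
        return percentage >= threshold_pct
    if mode == THRESHOLD_STRICTLY_GREATER:
        return percentage > threshold_pct
    raise ConfigError(f"unknown threshold_mode {mode!r}")


def select_candidates(ranked_records: Sequence[PercentageRecord],
                      config: RankingConfig) -> list[PercentageRecord]:
    """Filter ranked records by min_groups and the percentage threshold."""
    return [r for r in ranked_records
            if r.n_measured >= config.min_groups
            and passes_threshold(r.percentage, config.candidate_threshold_pct,
                                 config.threshold_mode)]


def mean_percentage(records: Sequence[PercentageRecord]) -> float:
    """Unweighted mean of per-gene percentages (the genome-wide average)."""
    if not records:
        raise ValidationError("mean_percentage of empty record list")
    return float(np.mean([r.percentage for r in records]))


def adjust_pvalues(p_list: Sequence[float], method: str) -> list[float]:
    """Adjust a P-value list by Bonferroni or Benjamini-Hochberg step-up.

    Input order is preserved in the output.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values outside [0, 1]")
    if method == "bonferroni":
        adj = multipletests(p, method="bonferroni")[1]
    elif method == "bh_fdr":
        adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ConfigError(f"unknown adjustment method {method!r}")
    return [float(x) for x in adj]


@dataclass(frozen=True)
class AdjustmentCounts:
    """Per-group significant-gene counts under raw/FDR/Bonferroni criteria."""

    group_id: str
    n_genes: int
    raw_significant: int
    fdr_significant: int
    bonferroni_significant: int


def compare_adjustment(group_results: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> list[AdjustmentCounts]:
    """Count significant genes per group before and after adjustment.

    For every group the counts are ordered raw >= FDR >= Bonferroni
    because BH-adjusted values never exceed Bonferroni-adjusted ones and
    never fall below the raw P values.
    """
    out = []
    for group_id in sorted(group_results):
        p = list(group_results[group_id])
        if not p:
            out.append(AdjustmentCounts(group_id, 0, 0, 0, 0))
            continue
        raw = sum(1 for x in p if x <= alpha)
        fdr = sum(1 for x in adjust_pvalues(p, "bh_fdr") if x <= alpha)
        bonf = sum(1 for x in adjust_pvalues(p, "bonferroni") if x <= alpha)
        out.append(AdjustmentCounts(group_id, len(p), raw, fdr, bonf))
    return out
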