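"""End-to-end orchestration: per-group testing, vote-count ranking, the
SNP-window screen, and direction summaries, with deterministic reports.

A *study directory* is the on-disk layout produced by
:func:`genevote.simulate.write_study` (and the natural layout for real
data prepared by hand):

    groups/<group_id>.matrix.tsv + <group_id>.design.tsv
    annotations/<platform_id>.tsv
    genes.tsv  (optional, gene intervals)
    snps.tsv   (optional, SNP panel; or per-arm snps_<disease>.tsv)

Outputs are TSV reports plus a JSON manifest echoing the configuration;
identical inputs and config reproduce every report byte for byte. The
candidate selection uses raw per-group P values; the Bonferroni/FDR
comparison table is reported alongside, not used as a gate.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import io as study_io
from .direction import summarize_directions
from .errors import GenevoteError, ValidationError
from .ranking import (
    RankingConfig,
    THRESHOLD_AT_LEAST,
    THRESHOLD_STRICTLY_GREATER,
    compare_adjustment,
    mean_percentage,
    percentages_from_results,
    rank_genes,
    select_candidates,
)
from .snpwindow import DEFAULT_RADIUS, MODE_INTERVAL, genes_near_snps, screen_candidates
from .stats import test_group
from .types import format_percentage

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; defaults reproduce the published analysis.

    Per-arm dictionaries are keyed by disease label: the T2DM arm selects
    candidates at >=50% with no minimum group count, the smaller obesity
    arm at >=60% with at least 10 available P values; the SNP-window
    re-ranking uses strictly-greater thresholds (>40% / >50%).
    """

    p_threshold: float = 0.05
    f_alpha: float = 0.05
    min_groups: dict = field(default_factory=lambda: {"T2DM": 0, "obesity": 10})
    candidate_threshold_pct: dict = field(
        default_factory=lambda: {"T2DM": 50.0, "obesity": 60.0})
    screen_threshold_pct: dict = field(
        default_factory=lambda: {"T2DM": 40.0, "obesity": 50.0})
    candidate_mode: str = THRESHOLD_AT_LEAST
    screen_mode: str = THRESHOLD_STRICTLY_GREATER
    window_radius: int = DEFAULT_RADIUS
    window_mode: str = MODE_INTERVAL
    snp_assoc_p_max: Optional[float] = 5e-8
    seed: int = 0

    def ranking_config(self, arm: str) -> RankingConfig:
        return RankingConfig(
            p_threshold=self.p_threshold,
            min_groups=int(self.min_groups.get(arm, 0)),
            candidate_threshold_pct=float(self.candidate_threshold_pct.get(arm, 50.0)),
            threshold_mode=self.candidate_mode)

    def screen_config(self, arm: str) -> RankingConfig:
        return RankingConfig(
            p_threshold=self.p_threshold,
            min_groups=int(self.min_groups.get(arm, 0)),
            candidate_threshold_pct=float(self.screen_threshold_pct.get(arm, 40.0)),
            threshold_mode=self.screen_mode)

    @classmethod
    def from_file(cls, path: PathLike) -> "PipelineConfig":
        """Load overrides from a JSON config file."""
        data = json.loads(Path(path).read_text())
        return cls(**data)


def discover_groups(study_dir: PathLike):
    """Load every (group, annotation) pair in a study directory."""
    study = Path(study_dir)
    designs = sorted((study / "groups").glob("*.design.tsv"))
    if not designs:
        raise ValidationError(f"{study}: no groups/*.design.tsv inputs found")
    pairs = []
    for design in designs:
        matrix = design.with_name(design.name.replace(".design.tsv", ".matrix.tsv"))
        if not matrix.exists():
            raise ValidationError(f"{study}: missing matrix for {design.name}")
        group = study_io.read_expression_group(matrix, design)
        ann_path = study / "annotations" / f"{group.platform_id}.tsv"
        if not ann_path.exists():
            raise ValidationError(
                f"{study}: missing annotation {ann_path.name} for group "
                f"{group.group_id}")
        annotation = study_io.read_probe_annotation(ann_path, group.platform_id)
        pairs.append((group, annotation))
    return pairs


def _snp_path(study: Path, arm: str) -> Optional[Path]:
    for cand in (study / f"snps_{arm}.tsv", study / "snps.tsv"):
        if cand.exists():
            return cand
    return None


def run_pipeline(study_dir: PathLike, out_dir: PathLike,
                 config: PipelineConfig = PipelineConfig()) -> dict:
    """Run test-groups -> rank -> snp-screen -> direction; return the manifest.

    Partial outputs are removed if any stage fails.
    """
    study = Path(study_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(study, out, config, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
    written.append(path)


def _run(study: Path, out: Path, config: PipelineConfig,
         written: list[Path]) -> dict:
    stages: dict[str, dict] = {}

    # stage 1: per-group gene tests
    pairs = discover_groups(study)
    all_results = []
    for group, annotation in pairs:
        all_results.extend(test_group(group, annotation, f_alpha=config.f_alpha))
    res_df = pd.DataFrame(
        [{"group_id": r.group_id, "gene_id": r.gene_id, "p_value": r.p_value,
          "direction": r.direction, "n_probes_used": r.n_probes_used}
         for r in all_results]).sort_values(["group_id", "gene_id"])
    _write_tsv(res_df, out / "group_results.tsv", written)
    stages["test_groups"] = {"n_groups": len(pairs), "n_rows": len(res_df)}

    # multiplicity comparison (reporting side-channel)
    by_group = {g.group_id: [] for g, _ in pairs}
    for r in all_results:
        by_group[r.group_id].append(r.p_value)
    adj = compare_adjustment(by_group, alpha=config.p_threshold)
    _write_tsv(pd.DataFrame([dataclasses.asdict(a) for a in adj]),
               out / "adjustment_comparison.tsv", written)

    arms = sorted({g.disease_label for g, _ in pairs})
    group_tissues = {g.group_id: g.tissue for g, _ in pairs}

    # stage 2: vote-count ranking and candidate selection per arm
    candidates_by_arm: dict[str, list[str]] = {}
    ranked_by_arm = {}
    for arm in arms:
        arm_groups = {g.group_id for g, _ in pairs if g.disease_label == arm}
        arm_results = [r for r in all_results if r.group_id in arm_groups]
        rcfg = config.ranking_config(arm)
        ranked = rank_genes(percentages_from_results(arm_results, rcfg))
        eligible = [r for r in ranked if r.n_measured >= rcfg.min_groups]
        selected = select_candidates(ranked, rcfg)
        chosen = {r.gene_id for r in selected}
        table = pd.DataFrame(
            [{"rank": r.rank, "gene_id": r.gene_id,
              "n_significant": r.n_significant, "n_measured": r.n_measured,
              "percentage": format_percentage(r.percentage),
              "candidate": int(r.gene_id in chosen)} for r in ranked])
        _write_tsv(table, out / f"ranked_{arm}.tsv", written)
        ranked_by_arm[arm] = ranked
        candidates_by_arm[arm] = [r.gene_id for r in selected]
        stages[f"rank_{arm}"] = {
            "n_genes": len(ranked), "n_eligible": len(eligible),
            "n_candidates": len(selected),
            "mean_percentage": (mean_percentage(eligible) if eligible else None)}

    # stage 3: optional SNP-window screen per arm
    genes_path = study / "genes.tsv"
    for arm in arms:
        snp_path = _snp_path(study, arm)
        if snp_path is None or not genes_path.exists():
            logger.info("snp-screen[%s]: no SNP panel and/or gene intervals; skipped", arm)
            stages[f"snp_screen_{arm}"] = {"skipped": True}
            continue
        snps = study_io.read_snp_table(snp_path, max_assoc_p=config.snp_assoc_p_max)
        intervals = study_io.read_gene_intervals(genes_path)
        assignments = genes_near_snps(intervals, snps, radius=config.window_radius,
                                      mode=config.window_mode)
        screened, unranked = screen_candidates(
            assignments, ranked_by_arm[arm], config.screen_config(arm))
        table = pd.DataFrame(
            [{"gene_id": c.gene_id, "percentage": format_percentage(c.percentage),
              "n_significant": c.n_significant, "n_measured": c.n_measured,
              "rsids": ";".join(c.rsids), "min_distance": c.min_distance}
             for c in screened])
        _write_tsv(table, out / f"snp_screen_{arm}.tsv", written)
        _write_tsv(pd.DataFrame(
            [{"gene_id": a.gene_id, "rsids": ";".join(a.rsids),
              "min_distance": a.min_distance} for a in unranked]),
            out / f"snp_screen_{arm}.unranked.tsv", written)
        stages[f"snp_screen_{arm}"] = {
            "n_assigned": len(assignments), "n_candidates": len(screened),
            "n_unranked": len(unranked)}

    # stage 4: direction summaries for the selected candidates
    for arm in arms:
        arm_groups = {g.group_id for g, _ in pairs if g.disease_label == arm}
        arm_results = [r for r in all_results if r.group_id in arm_groups]
        summaries = summarize_directions(arm_results, group_tissues,
                                         candidates_by_arm[arm])
        _write_tsv(pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries],
            columns=["gene_id", "tissue", "n_up", "n_down", "n_flat", "call"]),
            out / f"direction_{arm}.tsv", written)
        stages[f"direction_{arm}"] = {"n_rows": len(summaries)}

    import numpy
    import scipy

    from . import __version__
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {"genevote": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "stages": stages,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    written.append(path)
    return manifest
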