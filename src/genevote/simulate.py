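"""Synthetic multi-group case-control studies with known ground truth.

The generator stands in for a collection of public microarray datasets:
several groups (one per dataset) across tissues, each measured on its
own platform so genes are present only on a subset of platforms, with
multiple probes per gene, a sprinkling of ambiguous multi-gene probes,
and normalized log2 intensities modeled as Gaussian noise around a
per-gene baseline. A configurable set of planted genes carries a
constant case-control shift (in units of the noise SD) in a fraction of
the groups that measure them, with the shift's sign fixed per gene and
tissue so direction summaries have recoverable truth. Designated groups
can have their case subgroup's variance inflated to exercise the Welch
branch of the gated t-test.

Everything is reproducible from the single config seed, and a
:class:`SimulationTruth` ledger binds the emitted files to the planted
design for recovery tests.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import io as study_io
from .errors import ConfigError
from .types import ExpressionGroup, GeneInterval, ProbeAnnotation, SnpRecord

TISSUES = ("skeletal muscle", "adipose tissue", "islet", "liver", "blood",
           "arterial tissue")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the larger disease arm of a multi-tissue microarray
    compendium: 21 groups over 6 tissues, ~2000 genes per platform with
    1-3 probes each, unit-SD log2 noise around a baseline of 7, and 20
    planted genes shifted by 2 noise SDs in 70% of the groups that
    measure them.
    """

    n_groups: int = 21
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive uniform range
    multi_gene_probe_fraction: float = 0.05
    samples_per_subgroup: int = 5
    baseline_mean: float = 7.0
    noise_sd: float = 1.0
    n_planted: int = 20
    effect_sd_units: float = 2.0
    planted_group_fraction: float = 0.7
    variance_inflation: float = 1.0
    variance_inflation_fraction: float = 0.0
    platform_gene_dropout: float = 0.10
    n_tissues: int = 6
    disease_label: str = "T2DM"
    noise: str = "gaussian"  # or "student_t" (df=4) for heavier tails
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_genes < 1:
            raise ConfigError("n_groups and n_genes must be positive")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad probes_per_gene range {self.probes_per_gene}")
        if self.samples_per_subgroup < 3:
            raise ConfigError("samples_per_subgroup must be >= 3")
        if not 0 <= self.multi_gene_probe_fraction < 1:
            raise ConfigError("multi_gene_probe_fraction outside [0, 1)")
        if not 0 <= self.platform_gene_dropout < 1:
            raise ConfigError("platform_gene_dropout outside [0, 1)")
        if not 0 < self.planted_group_fraction <= 1:
            raise ConfigError("planted_group_fraction outside (0, 1]")
        if self.n_planted > self.n_genes:
            raise ConfigError("n_planted exceeds n_genes")
        if self.noise_sd <= 0 or self.effect_sd_units <= 0:
            raise ConfigError("noise_sd and effect_sd_units must be positive")
        if self.variance_inflation < 1:
            raise ConfigError("variance_inflation must be >= 1")
        if not 0 <= self.variance_inflation_fraction <= 1:
            raise ConfigError("variance_inflation_fraction outside [0, 1]")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise ConfigError(f"n_tissues must be in [1, {len(TISSUES)}]")
        if self.noise not in ("gaussian", "student_t"):
            raise ConfigError(f"unknown noise model {self.noise!r}")


@dataclass
class SimulationTruth:
    """Ground-truth ledger: what was planted where, and with which sign."""

    seed: int
    planted_gene_ids: tuple[str, ...]
    # gene -> tissue -> +1/-1 (sign of the case shift in that tissue)
    tissue_signs: dict[str, dict[str, int]]
    # gene -> group_id -> signed effect on the log2 scale
    perturbed: dict[str, dict[str, float]]
    # group_id -> genes present on that group's platform
    group_genes: dict[str, list[str]]
    # group_id -> tissue
    group_tissues: dict[str, str]
    variance_inflated_groups: tuple[str, ...]
    # probes tagged to >1 gene, per platform: probe -> [primary, secondary];
    # the probe's values follow the primary gene; must never reach results
    multi_gene_probes: dict[str, dict[str, list[str]]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        d["planted_gene_ids"] = tuple(d["planted_gene_ids"])
        d["variance_inflated_groups"] = tuple(d["variance_inflated_groups"])
        return cls(**d)


def _noise(rng: np.random.Generator, shape, model: str) -> np.ndarray:
    if model == "gaussian":
        return rng.standard_normal(shape)
    # unit-variance Student t(4): heavier tails, same scale
    df = 4
    return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2))


def simulate_studies(config: SimulationConfig
                     ) -> tuple[list[ExpressionGroup], list[ProbeAnnotation],
                                SimulationTruth]:
    """Generate a full multi-group study and its truth ledger."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    group_ids = [f"grp{i + 1:02d}" for i in range(config.n_groups)]
    tissues = {g: TISSUES[i % config.n_tissues] for i, g in enumerate(group_ids)}

    planted = sorted(rng.choice(config.n_genes, size=config.n_planted,
                                replace=False).tolist())
    planted_ids = tuple(gene_ids[i] for i in planted)
    tissue_signs = {
        g: {t: int(s) for t, s in zip(
            TISSUES[:config.n_tissues],
            rng.choice([-1, 1], size=config.n_tissues))}
        for g in planted_ids
    }
    gene_offsets = rng.normal(0.0, 0.5, size=config.n_genes)

    # per-group gene presence (platform content), drawn up front so planted
    # genes can be perturbed only in groups that actually measure them
    present: dict[str, np.ndarray] = {}
    for gid in group_ids:
        keep = rng.random(config.n_genes) >= config.platform_gene_dropout
        if not keep.any():
            keep[0] = True
        present[gid] = keep

    perturbed: dict[str, dict[str, float]] = {}
    effect = config.effect_sd_units * config.noise_sd
    for gi, gene in zip(planted, planted_ids):
        carrying = [g for g in group_ids if present[g][gi]]
        n_hit = int(round(config.planted_group_fraction * len(carrying)))
        n_hit = max(n_hit, 1) if carrying else 0
        hit = rng.choice(len(carrying), size=n_hit, replace=False) if n_hit else []
        perturbed[gene] = {
            carrying[j]: float(tissue_signs[gene][tissues[carrying[j]]] * effect)
            for j in sorted(int(x) for x in np.atleast_1d(hit))
        }

    n_inflated = int(round(config.variance_inflation_fraction * config.n_groups))
    inflated = set(rng.choice(config.n_groups, size=n_inflated,
                              replace=False).tolist()) if n_inflated else set()

    ns = config.samples_per_subgroup
    lo, hi = config.probes_per_gene
    groups: list[ExpressionGroup] = []
    annotations: list[ProbeAnnotation] = []
    multi_probes: dict[str, dict[str, list[str]]] = {}
    for idx, gid in enumerate(group_ids):
        platform = f"PLAT{idx + 1:02d}"
        gidx = np.flatnonzero(present[gid])
        n_probes_per = rng.integers(lo, hi + 1, size=gidx.size)
        probe_gene_idx = np.repeat(gidx, n_probes_per)
        n_probes = probe_gene_idx.size
        probe_ids = tuple(f"{platform}_p{j + 1:06d}" for j in range(n_probes))

        multi_mask = rng.random(n_probes) < config.multi_gene_probe_fraction
        second = rng.integers(0, config.n_genes, size=n_probes)
        mapping: dict[str, frozenset[str]] = {}
        tagged: dict[str, list[str]] = {}
        for j, pid in enumerate(probe_ids):
            g1 = gene_ids[probe_gene_idx[j]]
            if multi_mask[j]:
                g2 = gene_ids[second[j]]
                if g2 == g1:  # ensure genuinely multi-gene
                    g2 = gene_ids[(second[j] + 1) % config.n_genes]
                mapping[pid] = frozenset({g1, g2})
                tagged[pid] = [g1, g2]
            else:
                mapping[pid] = frozenset({g1})
        multi_probes[platform] = tagged
        annotations.append(ProbeAnnotation(platform_id=platform, mapping=mapping))

        noise = _noise(rng, (n_probes, 2 * ns), config.noise)
        if idx in inflated:
            noise[:, :ns] *= np.sqrt(config.variance_inflation)
        values = (config.baseline_mean
                  + gene_offsets[probe_gene_idx][:, None]
                  + config.noise_sd * noise)
        for gene, by_group in perturbed.items():
            if gid in by_group:
                rows = probe_gene_idx == gene_ids.index(gene)
                values[np.ix_(rows, range(ns))] += by_group[gid]

        case = tuple(f"{gid}_case{j + 1}" for j in range(ns))
        ctrl = tuple(f"{gid}_ctrl{j + 1}" for j in range(ns))
        groups.append(ExpressionGroup(
            group_id=gid, disease_label=config.disease_label,
            tissue=tissues[gid], platform_id=platform,
            probe_ids=probe_ids, sample_ids=case + ctrl,
            values=values, case_samples=case, control_samples=ctrl))

    truth = SimulationTruth(
        seed=config.seed,
        planted_gene_ids=planted_ids,
        tissue_signs=tissue_signs,
        perturbed=perturbed,
        group_genes={g: [gene_ids[i] for i in np.flatnonzero(present[g])]
                     for g in group_ids},
        group_tissues=dict(tissues),
        variance_inflated_groups=tuple(group_ids[i] for i in sorted(inflated)),
        multi_gene_probes=multi_probes,
    )
    return groups, annotations, truth


def simulate_gene_intervals(n_genes: int, n_chromosomes: int, chrom_length: int,
                            gene_length_range: tuple[int, int] = (5_000, 200_000),
                            seed: int = 0,
                            gene_ids: Optional[Sequence[str]] = None
                            ) -> list[GeneInterval]:
    """Place non-overlapping gene intervals on synthetic chromosomes.

    Genes are dealt round-robin to chromosomes; within each chromosome
    random lengths are drawn and starts chosen uniformly in the slack,
    so intervals never overlap and fit in [1, chrom_length].
    """
    lo, hi = gene_length_range
    if lo < 1 or lo > hi:
        raise ConfigError(f"bad gene_length_range {gene_length_range}")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ConfigError("gene_ids length does not match n_genes")
    rng = np.random.default_rng(seed)
    per_chrom: dict[int, list[str]] = {c: [] for c in range(n_chromosomes)}
    for i, g in enumerate(gene_ids):
        per_chrom[i % n_chromosomes].append(g)
    out: list[GeneInterval] = []
    for c in range(n_chromosomes):
        genes = per_chrom[c]
        if not genes:
            continue
        lengths = rng.integers(lo, hi + 1, size=len(genes))
        free = chrom_length - int(lengths.sum())
        if free < 0:
            raise ConfigError(
                f"chromosome {c + 1}: {len(genes)} genes of total length "
                f"{int(lengths.sum())} do not fit in {chrom_length}")
        cuts = np.sort(rng.integers(0, free + 1, size=len(genes)))
        offset = 0
        for g, length, cut in zip(genes, lengths, cuts):
            start = int(cut) + offset + 1
            out.append(GeneInterval(gene_id=g, chromosome=str(c + 1),
                                    start=start, end=start + int(length) - 1))
            offset += int(length)
    return out


def simulate_snp_panel(truth: SimulationTruth,
                       gene_intervals: Sequence[GeneInterval],
                       n_snps: int, near_fraction: float,
                       radius: int = 1_000_000, seed: int = 0,
                       chrom_length: Optional[int] = None) -> list[SnpRecord]:
    """Draw a SNP panel with a controlled share near planted genes.

    A ``near_fraction`` share of SNPs is placed uniformly within
    ``radius`` of a planted gene's interval; the rest uniformly over the
    chromosome space. Association P values are drawn below the usual
    genome-wide-significance line (5e-8) so the panel survives the
    input filter unchanged.
    """
    if not 0 <= near_fraction <= 1:
        raise ConfigError("near_fraction outside [0, 1]")
    by_gene = {g.gene_id: g for g in gene_intervals}
    chrom_max: dict[str, int] = {}
    for g in gene_intervals:
        chrom_max[g.chromosome] = max(chrom_max.get(g.chromosome, 1), g.end)
    if chrom_length is not None:
        for c in chrom_max:
            chrom_max[c] = max(chrom_max[c], chrom_length)
    if radius > max(chrom_max.values()):
        raise ConfigError(
            f"radius {radius} exceeds the longest chromosome "
            f"({max(chrom_max.values())})")
    planted_with_coords = [g for g in truth.planted_gene_ids if g in by_gene]
    rng = np.random.default_rng(seed)
    n_near = int(round(near_fraction * n_snps))
    if n_near and not planted_with_coords:
        raise ConfigError("near_fraction > 0 but no planted gene has coordinates")
    snps: list[SnpRecord] = []
    chroms = sorted(chrom_max)
    for i in range(n_snps):
        if i < n_near:
            gene = by_gene[planted_with_coords[int(rng.integers(0, len(planted_with_coords)))]]
            lo = max(1, gene.start - radius)
            hi = min(chrom_max[gene.chromosome], gene.end + radius)
            chrom, pos = gene.chromosome, int(rng.integers(lo, hi + 1))
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, chrom_max[chrom] + 1))
        assoc_p = float(10 ** rng.uniform(-12, np.log10(5e-8)))
        snps.append(SnpRecord(rsid=f"rs{900000 + i}", chromosome=chrom,
                              position=pos, assoc_p=assoc_p))
    return snps


def write_study(out_dir: Union[str, Path], groups: Sequence[ExpressionGroup],
                annotations: Sequence[ProbeAnnotation], truth: SimulationTruth,
                intervals: Optional[Sequence[GeneInterval]] = None,
                snps: Optional[Sequence[SnpRecord]] = None) -> Path:
    """Materialize a simulated study as a directory of pipeline inputs."""
    out = Path(out_dir)
    (out / "groups").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    for g in groups:
        study_io.write_expression_group(
            g, out / "groups" / f"{g.group_id}.matrix.tsv",
            out / "groups" / f"{g.group_id}.design.tsv")
    for a in annotations:
        study_io.write_probe_annotation(a, out / "annotations" / f"{a.platform_id}.tsv")
    (out / "truth.json").write_text(truth.to_json() + "\n")
    if intervals is not None:
        study_io.write_gene_intervals(intervals, out / "genes.tsv")
    if snps is not None:
        study_io.write_snp_table(snps, out / "snps.tsv")
    return out
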