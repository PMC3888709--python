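"""Core domain records shared across the pipeline.

Coordinates are stored 1-based inclusive at both ends (NCBI/CCDS
convention); BED input is converted on read. Chromosome labels from mixed
sources ("chr7" vs "7") are compared through :func:`normalize_chrom`.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CoordinateError, SubgroupSizeError, ValidationError

MIN_SUBGROUP_SIZE = 3

DISEASE_LABELS = ("T2DM", "obesity")


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a leading 'chr', uppercase X/Y/MT."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in {"x", "y", "mt", "m"} else s


def format_percentage(pct: float) -> str:
    """Render a percentage to one decimal place, rounding half up.

    The convention of the candidate tables: 61.111... -> "61.1", 50.0 -> "50.0".
    """
    q = decimal.Decimal(repr(float(pct))).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return str(q)


@dataclass(frozen=True)
class ExpressionGroup:
    """One case-control experiment: a normalized log2 probe matrix plus design.

    ``values`` is probes x samples, column order following ``sample_ids``.
    Case and control subgroups are disjoint, cover all samples, and each
    has at least :data:`MIN_SUBGROUP_SIZE` members.
    """

    group_id: str
    disease_label: str
    tissue: str
    platform_id: str
    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.disease_label not in DISEASE_LABELS:
            raise ValidationError(
                f"group {self.group_id!r}: unknown disease label "
                f"{self.disease_label!r}; expected one of {DISEASE_LABELS}"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = [p for p in set(self.probe_ids) if self.probe_ids.count(p) > 1]
            raise ValidationError(
                f"group {self.group_id!r}: duplicate probe id(s) {sorted(dupes)[:5]}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"group {self.group_id!r}: duplicate sample ids")
        case, ctrl = set(self.case_samples), set(self.control_samples)
        if case & ctrl:
            raise ValidationError(
                f"group {self.group_id!r}: samples in both subgroups: "
                f"{sorted(case & ctrl)}"
            )
        if case | ctrl != set(self.sample_ids):
            raise ValidationError(
                f"group {self.group_id!r}: case/control union does not equal "
                "the sample set"
            )
        for name, members in (("case", case), ("control", ctrl)):
            if len(members) < MIN_SUBGROUP_SIZE:
                raise SubgroupSizeError(
                    f"group {self.group_id!r}: {name} subgroup below minimum "
                    f"size {MIN_SUBGROUP_SIZE} (has {len(members)})"
                )
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"group {self.group_id!r}: matrix shape {v.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(v)):
            i, j = map(int, np.argwhere(~np.isfinite(v))[0])
            raise ValidationError(
                f"group {self.group_id!r}: non-finite value at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        object.__setattr__(self, "values", v)

    @property
    def case_columns(self) -> list[int]:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return [idx[s] for s in self.case_samples]

    @property
    def control_columns(self) -> list[int]:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return [idx[s] for s in self.control_samples]

    def case_matrix(self) -> np.ndarray:
        return self.values[:, self.case_columns]

    def control_matrix(self) -> np.ndarray:
        return self.values[:, self.control_columns]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Platform annotation: probe id -> set of gene ids (possibly empty/multi)."""

    platform_id: str
    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for probe, genes in self.mapping.items():
            gs = frozenset(str(g) for g in genes)
            if any(not g for g in gs):
                raise ValidationError(
                    f"platform {self.platform_id!r}: empty gene id for probe {probe!r}"
                )
            clean[str(probe)] = gs
        object.__setattr__(self, "mapping", clean)


@dataclass(frozen=True)
class SnpRecord:
    """A susceptibility SNP with 1-based chromosome position.

    ``assoc_p`` is the reported association P value (used only for the
    genome-wide-significance input filter); ``allele_freq_note`` is
    pass-through metadata.
    """

    rsid: str
    chromosome: str
    position: int
    assoc_p: Optional[float] = None
    allele_freq_note: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.position) < 1:
            raise CoordinateError(
                f"SNP {self.rsid!r}: position must be >= 1, got {self.position}"
            )
        object.__setattr__(self, "position", int(self.position))
        if self.assoc_p is not None and not (0 < float(self.assoc_p) <= 1):
            raise ValidationError(
                f"SNP {self.rsid!r}: assoc_p {self.assoc_p} outside (0, 1]"
            )


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic extent, 1-based and inclusive at both ends."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        s, e = int(self.start), int(self.end)
        if s < 1:
            raise CoordinateError(f"gene {self.gene_id!r}: start must be >= 1, got {s}")
        if s > e:
            raise CoordinateError(
                f"gene {self.gene_id!r}: start {s} > end {e}"
            )
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneTestResult:
    """Per (group, gene): aggregated P value, direction, and probe count.

    The P value is the minimum over the gene's retained probes; direction
    comes from the probe achieving that minimum.
    """

    group_id: str
    gene_id: str
    p_value: float
    direction: str  # {"up", "down", "flat"}
    n_probes_used: int


@dataclass
class PercentageRecord:
    """Per gene: k significant groups of n measured, and 100*k/n."""

    gene_id: str
    n_measured: int
    n_significant: int
    percentage: float = field(init=False)
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_measured < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: measured in zero groups"
            )
        if not 0 <= self.n_significant <= self.n_measured:
            raise ValidationError(
                f"gene {self.gene_id!r}: n_significant {self.n_significant} "
                f"outside [0, {self.n_measured}]"
            )
        self.percentage = 100.0 * self.n_significant / self.n_measured
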