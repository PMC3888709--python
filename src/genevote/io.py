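"""Readers and writers for every table the pipeline touches.

All tables are plain tab-delimited text:

* expression matrix — first column ``probe_id``, one column per sample;
* design — columns ``sample_id``, ``role`` (case/control), ``group_id``,
  ``disease``, ``tissue``, ``platform_id``;
* probe annotation — ``probe_id``, ``gene_ids`` (semicolon-joined, may be
  empty for unannotated probes);
* SNP panel — ``rsid``, ``chrom``, ``pos``, optional ``assoc_p`` and
  ``allele_freq_note``;
* gene intervals — ``gene_id``, ``chrom``, ``start``, ``end``, or standard
  4-column headerless BED.

The design file, not sample naming, is authoritative for case/control
assignment. Validation failures raise errors naming the offending
row/column so malformed public data fails loudly.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    DesignError,
    MatrixError,
    ValidationError,
)
from .types import (
    ExpressionGroup,
    GeneInterval,
    ProbeAnnotation,
    SnpRecord,
    format_percentage,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DESIGN_COLUMNS = ("sample_id", "role", "group_id", "disease", "tissue", "platform_id")


def read_expression_group(matrix_path: PathLike, design_path: PathLike) -> ExpressionGroup:
    """Read one group's expression matrix and its sample design table.

    The matrix is probes x samples with normalized log2 intensities; the
    design assigns every sample to exactly one of case/control and names
    the group, disease, tissue, and platform. Returns a validated
    :class:`ExpressionGroup` with matrix column order preserved.
    """
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    missing_cols = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing_cols:
        raise DesignError(f"{design_path}: design missing columns {missing_cols}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DesignError(f"{design_path}: duplicate sample {dup!r} in design")
    bad_role = design.loc[~design["role"].isin(["case", "control"])]
    if len(bad_role):
        raise DesignError(
            f"{design_path}: sample {bad_role['sample_id'].iloc[0]!r} has role "
            f"{bad_role['role'].iloc[0]!r}; expected case or control"
        )
    for col in ("group_id", "disease", "tissue", "platform_id"):
        if design[col].nunique() != 1:
            raise DesignError(
                f"{design_path}: column {col!r} must be constant within one group"
            )

    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "probe_id":
        raise MatrixError(
            f"{matrix_path}: first column must be 'probe_id', got {raw.columns[0]!r}"
        )
    probe_ids = raw["probe_id"].tolist()
    dup_probes = raw.loc[raw["probe_id"].duplicated(), "probe_id"]
    if len(dup_probes):
        raise MatrixError(f"{matrix_path}: duplicate probe id {dup_probes.iloc[0]!r}")

    sample_ids = list(raw.columns[1:])
    designed = set(design["sample_id"])
    undesigned = [s for s in sample_ids if s not in designed]
    if undesigned:
        raise DesignError(
            f"{design_path}: sample {undesigned[0]!r} in matrix has no design row"
        )
    absent = [s for s in designed if s not in sample_ids]
    if absent:
        raise DesignError(
            f"{matrix_path}: designed sample {sorted(absent)[0]!r} missing from matrix"
        )

    cells = raw[sample_ids]
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | cells.isna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise MatrixError(
            f"{matrix_path}: non-numeric or missing value at probe "
            f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )

    role = dict(zip(design["sample_id"], design["role"]))
    meta = design.iloc[0]
    return ExpressionGroup(
        group_id=meta["group_id"],
        disease_label=meta["disease"],
        tissue=meta["tissue"],
        platform_id=meta["platform_id"],
        probe_ids=tuple(probe_ids),
        sample_ids=tuple(sample_ids),
        values=numeric.to_numpy(dtype=float),
        case_samples=tuple(s for s in sample_ids if role[s] == "case"),
        control_samples=tuple(s for s in sample_ids if role[s] == "control"),
    )


def write_expression_group(group: ExpressionGroup, matrix_path: PathLike,
                           design_path: PathLike) -> None:
    """Write a group back to matrix + design TSVs (inverse of the reader)."""
    mat = pd.DataFrame(group.values, columns=list(group.sample_ids))
    mat.insert(0, "probe_id", list(group.probe_ids))
    mat.to_csv(matrix_path, sep="\t", index=False, float_format="%.6f")
    roles = {s: "case" for s in group.case_samples}
    roles.update({s: "control" for s in group.control_samples})
    design = pd.DataFrame({
        "sample_id": list(group.sample_ids),
        "role": [roles[s] for s in group.sample_ids],
        "group_id": group.group_id,
        "disease": group.disease_label,
        "tissue": group.tissue,
        "platform_id": group.platform_id,
    })
    design.to_csv(design_path, sep="\t", index=False)


def read_probe_annotation(path: PathLike, platform_id: str) -> ProbeAnnotation:
    """Read a probe -> gene-set annotation table for one platform."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_ids"):
        if col not in df.columns:
            raise ValidationError(f"{path}: annotation missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"{path}: probe {dup!r} annotated more than once")
    mapping = {
        row.probe_id: frozenset(g for g in row.gene_ids.split(";") if g)
        for row in df.itertuples()
    }
    return ProbeAnnotation(platform_id=platform_id, mapping=mapping)


def write_probe_annotation(annotation: ProbeAnnotation, path: PathLike) -> None:
    rows = [
        {"probe_id": probe, "gene_ids": ";".join(sorted(genes))}
        for probe, genes in sorted(annotation.mapping.items())
    ]
    pd.DataFrame(rows, columns=["probe_id", "gene_ids"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_table(path: PathLike, max_assoc_p: Optional[float] = None) -> list[SnpRecord]:
    """Read a SNP panel, optionally dropping rows with assoc_p above a cap.

    The cap reproduces the genome-wide-significance input filter
    (P <= 5e-8) applied when assembling the susceptibility panels; rows
    without an assoc_p column (or with blank cells) are always retained.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("rsid", "chrom", "pos"):
        if col not in df.columns:
            raise ValidationError(f"{path}: SNP table missing column {col!r}")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValidationError(f"{path}: duplicate rsid {dup!r}")
    records: list[SnpRecord] = []
    n_dropped = 0
    for row in df.itertuples():
        pos_text = row.pos.replace(",", "")
        try:
            pos = int(pos_text)
        except ValueError:
            raise CoordinateError(
                f"{path}: SNP {row.rsid!r} has non-integer position {row.pos!r}"
            ) from None
        assoc_p = None
        if "assoc_p" in df.columns and getattr(row, "assoc_p", "") != "":
            assoc_p = float(row.assoc_p)
        if max_assoc_p is not None and assoc_p is not None and assoc_p > max_assoc_p:
            n_dropped += 1
            continue
        note = getattr(row, "allele_freq_note", None) or None
        records.append(SnpRecord(rsid=row.rsid, chromosome=row.chrom,
                                 position=pos, assoc_p=assoc_p,
                                 allele_freq_note=note))
    if max_assoc_p is not None:
        logger.info("read_snp_table: dropped %d of %d SNPs with assoc_p > %g",
                    n_dropped, len(df), max_assoc_p)
    return records


def write_snp_table(snps: Sequence[SnpRecord], path: PathLike) -> None:
    rows = [{
        "rsid": s.rsid, "chrom": s.chromosome, "pos": s.position,
        "assoc_p": "" if s.assoc_p is None else repr(s.assoc_p),
        "allele_freq_note": s.allele_freq_note or "",
    } for s in snps]
    pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "assoc_p",
                                "allele_freq_note"]).to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: PathLike, dialect: str = "one_based_inclusive") -> list[GeneInterval]:
    """Read gene coordinates as 1-based inclusive intervals.

    ``dialect='bed'`` accepts standard headerless 4-column BED (0-based,
    half-open) and converts with start+1, end unchanged. Duplicate gene
    ids on the same chromosome are merged by coordinate union; on
    different chromosomes they are an error.
    """
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["chrom", "start", "end", "gene_id"], comment="#")
        starts = df["start"].astype(int) + 1
        ends = df["end"].astype(int)
    elif dialect == "one_based_inclusive":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"{path}: interval table missing column {col!r}")
        starts = df["start"].str.replace(",", "").astype(int)
        ends = df["end"].str.replace(",", "").astype(int)
    else:
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")

    merged: dict[str, GeneInterval] = {}
    for gene_id, chrom, start, end in zip(df["gene_id"], df["chrom"], starts, ends):
        iv = GeneInterval(gene_id=gene_id, chromosome=chrom, start=int(start), end=int(end))
        prev = merged.get(gene_id)
        if prev is None:
            merged[gene_id] = iv
        elif prev.chromosome == iv.chromosome:
            merged[gene_id] = GeneInterval(
                gene_id=gene_id, chromosome=prev.chromosome,
                start=min(prev.start, iv.start), end=max(prev.end, iv.end))
        else:
            raise CoordinateError(
                f"{path}: gene {gene_id!r} appears on chromosomes "
                f"{prev.chromosome!r} and {iv.chromosome!r}"
            )
    return list(merged.values())


def write_gene_intervals(intervals: Sequence[GeneInterval], path: PathLike,
                         dialect: str = "one_based_inclusive") -> None:
    if dialect == "bed":
        rows = [{"chrom": g.chromosome, "start": g.start - 1, "end": g.end,
                 "gene_id": g.gene_id} for g in intervals]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
    elif dialect == "one_based_inclusive":
        rows = [{"gene_id": g.gene_id, "chrom": g.chromosome, "start": g.start,
                 "end": g.end} for g in intervals]
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")


def write_candidate_report(records: Iterable[Mapping], path: PathLike,
                           format: str = "tsv") -> None:
    """Write a candidate-gene report with deterministic row order.

    Records carry at least gene_id, percentage, n_significant (k),
    n_measured (n) and rank; SNP-screen records add a semicolon-joined
    ``rsids`` field. Rows are ordered by rank then gene_id and
    percentages rendered to one decimal (half-up).
    """
    recs = sorted(records, key=lambda r: (r.get("rank") or 0, r["gene_id"]))
    if not recs:
        logger.warning("write_candidate_report: empty record list -> header-only file")
    columns = ["rank", "gene_id", "n_significant", "n_measured", "percentage"]
    extra = sorted({k for r in recs for k in r} - set(columns))
    columns += extra
    rows = []
    for r in recs:
        row = {c: r.get(c, "") for c in columns}
        row["percentage"] = format_percentage(r["percentage"])
        rows.append(row)
    if format == "tsv":
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(json.dumps(rows, indent=1, sort_keys=True) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
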