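"""Per-group differential expression: variance-ratio-gated t-tests and
min-P probe-to-gene aggregation.

Within one case-control group, each retained probe is tested with a
two-sided two-sample t-test. The pooled-variance test is used when a
two-sided variance-ratio F pretest does not reject equality at
``f_alpha`` (default 0.05); otherwise the Welch unequal-variance test.
A gene's P value is the minimum over its single-gene probes, and its
direction (up/down in cases) is taken from the probe achieving that
minimum, so significance and direction rest on the same evidence.

Multi-gene and unannotated probes are excluded before testing. The
degenerate case of zero variance on both sides yields P=1 when the means
agree and P=0 when they differ, with a logged warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .types import ExpressionGroup, GeneTestResult, ProbeAnnotation

logger = logging.getLogger(__name__)

BRANCH_POOLED = "pooled"
BRANCH_WELCH = "welch"
BRANCH_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class ProbeTestResult:
    """Outcome of the gated t-test for one probe."""

    probe_id: str
    f_statistic: float
    f_p: float
    variance_equal: bool
    t_statistic: float
    t_df: float
    p_value: float
    mean_case: float
    mean_control: float
    branch: str


def _as_arrays(case_values, control_values) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(case_values, dtype=float))
    b = np.atleast_2d(np.asarray(control_values, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each subgroup needs at least 2 values")
    return a, b


def variance_ratio_test(case_values: Sequence[float],
                        control_values: Sequence[float]) -> tuple[float, float]:
    """Two-sided variance-ratio F test with the larger variance on top.

    Returns ``(f_statistic, f_p)`` where the statistic is
    max(s1², s2²)/min(s1², s2²) and the P value is twice the upper tail
    of the F distribution with the corresponding degrees of freedom,
    capped at 1. Symmetric in its arguments by construction.
    """
    a, b = _as_arrays(case_values, control_values)
    f, fp, _ = _variance_ratio_arrays(a, b)
    if not np.isfinite(f[0]):
        raise ValidationError("both sample variances are zero")
    return float(f[0]), float(fp[0])


def _variance_ratio_arrays(case: np.ndarray, control: np.ndarray):
    """Vectorized F pretest over probe rows; returns (F, p, both_zero mask)."""
    n1, n2 = case.shape[1], control.shape[1]
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    both_zero = (v1 == 0) & (v2 == 0)
    case_larger = v1 >= v2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(case_larger, v1 / np.where(v2 == 0, np.nan, v2),
                     v2 / np.where(v1 == 0, np.nan, v1))
    f = np.where(both_zero, np.nan, f)
    # one-sided variance with zero partner -> infinite ratio, p = 0
    one_zero = ((v1 == 0) ^ (v2 == 0))
    f = np.where(one_zero, np.inf, f)
    dfn = np.where(case_larger, n1 - 1, n2 - 1)
    dfd = np.where(case_larger, n2 - 1, n1 - 1)
    with np.errstate(invalid="ignore"):
        fp = np.minimum(2.0 * sps.f.sf(f, dfn, dfd), 1.0)
    fp = np.where(one_zero, 0.0, fp)
    fp = np.where(both_zero, np.nan, fp)
    return f, fp, both_zero


def t_test_pooled(case_values: Sequence[float],
                  control_values: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided pooled-variance two-sample t-test; df = n1 + n2 - 2."""
    a, b = _as_arrays(case_values, control_values)
    t, df, p = _t_pooled_arrays(a, b)
    return float(t[0]), float(df), float(p[0])


def _t_pooled_arrays(case: np.ndarray, control: np.ndarray):
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # identical constant samples: 0/0 -> define t=0, p=1
    zero_zero = (sp2 == 0) & (m1 == m2)
    t = np.where(zero_zero, 0.0, t)
    p = np.where(zero_zero, 1.0, p)
    p = np.where((sp2 == 0) & (m1 != m2), 0.0, p)
    return t, float(df), p


def t_test_welch(case_values: Sequence[float],
                 control_values: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    a, b = _as_arrays(case_values, control_values)
    t, df, p = _t_welch_arrays(a, b)
    return float(t[0]), float(df[0]), float(p[0])


def _t_welch_arrays(case: np.ndarray, control: np.ndarray):
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        # Satterthwaite df via the normalized weight w = (v1/n1)/se2, which
        # is scale-invariant and immune to underflow of se2**2
        w = np.where(se2 > 0, (v1 / n1) / se2, 0.5)
        df = 1.0 / (w ** 2 / (n1 - 1) + (1 - w) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero_zero = (se2 == 0) & (m1 == m2)
    t = np.where(zero_zero, 0.0, t)
    df = np.where(se2 == 0, n1 + n2 - 2, df)
    p = np.where(zero_zero, 1.0, p)
    p = np.where((se2 == 0) & (m1 != m2), 0.0, p)
    return t, df, p


def select_and_test(case_values: Sequence[float], control_values: Sequence[float],
                    f_alpha: float = 0.05, probe_id: str = "") -> ProbeTestResult:
    """Run the F pretest, then the pooled or Welch t-test accordingly.

    The boundary f_p == f_alpha is assigned to the equal-variance
    (pooled) branch. Zero variance on both sides short-circuits to the
    degenerate rule (P=1 if means equal, else P=0) with a warning.
    """
    a, b = _as_arrays(case_values, control_values)
    res = _test_probe_arrays(a, b, f_alpha)
    r = {k: v[0] for k, v in res.items()}
    if r["branch"] == BRANCH_DEGENERATE:
        logger.warning(
            "select_and_test: probe %r has zero variance in both subgroups; "
            "degenerate p=%g", probe_id, r["p_value"])
    return ProbeTestResult(
        probe_id=probe_id,
        f_statistic=float(r["f_statistic"]), f_p=float(r["f_p"]),
        variance_equal=bool(r["variance_equal"]),
        t_statistic=float(r["t_statistic"]), t_df=float(r["t_df"]),
        p_value=float(r["p_value"]),
        mean_case=float(r["mean_case"]), mean_control=float(r["mean_control"]),
        branch=str(r["branch"]),
    )


def _test_probe_arrays(case: np.ndarray, control: np.ndarray,
                       f_alpha: float) -> dict[str, np.ndarray]:
    """Vectorized gated test over probe rows of two matrices."""
    f, fp, both_zero = _variance_ratio_arrays(case, control)
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    t_p, df_p, p_p = _t_pooled_arrays(case, control)
    t_w, df_w, p_w = _t_welch_arrays(case, control)

    welch = np.where(both_zero, False, fp < f_alpha)
    t = np.where(welch, t_w, t_p)
    df = np.where(welch, df_w, df_p)
    p = np.where(welch, p_w, p_p)
    # degenerate rule overrides the branches
    t = np.where(both_zero, 0.0, t)
    df = np.where(both_zero, case.shape[1] + control.shape[1] - 2, df)
    p = np.where(both_zero, np.where(m1 == m2, 1.0, 0.0), p)
    branch = np.where(both_zero, BRANCH_DEGENERATE,
                      np.where(welch, BRANCH_WELCH, BRANCH_POOLED))
    return {
        "f_statistic": f, "f_p": fp, "variance_equal": ~welch & ~both_zero,
        "t_statistic": t, "t_df": df, "p_value": p,
        "mean_case": m1, "mean_control": m2, "branch": branch,
    }


def resolve_probes(annotation: ProbeAnnotation) -> dict[str, str]:
    """Keep only probes mapping to exactly one gene.

    Probes with no annotated gene or with more than one are dropped (the
    multi-gene probes are ambiguous evidence); drop counts are logged by
    reason. Returns probe_id -> gene_id.
    """
    kept: dict[str, str] = {}
    n_empty = n_multi = 0
    for probe, genes in annotation.mapping.items():
        if len(genes) == 1:
            kept[probe] = next(iter(genes))
        elif len(genes) == 0:
            n_empty += 1
        else:
            n_multi += 1
    if n_empty or n_multi:
        logger.info(
            "resolve_probes[%s]: kept %d probes; dropped %d unannotated, "
            "%d multi-gene", annotation.platform_id, len(kept), n_empty, n_multi)
    if not kept:
        logger.warning("resolve_probes[%s]: no single-gene probes retained",
                       annotation.platform_id)
    return kept


def test_group(group: ExpressionGroup, annotation: ProbeAnnotation,
               f_alpha: float = 0.05) -> list[GeneTestResult]:
    """Test every gene of one group and aggregate probes by minimum P.

    Only single-gene probes present in the matrix are tested. Per gene,
    the P value is the minimum over its probes and the direction the
    sign of (case mean - control mean) of the min-P probe (first such
    probe in matrix order on exact ties). Genes with no retained probe
    are absent from the result.
    """
    if annotation.platform_id != group.platform_id:
        raise ValidationError(
            f"annotation platform {annotation.platform_id!r} does not match "
            f"group platform {group.platform_id!r}")
    probe2gene = resolve_probes(annotation)
    rows = [i for i, p in enumerate(group.probe_ids) if p in probe2gene]
    if not rows:
        logger.warning("test_group[%s]: no retained probes", group.group_id)
        return []
    case = group.case_matrix()[rows]
    control = group.control_matrix()[rows]
    res = _test_probe_arrays(case, control, f_alpha)
    p_values = res["p_value"]
    mean_diff = res["mean_case"] - res["mean_control"]

    by_gene: dict[str, list[int]] = {}
    for local_idx, row in enumerate(rows):
        by_gene.setdefault(probe2gene[group.probe_ids[row]], []).append(local_idx)

    out: list[GeneTestResult] = []
    for gene_id in sorted(by_gene):
        idxs = by_gene[gene_id]
        pvals = p_values[idxs]
        best_local = idxs[int(np.argmin(pvals))]  # argmin is stable: first min
        diff = mean_diff[best_local]
        direction = "up" if diff > 0 else ("down" if diff < 0 else "flat")
        out.append(GeneTestResult(
            group_id=group.group_id, gene_id=gene_id,
            p_value=float(pvals.min()), direction=direction,
            n_probes_used=len(idxs)))
    return out


test_group.__test__ = False  # noqa - name collides with pytest collection


def test_group_table(group: ExpressionGroup, annotation: ProbeAnnotation,
                     f_alpha: float = 0.05):
    """Per-probe result table for one group (diagnostics / reports)."""
    import pandas as pd

    probe2gene = resolve_probes(annotation)
    rows = [i for i, p in enumerate(group.probe_ids) if p in probe2gene]
    res = _test_probe_arrays(group.case_matrix()[rows],
                             group.control_matrix()[rows], f_alpha)
    return pd.DataFrame({
        "group_id": group.group_id,
        "probe_id": [group.probe_ids[i] for i in rows],
        "gene_id": [probe2gene[group.probe_ids[i]] for i in rows],
        **{k: res[k] for k in ("f_statistic", "f_p", "t_statistic", "t_df",
                               "p_value", "mean_case", "mean_control", "branch")},
    })


test_group_table.__test__ = False  # noqa - pytest name collision
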