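import numpy as np
import pytest
from scipy import stats as sps

from genevote import (
    ProbeAnnotation,
    resolve_probes,
    select_and_test,
    t_test_pooled,
    t_test_welch,
    test_group,
    test_group_table,
    variance_ratio_test,
)

from .conftest import make_group

rng = np.random.default_rng(20240917)


def f_oracle(a, b):
    """Two-sided variance-ratio P via direct F CDF evaluation: put the
    larger sample variance on top and double the upper tail, capped at 1."""
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v1 >= v2:
        F, dfn, dfd = v1 / v2, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = v2 / v1, len(b) - 1, len(a) - 1
    return min(1.0, 2 * (1 - sps.f.cdf(F, dfn, dfd)))


class TestVarianceRatio:
    def test_equal_variances(self):
        f, fp = variance_ratio_test([1, 2, 3], [2, 3, 4])
        assert f == 1.0 and fp == 1.0

    def test_known_ratio_against_oracle(self):
        case, control = [1, 2, 3], [2, 4, 6, 8]
        f, fp = variance_ratio_test(case, control)
        assert f == pytest.approx(20 / 3)  # s2=6.667 over s2=1, df (3, 2)
        assert fp == pytest.approx(f_oracle(case, control), abs=1e-12)
        assert fp == pytest.approx(0.2664316559171049, abs=1e-10)

    def test_symmetric_in_arguments(self):
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert variance_ratio_test(a, b) == variance_ratio_test(b, a)

    def test_oracle_equivalence_random(self):
        for _ in range(100):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 8))
            b = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 8))
            _, fp = variance_ratio_test(a, b)
            assert fp == pytest.approx(f_oracle(a, b), abs=1e-10)


class TestTTests:
    def test_pooled_closed_form(self):
        t, df, p = t_test_pooled([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(3 / np.sqrt(2 / 3), 4))

    def test_identical_samples(self):
        t, _, p = t_test_pooled([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_pooled_matches_scipy_on_random_inputs(self):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0.5, 2, rng.integers(3, 9))
            t, df, p = t_test_pooled(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_matches_scipy_on_random_inputs(self):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0.5, 3, rng.integers(3, 9))
            t, df, p = t_test_welch(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_example_against_oracle(self):
        t, df, p = t_test_welch([0, 0, 1], [10, 20, 30])
        ref = sps.ttest_ind([0, 0, 1], [10, 20, 30], equal_var=False)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue), abs=1e-12)

    def test_welch_equals_pooled_t_for_balanced_equal_variance(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        tp, _, _ = t_test_pooled(a, b)
        tw, dfw, _ = t_test_welch(a, b)
        assert tw == pytest.approx(tp, abs=1e-12)
        assert dfw == pytest.approx(6.0)  # Satterthwaite df = pooled df here

    def test_scale_invariance(self):
        a, b = rng.normal(size=5), rng.normal(size=6)
        t1, _, p1 = t_test_welch(a, b)
        t2, _, p2 = t_test_welch(7.3 * a, 7.3 * b)
        assert (t1, p1) == pytest.approx((t2, p2), abs=1e-12)


class TestSelectAndTest:
    def test_unequal_variances_take_welch_branch(self):
        a = rng.normal(0, 0.05, 6)
        b = rng.normal(0, 10.0, 6)
        r = select_and_test(a, b, f_alpha=0.05)
        assert not r.variance_equal and r.branch == "welch"
        assert r.p_value == pytest.approx(t_test_welch(a, b)[2])

    def test_boundary_f_p_goes_pooled(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0, 8.0]
        _, fp = variance_ratio_test(a, b)
        r = select_and_test(a, b, f_alpha=fp)  # f_p == f_alpha exactly
        assert r.variance_equal and r.branch == "pooled"

    def test_degenerate_constant_samples(self):
        r = select_and_test([5, 5, 5], [5, 5, 5])
        assert r.branch == "degenerate" and r.p_value == 1.0
        r2 = select_and_test([5, 5, 5], [6, 6, 6])
        assert r2.branch == "degenerate" and r2.p_value == 0.0

    def test_branch_consistency_random(self):
        """Welch fires iff the two-sided F pretest p < f_alpha."""
        for _ in range(200):
            a = rng.normal(0, rng.uniform(0.3, 3), 5)
            b = rng.normal(0, rng.uniform(0.3, 3), 5)
            r = select_and_test(a, b, f_alpha=0.05)
            _, fp = variance_ratio_test(a, b)
            assert (r.branch == "welch") == (fp < 0.05)


class TestResolveProbes:
    def test_multi_and_unannotated_dropped(self):
        ann = ProbeAnnotation("P", {"p1": frozenset({"A"}),
                                    "p2": frozenset({"A", "B"}),
                                    "p3": frozenset()})
        assert resolve_probes(ann) == {"p1": "A"}

    def test_all_single_gene_identity(self):
        ann = ProbeAnnotation("P", {f"p{i}": frozenset({f"G{i}"}) for i in range(9)})
        assert resolve_probes(ann) == {f"p{i}": f"G{i}" for i in range(9)}

    def test_brute_force_over_random_annotations(self):
        genes = [f"G{i}" for i in range(6)]
        for _ in range(300):
            mapping = {f"p{j}": frozenset(
                rng.choice(genes, size=rng.integers(0, 4), replace=False))
                for j in range(rng.integers(1, 12))}
            ann = ProbeAnnotation("P", mapping)
            kept = resolve_probes(ann)
            expected = {p: next(iter(gs)) for p, gs in mapping.items()
                        if len(gs) == 1}
            assert kept == expected


class TestTestGroup:
    def test_gene_p_is_min_over_probes(self, tiny_group, tiny_annotation):
        results = {r.gene_id: r for r in test_group(tiny_group, tiny_annotation)}
        table = test_group_table(tiny_group, tiny_annotation)
        for gene, sub in table.groupby("gene_id"):
            assert results[gene].p_value == pytest.approx(sub["p_value"].min())
            assert results[gene].n_probes_used == len(sub)
            assert all(results[gene].p_value <= p for p in sub["p_value"])

    def test_single_probe_gene_passthrough(self):
        g = make_group(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)))
        ann = ProbeAnnotation("PLATX", {"p1": frozenset({"A"})})
        (res,) = test_group(g, ann)
        probe = select_and_test(g.case_matrix()[0], g.control_matrix()[0])
        assert res.p_value == pytest.approx(probe.p_value)

    def test_direction_follows_min_p_probe_sign(self):
        case = np.vstack([rng.normal(5, 1, 5), rng.normal(9, 0.1, 5)])
        ctrl = np.vstack([rng.normal(5, 1, 5), rng.normal(7, 0.1, 5)])
        g = make_group(case, ctrl)
        ann = ProbeAnnotation("PLATX", {"p1": frozenset({"A"}),
                                        "p2": frozenset({"A"})})
        (res,) = test_group(g, ann)
        assert res.direction == "up"  # the strong +2 probe dominates

    def test_label_exchange_flips_direction_fixes_p(self):
        case, ctrl = rng.normal(8, 1, (3, 5)), rng.normal(7, 1, (3, 5))
        ann = ProbeAnnotation("PLATX", {f"p{i+1}": frozenset({f"G{i}"})
                                        for i in range(3)})
        fwd = test_group(make_group(case, ctrl), ann)
        rev = test_group(make_group(ctrl, case), ann)
        flip = {"up": "down", "down": "up", "flat": "flat"}
        for a, b in zip(fwd, rev):
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
            assert b.direction == flip[a.direction]

    def test_planted_gene_attains_smallest_p(self):
        """One gene shifted +2 noise SDs (5v5, 3 probes/gene) should beat its
        null competitor's min-P in nearly every replicate."""
        local = np.random.default_rng(42)
        wins = 0
        ann = ProbeAnnotation("PLATX", {
            "p1": frozenset({"PLANTED"}), "p2": frozenset({"PLANTED"}),
            "p3": frozenset({"PLANTED"}), "p4": frozenset({"NULL"}),
            "p5": frozenset({"NULL"}), "p6": frozenset({"NULL"})})
        for _ in range(100):
            case = local.standard_normal((6, 5))
            ctrl = local.standard_normal((6, 5))
            case[:3] += 2.0
            res = {r.gene_id: r.p_value
                   for r in test_group(make_group(case, ctrl), ann)}
            wins += res["PLANTED"] < res["NULL"]
        assert wins >= 95

    def test_null_calibration_single_group(self):
        """Fraction of null genes at p <= 0.05 stays near 0.05."""
        local = np.random.default_rng(11)
        G = 2000
        g = make_group(local.normal(7, 1, (G, 5)), local.normal(7, 1, (G, 5)))
        ann = ProbeAnnotation("PLATX", {f"p{i+1}": frozenset({f"G{i}"})
                                        for i in range(G)})
        frac = np.mean([r.p_value <= 0.05 for r in test_group(g, ann)])
        tol = 3 * np.sqrt(0.05 * 0.95 / G)
        assert abs(frac - 0.05) < tol

    def test_platform_mismatch_rejected(self, tiny_group):
        ann = ProbeAnnotation("OTHER", {"p1": frozenset({"A"})})
        with pytest.raises(Exception, match="platform"):
            test_group(tiny_group, ann)
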