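import numpy as np
import pytest
from scipy import stats as sps

from genevote import (
    GeneTestResult,
    PercentageRecord,
    RankingConfig,
    ValidationError,
    adjust_pvalues,
    compare_adjustment,
    de_percentage,
    mean_percentage,
    rank_genes,
    select_candidates,
)
from genevote.types import format_percentage

rng = np.random.default_rng(5150)


def gres(gene, group, p, direction="up"):
    return GeneTestResult(group_id=group, gene_id=gene, p_value=p,
                          direction=direction, n_probes_used=1)


class TestDePercentage:
    def test_inclusive_boundary_count(self):
        rec = de_percentage([gres("A", "g1", 0.01), gres("A", "g2", 0.05),
                             gres("A", "g3", 0.20)])
        assert (rec.n_significant, rec.n_measured) == (2, 3)
        assert rec.percentage == pytest.approx(200 / 3)
        assert format_percentage(rec.percentage) == "66.7"

    def test_no_significant_groups(self):
        rec = de_percentage([gres("A", "g1", 0.5), gres("A", "g2", 0.9)])
        assert rec.percentage == 0.0

    def test_eleven_of_eighteen_renders_one_decimal(self):
        rec = PercentageRecord("A", n_measured=18, n_significant=11)
        assert format_percentage(rec.percentage) == "61.1"

    def test_duplicate_group_rejected(self):
        with pytest.raises(ValidationError, match="duplicate group"):
            de_percentage([gres("A", "g1", 0.1), gres("A", "g1", 0.2)])

    def test_monotone_in_p_threshold(self):
        ps = rng.uniform(size=12)
        results = [gres("A", f"g{i}", p) for i, p in enumerate(ps)]
        pcts = [de_percentage(results, RankingConfig(p_threshold=t)).percentage
                for t in (0.01, 0.05, 0.1, 0.5, 0.99)]
        assert pcts == sorted(pcts)

    def test_count_consistency_random(self):
        for _ in range(50):
            n = int(rng.integers(1, 25))
            results = [gres("A", f"g{i}", float(rng.uniform()))
                       for i in range(n)]
            rec = de_percentage(results)
            assert 0 <= rec.n_significant <= rec.n_measured
            assert rec.percentage == pytest.approx(
                100 * rec.n_significant / rec.n_measured)


class TestRanking:
    def test_descending_percentage(self):
        recs = [PercentageRecord("A", 10, 6), PercentageRecord("B", 4, 3)]
        assert [r.gene_id for r in rank_genes(recs)] == ["B", "A"]

    def test_tie_broken_by_more_groups_then_name(self):
        recs = [PercentageRecord("B", 6, 3), PercentageRecord("A", 20, 10),
                PercentageRecord("C", 6, 3)]
        ranked = rank_genes(recs)
        assert [r.gene_id for r in ranked] == ["A", "B", "C"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_order_independent_of_input_permutation(self):
        recs = []
        for i, n in enumerate(rng.integers(1, 20, 30)):
            recs.append(PercentageRecord(f"G{i}", int(n),
                                         int(rng.integers(0, n + 1))))
        base = [r.gene_id for r in rank_genes(list(recs))]
        for _ in range(5):
            perm = list(rng.permutation(len(recs)))
            assert [r.gene_id for r in rank_genes([recs[i] for i in perm])] == base

    def test_brute_force_sort_oracle(self):
        recs = []
        for i, n in enumerate(rng.integers(1, 10, 40)):
            recs.append(PercentageRecord(f"G{i}", int(n),
                                         int(rng.integers(0, n + 1))))
        ranked = rank_genes(list(recs))

        def beats(a, b):
            if a.percentage != b.percentage:
                return a.percentage > b.percentage
            if a.n_measured != b.n_measured:
                return a.n_measured > b.n_measured
            return a.gene_id < b.gene_id

        remaining, order = list(recs), []
        while remaining:  # O(n^2) selection by the pairwise rule
            best = remaining[0]
            for r in remaining[1:]:
                if beats(r, best):
                    best = r
            order.append(best)
            remaining.remove(best)
        assert [r.gene_id for r in ranked] == [r.gene_id for r in order]


class TestSelection:
    def _recs(self, pcts, n=10):
        return rank_genes([
            PercentageRecord(f"G{i}", n, round(p * n / 100))
            for i, p in enumerate(pcts)])

    def test_at_least_vs_strictly_greater(self):
        recs = [PercentageRecord("A", 20, 11), PercentageRecord("B", 20, 10),
                PercentageRecord("C", 100, 49)]
        ranked = rank_genes(recs)  # 55%, 50%, 49%
        at_least = select_candidates(ranked, RankingConfig(
            candidate_threshold_pct=50, threshold_mode="at_least"))
        strict = select_candidates(ranked, RankingConfig(
            candidate_threshold_pct=50, threshold_mode="strictly_greater"))
        assert [r.gene_id for r in at_least] == ["A", "B"]
        assert [r.gene_id for r in strict] == ["A"]

    def test_min_groups_excludes_regardless_of_percentage(self):
        ranked = rank_genes([PercentageRecord("HIGH", 9, 9),
                             PercentageRecord("LOW", 12, 8)])
        sel = select_candidates(ranked, RankingConfig(
            min_groups=10, candidate_threshold_pct=60))
        assert [r.gene_id for r in sel] == ["LOW"]


class TestMeanPercentage:
    def test_simple_mean(self):
        assert mean_percentage([PercentageRecord("A", 10, 0),
                                PercentageRecord("B", 10, 10)]) == 50.0

    def test_single_record(self):
        assert mean_percentage([PercentageRecord("A", 4, 1)]) == 25.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mean_percentage([])

    def test_null_binomial_expectation(self):
        """With per-group significance probability 0.05, the mean percentage
        over many genes concentrates at 5%."""
        local = np.random.default_rng(99)
        G, n_groups = 2000, 20
        recs = [PercentageRecord(f"G{i}", n_groups,
                                 int(local.binomial(n_groups, 0.05)))
                for i in range(G)]
        se = 100 * np.sqrt(0.05 * 0.95 / n_groups / G)
        assert abs(mean_percentage(recs) - 5.0) < 3 * se


class TestAdjustment:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03], "bonferroni") == [0.03]
        assert adjust_pvalues([0.03], "bh_fdr") == [0.03]

    def test_bonferroni_hand_computed(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bonferroni") == \
            pytest.approx([0.04, 0.08, 0.12, 0.16])

    def test_bh_hand_computed_step_up(self):
        # sorted p*m/i = [.04,.04,.04,.04]; step-up minima all 0.04
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr") == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])
        # and a non-flat case, by the step-up definition
        assert adjust_pvalues([0.001, 0.02, 0.9], "bh_fdr") == \
            pytest.approx([0.003, 0.03, 0.9])

    def test_bh_dominated_by_bonferroni(self):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            bh = adjust_pvalues(p, "bh_fdr")
            bf = adjust_pvalues(p, "bonferroni")
            assert all(b <= f + 1e-12 for b, f in zip(bh, bf))
            assert all(b >= raw - 1e-12 for b, raw in zip(bh, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5], "bonferroni")


class TestCompareAdjustment:
    def test_null_group_fdr_mostly_empty(self):
        local = np.random.default_rng(13)
        zero_fdr = 0
        for rep in range(20):
            counts = compare_adjustment(
                {"g": local.uniform(size=2000)}, alpha=0.05)[0]
            zero_fdr += counts.fdr_significant == 0
        assert zero_fdr >= 15  # BH under a global null rarely rejects

    def test_planted_signals_survive_all_methods(self):
        p = np.concatenate([np.full(10, 1e-8), rng.uniform(0.2, 1, 990)])
        (c,) = compare_adjustment({"g": p}, alpha=0.05)
        assert c.bonferroni_significant == 10
        assert c.fdr_significant == 10
        assert c.raw_significant == 10

    def test_empty_group_zeros(self):
        (c,) = compare_adjustment({"g": []})
        assert (c.raw_significant, c.fdr_significant, c.bonferroni_significant) \
            == (0, 0, 0)

    def test_ordering_raw_fdr_bonferroni(self):
        groups = {f"g{i}": rng.uniform(size=int(rng.integers(1, 200)))
                  for i in range(20)}
        for c in compare_adjustment(groups):
            assert c.raw_significant >= c.fdr_significant >= c.bonferroni_significant


def test_null_vote_counts_binomial_chi_square():
    """Pooled null vote counts follow Binomial(n_measured, 0.05): a
    goodness-of-fit test on simulated single-probe nulls does not reject."""
    from genevote import SimulationConfig, simulate_studies, test_group
    from genevote import percentages_from_results

    cfg = SimulationConfig(n_groups=21, n_genes=1500, n_planted=0,
                           probes_per_gene=(1, 1), multi_gene_probe_fraction=0.0,
                           platform_gene_dropout=0.0, seed=77)
    groups, anns, _ = simulate_studies(cfg)
    results = [r for g, a in zip(groups, anns) for r in test_group(g, a)]
    recs = percentages_from_results(results)
    ks = np.array([r.n_significant for r in recs])
    n = 21
    pmf = sps.binom.pmf(np.arange(n + 1), n, 0.05)
    # pool the tail so expected counts stay above ~5
    edges = [0, 1, 2, 3]
    obs = [np.sum(ks == e) for e in edges] + [np.sum(ks > edges[-1])]
    exp = [pmf[e] * len(ks) for e in edges] + [pmf[edges[-1] + 1:].sum() * len(ks)]
    stat, p = sps.chisquare(obs, exp)
    assert p > 0.01
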