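import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from omicstrata import subtype_characterization as sc
from omicstrata._stats import bh_adjust
from omicstrata.errors import InvalidInputError
from omicstrata.matrix import SubtypeAssignment

from conftest import make_matrix


def oracle_exact_p(table):
    """Independent enumeration oracle using exact rational arithmetic."""
    t = np.asarray(table, dtype=int)
    colsums = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    denom = math.comb(n, r1)

    def prob(row):
        num = 1
        for a, c in zip(row, colsums):
            num *= math.comb(int(c), int(a))
        return Fraction(num, denom)

    p_obs = prob(t[0])
    total = Fraction(0)
    ranges = [range(int(c) + 1) for c in colsums]
    for row in itertools.product(*ranges):
        if sum(row) != r1:
            continue
        pr = prob(row)
        if pr <= p_obs:
            total += pr
    return float(total)


class TestExactTests:
    def test_identical_distributions_p1(self):
        assert sc.exact_rx_c_p([[5, 3, 2], [5, 3, 2]]) == pytest.approx(
            oracle_exact_p([[5, 3, 2], [5, 3, 2]]), abs=1e-10)

    def test_2x2_collapse(self):
        assert sc.exact_rx_c_p([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_2x3_margins_le_12_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 7, size=(2, 3))
            if t.sum() > 0 and t.sum(axis=0).max() <= 12 and t.sum(axis=1).max() <= 12:
                break
        assert sc.exact_rx_c_p(t) == pytest.approx(oracle_exact_p(t), abs=1e-10)

    def test_monte_carlo_close_to_enumeration(self):
        t = [[30, 50, 40], [45, 35, 50]]
        p_enum = sc.exact_rx_c_p(t)
        p_mc = sc.exact_rx_c_p(t, seed=1, enumeration_limit=10)
        assert abs(p_mc - p_enum) < 0.01


class TestFisherStateTest:
    def make_states(self):
        data = [["Gain"] * 10 + ["Normal"] * 10,
                ["Gain"] * 5 + ["Loss"] * 5 + ["Normal"] * 10]
        return pd.DataFrame(data, index=["f1", "f2"],
                            columns=[f"s{i}" for i in range(20)])

    def test_identical_groups_p1(self):
        states = pd.DataFrame([["Gain"] * 5 + ["Loss"] * 5], index=["f"],
                              columns=[f"s{i}" for i in range(10)])
        res = sc.fisher_state_test(states, [f"s{i}" for i in (0, 1, 5, 6)],
                                   [f"s{i}" for i in (2, 3, 7, 8)])
        assert res[0].p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.fisher_state_test(self.make_states(), [], ["s0"])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.fisher_state_test(self.make_states(), ["s0"], ["s0", "s1"])

    def test_fdr_attached(self):
        states = self.make_states()
        res = sc.fisher_state_test(states, [f"s{i}" for i in range(10)],
                                   [f"s{i}" for i in range(10, 20)])
        assert all(r.fdr >= r.p - 1e-12 for r in res)


class TestNBDifferentialExpression:
    def test_duplicated_columns_zero_lfc(self, rng):
        base = rng.poisson(50, size=(30, 6)).astype(float) + 1
        counts = make_matrix(np.hstack([base, base]), kind="counts",
                             samples=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        res = sc.nb_differential_expression(counts, [f"a{i}" for i in range(6)],
                                            [f"b{i}" for i in range(6)])
        assert np.allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_noise_free_fourfold(self):
        a = np.full((3, 4), 100.0)
        b = a.copy()
        b[0] = 400.0  # planted 4-fold gene with equal size factors
        counts = make_matrix(np.hstack([a, b]), kind="counts",
                             samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        res = sc.nb_differential_expression(counts, [f"a{i}" for i in range(4)],
                                            [f"b{i}" for i in range(4)])
        assert res.loc[0, "log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_gene_skipped(self, rng):
        vals = rng.poisson(20, size=(5, 8)).astype(float) + 1
        vals[2] = 0.0
        counts = make_matrix(vals, kind="counts",
                             samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="all-zero"):
            res = sc.nb_differential_expression(counts, [f"a{i}" for i in range(4)],
                                                [f"b{i}" for i in range(4)])
        assert "g2" not in set(res["gene"])

    def test_size_factors_median_of_ratios(self, rng):
        base = rng.poisson(100, size=(200, 4)).astype(float) + 1
        scaled = base * np.array([1.0, 2.0, 0.5, 1.0])
        sf = sc.median_of_ratios_size_factors(scaled)
        assert sf / sf[0] == pytest.approx([1.0, 2.0, 0.5, 1.0], rel=0.05)


class TestMutationTest:
    def groups(self):
        return [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)]

    def test_fully_separated_gene(self):
        ga, gb = self.groups()
        muts = pd.DataFrame({"Hugo_Symbol": ["G"] * 10,
                             "Tumor_Sample_Barcode": ga,
                             "Variant_Classification": ["Missense_Mutation"] * 10})
        res = sc.mutation_frequency_test(muts, ga, gb)
        assert res.loc[0, "p"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_equal_counts_p1(self):
        ga, gb = self.groups()
        muts = pd.DataFrame({"Hugo_Symbol": ["G"] * 6,
                             "Tumor_Sample_Barcode": ga[:3] + gb[:3],
                             "Variant_Classification": ["Missense_Mutation"] * 6})
        res = sc.mutation_frequency_test(muts, ga, gb)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_table(self):
        ga, gb = self.groups()
        empty = pd.DataFrame(columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                      "Variant_Classification"])
        assert len(sc.mutation_frequency_test(empty, ga, gb)) == 0


class TestKMLogrank:
    def clinical(self, times, events):
        return pd.DataFrame({"OS_time": times, "OS_event": events},
                            index=[f"s{i}" for i in range(len(times))])

    def test_identical_groups_null(self):
        clin = self.clinical([1, 2, 3, 4, 1, 2, 3, 4], [1] * 8)
        a = SubtypeAssignment("x", {f"s{i}": i // 4 for i in range(8)})
        pairwise, global_p, summary, tables = sc.km_logrank(clin, a)
        assert global_p == pytest.approx(1.0)
        assert summary["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_six_subject_hand_computed_oracle(self):
        # times 1..6, all events, groups ABABAB; O-E tabulated by hand:
        # risk sets 6,5,4,3,2,1; A at risk 3,2,2,1,1,0; A events at t=1,3,5
        # E_A = 3/6 + 2/5 + 2/4 + 1/3 + 1/2 + 0 = 2.2333...,  O_A = 3
        # V = sum of n1*n2*d*(n-d)/(n^2*(n-1)) with d=1 -> n1*n2/n^2
        clin = self.clinical([1, 2, 3, 4, 5, 6], [1] * 6)
        a = SubtypeAssignment("x", {f"s{i}": i % 2 for i in range(6)})
        e_a = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2
        v = (3 * 3) / 36 + (2 * 3) / 25 + (2 * 2) / 16 + (1 * 2) / 9 + (1 * 1) / 4
        expected_stat = (3 - e_a) ** 2 / v
        _, global_p, summary, _ = sc.km_logrank(clin, a)
        assert summary["statistic"].iloc[0] == pytest.approx(expected_stat, abs=1e-10)
        # cross-check the internal fast implementation too
        from omicstrata._stats import logrank_test
        stat, p, _ = logrank_test(np.arange(1, 7), np.ones(6, dtype=int),
                                  np.arange(6) % 2)
        assert stat == pytest.approx(expected_stat, abs=1e-10)
        assert p == pytest.approx(global_p, abs=1e-10)

    def test_single_group_rejected(self):
        clin = self.clinical([1, 2, 3], [1, 1, 1])
        a = SubtypeAssignment("x", {f"s{i}": 0 for i in range(3)})
        with pytest.raises(InvalidInputError):
            sc.km_logrank(clin, a)

    def test_global_equals_pairwise_for_two_groups(self, rng):
        n = 40
        clin = self.clinical(rng.exponential(5, n) + 0.01, rng.integers(0, 2, n))
        a = SubtypeAssignment("x", {f"s{i}": i % 2 for i in range(n)})
        pairwise, global_p, _, _ = sc.km_logrank(clin, a)
        assert pairwise["p"].iloc[0] == pytest.approx(global_p, abs=1e-9)

    def test_km_tables_are_step_functions(self, rng):
        n = 30
        clin = self.clinical(rng.exponential(5, n) + 0.01, rng.integers(0, 2, n))
        a = SubtypeAssignment("x", {f"s{i}": i % 2 for i in range(n)})
        _, _, _, tables = sc.km_logrank(clin, a)
        for tbl in tables.values():
            surv = tbl["survival"].to_numpy()
            assert np.all(np.diff(surv) <= 1e-12)
            assert surv[0] == pytest.approx(1.0)


class TestMarkerStratification:
    def test_tertiles_balanced(self, rng):
        expr = make_matrix(rng.uniform(1, 9, size=(1, 9)), kind="fpkm", genes=["g"])
        clin = pd.DataFrame({"OS_time": rng.exponential(5, 9) + 0.1,
                             "OS_event": np.ones(9, dtype=int)}, index=expr.samples)
        strat = sc.stratify_marker_expression(expr, "g", clin)
        sizes = pd.Series(strat.tiers).value_counts()
        assert set(sizes) == {3}

    def test_identical_survival_null(self):
        vals = np.arange(1.0, 10.0)[None, :]
        expr = make_matrix(vals, kind="fpkm", genes=["g"])
        clin = pd.DataFrame({"OS_time": np.tile([2.0, 3.0, 4.0], 3),
                             "OS_event": np.ones(9, dtype=int)}, index=expr.samples)
        # arrange survival identical across tiers by expression order
        strat = sc.stratify_marker_expression(expr, "g", clin)
        assert strat.global_p == pytest.approx(1.0)

    def test_planted_monotone_hazard_adverse(self):
        rng = np.random.default_rng(0)
        n = 120
        expr_vals = np.sort(rng.uniform(0, 10, n))[None, :]
        expr = make_matrix(expr_vals, kind="fpkm", genes=["g"])
        tier = np.repeat([0, 1, 2], n // 3)
        hazard = np.array([1.0, 2.0, 4.0])[tier] * 0.05
        t = rng.exponential(1 / hazard)
        clin = pd.DataFrame({"OS_time": np.maximum(t, 1e-3),
                             "OS_event": np.ones(n, dtype=int)}, index=expr.samples)
        strat = sc.stratify_marker_expression(expr, "g", clin)
        assert strat.direction == "adverse"
        assert strat.global_p < 0.05

    def test_heavy_ties_fallback(self):
        expr = make_matrix(np.ones((1, 9)), kind="fpkm", genes=["g"])
        clin = pd.DataFrame({"OS_time": np.arange(1.0, 10.0),
                             "OS_event": np.ones(9, dtype=int)}, index=expr.samples)
        with pytest.warns(UserWarning, match="ties"):
            strat = sc.stratify_marker_expression(expr, "g", clin, seed=1)
        assert sorted(pd.Series(strat.tiers).value_counts()) == [3, 3, 3]


class TestScoreComparison:
    def test_identical_distributions(self):
        scores = pd.Series(np.tile([1.0, 2.0, 3.0], 2), index=[f"s{i}" for i in range(6)])
        a = SubtypeAssignment("x", {f"s{i}": i // 3 for i in range(6)})
        _, kw_p, _ = sc.compare_scores_across_subtypes(scores, a)
        assert kw_p > 0.9

    def test_exact_3v3_matches_enumeration(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        scores = pd.Series(vals, index=[f"s{i}" for i in range(6)])
        a = SubtypeAssignment("x", {f"s{i}": i // 3 for i in range(6)})
        pairwise, _, _ = sc.compare_scores_across_subtypes(scores, a)
        # exhaustive enumeration over all C(6,3)=20 splits of the rank-sum statistic
        ranks = np.argsort(np.argsort(vals)) + 1
        obs = ranks[:3].sum()
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            s = ranks[list(combo)].sum()
            total += 1
            if abs(s - 10.5) >= abs(obs - 10.5) - 1e-12:
                count += 1
        assert pairwise["p"].iloc[0] == pytest.approx(count / total, rel=1e-9)

    def test_shifted_group_detected(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(10, 1, 12)])
        scores = pd.Series(vals, index=[f"s{i}" for i in range(24)])
        a = SubtypeAssignment("x", {f"s{i}": i // 12 for i in range(24)})
        _, kw_p, medians = sc.compare_scores_across_subtypes(scores, a)
        assert kw_p < 0.05
        assert medians["median"].iloc[1] > medians["median"].iloc[0]

    def test_constant_scores_warn(self):
        scores = pd.Series(np.ones(8), index=[f"s{i}" for i in range(8)])
        a = SubtypeAssignment("x", {f"s{i}": i // 4 for i in range(8)})
        with pytest.warns(UserWarning, match="constant"):
            _, kw_p, _ = sc.compare_scores_across_subtypes(scores, a)
        assert kw_p == 1.0


class TestEnrichment:
    def test_perfect_enrichment(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = sc.hypergeometric_enrichment(term, universe, {"T": term})
        assert res.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_disjoint_hits_p1(self):
        universe = {f"g{i}" for i in range(20)}
        res = sc.hypergeometric_enrichment({"g10", "g11"}, universe,
                                           {"T": {"g0", "g1", "g2"}})
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_term_equals_universe_p1(self):
        universe = {f"g{i}" for i in range(10)}
        res = sc.hypergeometric_enrichment({"g0", "g1"}, universe, {"T": set(universe)})
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.hypergeometric_enrichment(set(), set(), {})


class TestStateCalling:
    def test_cnv_states(self):
        m = make_matrix([[0.31, -0.31, 0.0]], kind="cnv_logratio")
        states = sc.call_states(m)
        assert list(states.iloc[0]) == ["Gain", "Loss", "Normal"]

    def test_beta_states(self):
        m = make_matrix([[0.85, 0.15, 0.5]], kind="beta")
        states = sc.call_states(m)
        assert list(states.iloc[0]) == ["HyperMethy", "HypoMethy", "Normal"]


def test_bh_monotone(rng):
    p = rng.uniform(size=200)
    fdr = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(fdr[order]) >= -1e-12)
    assert np.all(fdr >= p - 1e-12)
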