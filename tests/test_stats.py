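"""Contingency machinery: expected counts, chi-square, Fisher, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import PRINTED_GROUP_TABLES, PRINTED_PAIR_TABLES, printed_round_equal
from palinsig.stats import (
    categorical_association,
    chi_square_test,
    cooccurrence_table,
    expected_counts,
    fisher_exact_two_sided,
    pairwise_cooccurrence,
    rank_group_test,
    select_and_run_test,
)


def fisher_by_enumeration(table) -> float:
    """Independent oracle: enumerate every table with the observed
    margins, sum hypergeometric point probabilities <= the observed."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t.sum(axis=1)
    c1, _c2 = t.sum(axis=0)
    n = t.sum()
    obs = sps.hypergeom.pmf(t[0, 0], n, r1, c1)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = sps.hypergeom.pmf(a, n, r1, c1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestExpectedCounts:
    def test_hand_arithmetic(self):
        e = expected_counts([[70, 21], [3, 9]])
        assert e[1, 1] == pytest.approx(12 * 30 / 103)
        assert e.min() == pytest.approx(3.4951, abs=1e-4)

    def test_uniform_table(self):
        assert np.allclose(expected_counts([[10, 10], [10, 10]]), 10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            expected_counts([[0, 0], [5, 5]])


class TestChiSquare:
    def test_plain_matches_printed_value(self):
        res = chi_square_test([[45, 28], [11, 19]])
        assert res.test_used == "chi2" and res.df == 1
        assert printed_round_equal(res.p_value, 0.021)

    def test_yates_matches_printed_value(self):
        res = chi_square_test([[70, 21], [3, 9]], yates=True)
        assert res.test_used == "chi2_yates"
        assert printed_round_equal(res.p_value, 0.0007)

    def test_independence_gives_p_one(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p_value == 1

    def test_plain_stat_at_least_yates_stat(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2))
            plain = chi_square_test(t)
            corr = chi_square_test(t, yates=True)
            assert plain.statistic >= corr.statistic - 1e-12
            assert plain.p_value <= corr.p_value + 1e-12

    def test_yates_floor_cannot_overshoot(self):
        # deviations |O-E| < 0.5 everywhere: corrected statistic is 0
        res = chi_square_test([[10, 10], [10, 11]], yates=True)
        assert res.statistic == 0 and res.p_value == 1

    def test_yates_only_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            chi_square_test([[5, 5, 5], [5, 5, 5]], yates=True)

    def test_df2_closed_form(self):
        # for df = 2 the chi-square upper tail is exp(-x/2)
        res = chi_square_test([[36, 40, 10], [3, 6, 8]])
        assert res.df == 2
        assert res.p_value == pytest.approx(np.exp(-res.statistic / 2), rel=1e-12)

    def test_permutation_invariance(self):
        t = np.array([[45, 28], [11, 19]])
        base = chi_square_test(t).p_value
        for rows in itertools.permutations(range(2)):
            for cols in itertools.permutations(range(2)):
                assert chi_square_test(t[list(rows)][:, list(cols)]).p_value == pytest.approx(base)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 0], [0, 2]], 1 / 3),
            ([[0, 5], [5, 0]], 2 / 252),
            ([[88, 7], [3, 5]], 0.0004),
        ],
    )
    def test_examples(self, table, expected):
        p = fisher_exact_two_sided(table).p_value
        if expected in (1 / 3, 2 / 252):
            assert p == pytest.approx(expected, rel=1e-9)
        else:
            assert printed_round_equal(p, expected)

    def test_zero_margin_degenerate(self):
        res = fisher_exact_two_sided([[0, 0], [3, 4]])
        assert res.degenerate and res.p_value == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            t = rng.integers(0, 20, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_two_sided(t).p_value == pytest.approx(
                fisher_by_enumeration(t), rel=1e-8)


class TestSelection:
    @pytest.mark.parametrize("pair,entry", list(PRINTED_PAIR_TABLES.items()),
                             ids=["x".join(p) for p in PRINTED_PAIR_TABLES])
    def test_reproduces_every_printed_cell(self, pair, entry):
        table, printed_p, expected_test = entry
        res = select_and_run_test(table)
        assert res.test_used == expected_test
        assert printed_round_equal(res.p_value, printed_p)

    def test_thresholds_configurable(self):
        t = [[45, 28], [11, 19]]
        assert select_and_run_test(t).test_used == "chi2"
        assert select_and_run_test(t, plain_min_expected=50).test_used == "chi2_yates"
        assert select_and_run_test(t, plain_min_expected=50,
                                   yates_min_expected=50).test_used == "fisher"

    def test_degenerate_table_flagged(self):
        res = select_and_run_test([[5, 5], [0, 0]])
        assert res.degenerate and res.p_value == 1.0


class TestPairwiseCooccurrence:
    def test_table3_layout_on_pair_matrices(self, fixture_matrix):
        res = pairwise_cooccurrence(fixture_matrix, ["GPR126", "PLEKHS1"])
        assert len(res) == 1
        row = res.iloc[0]
        # fixture overlap: GPR126 0..46, PLEKHS1 34..63 -> joint 13
        assert (row.a_m_b_m, row.a_m_b_wt, row.a_wt_b_m, row.a_wt_b_wt) == (13, 34, 17, 39)
        assert row.test_used in {"chi2", "chi2_yates", "fisher"}

    def test_constant_locus_flagged_untestable(self, fixture_matrix):
        frame = fixture_matrix.to_frame()
        import palinsig.cohort as cm
        calls = frame.to_numpy().copy()
        calls[:, 0] = 0  # make first locus constant
        mat = cm.CohortMatrix(fixture_matrix.samples, fixture_matrix.registry, calls)
        res = pairwise_cooccurrence(mat, [mat.locus_ids[0], mat.locus_ids[1]])
        assert bool(res.iloc[0].untestable) and np.isnan(res.iloc[0].p_value)

    def test_bonferroni_column_present_but_raw_p_reported(self, fixture_matrix):
        res = pairwise_cooccurrence(fixture_matrix,
                                    ["GPR126", "PLEKHS1", "Intron ADM"])
        assert {"p_value", "p_bonferroni"} <= set(res.columns)
        assert (res.p_bonferroni >= res.p_value - 1e-12).all()

    def test_needs_two_loci(self, fixture_matrix):
        with pytest.raises(ValueError, match="two loci"):
            pairwise_cooccurrence(fixture_matrix, ["GPR126"])


class TestCategoricalAssociation:
    @pytest.mark.parametrize("cov,entry", list(PRINTED_GROUP_TABLES.items()))
    def test_printed_group_tables(self, cov, entry):
        table, printed_p = entry
        res = chi_square_test(table)
        assert res.df == 2
        assert printed_round_equal(res.p_value, printed_p)

    def test_pairwise_deletion_of_missing(self):
        groups = pd.Series(["G1", "G1", "G2", "G2", "G3", "G3"] * 10)
        cov = pd.Series((["a", "b"] * 30))
        cov.iloc[:6] = None
        res = categorical_association(groups, cov)
        assert res.test_used == "chi2"

    def test_constant_covariate_rejected(self):
        groups = pd.Series(["G1", "G2", "G3"] * 10)
        with pytest.raises(ValueError, match="levels"):
            categorical_association(groups, pd.Series(["x"] * 30))


class TestRankGroupTest:
    def test_three_groups_use_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        stat, p, test = rank_group_test(rng.standard_normal(90),
                                        ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        assert test == "kruskalwallis" and 0 <= p <= 1

    def test_two_groups_use_mann_whitney(self):
        rng = np.random.default_rng(0)
        stat, p, test = rank_group_test(rng.standard_normal(40), ["a", "b"] * 20)
        assert test == "mannwhitney" and 0 <= p <= 1

    def test_constant_values_degenerate(self):
        stat, p, test = rank_group_test([1.0] * 30, ["a", "b", "c"] * 10)
        assert test == "degenerate" and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            rank_group_test([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_detects_large_shift(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.standard_normal(50), rng.standard_normal(50) + 2])
        _, p, _ = rank_group_test(v, ["a"] * 50 + ["b"] * 50)
        assert p < 1e-6
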