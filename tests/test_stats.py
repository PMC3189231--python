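"""Exact contingency statistics and the rank-sum comparison."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from pedcnvseg.stats import (
    ContingencyTable2x2,
    carrier_frequency,
    carrier_spouse_comparison,
    fisher_exact_two_sided,
    kruskal_wallis,
)
from pedcnvseg.simulate import generate_pedigree

from oracles import fisher_p_by_enumeration


class TestFisher:
    def test_printed_carrier_spouse_table(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(12, 8, 6, 14))
        assert round(p, 3) == 0.111

    def test_balanced_table_by_enumeration(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5))
        assert math.isclose(p, float(fisher_p_by_enumeration(5, 5, 5, 5)), rel_tol=1e-9)

    def test_perfect_separation(self):
        # margins (5,5)/(5,5): only the two extreme tables are as improbable
        p = fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5))
        assert math.isclose(p, 2 / 252, rel_tol=1e-9)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 0, 4, 0)) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_invariant_under_row_and_column_swaps(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            for cells in ((c, d, a, b), (b, a, d, c), (a, c, b, d)):
                assert math.isclose(
                    p, fisher_exact_two_sided(ContingencyTable2x2(*cells)), rel_tol=1e-9
                )

    def test_exhaustive_scan_all_tables_up_to_n25(self):
        """Every 2x2 table with total <= 25 against the exact-fraction
        enumeration oracle (the full scan to 40 runs in the acceptance
        suite)."""
        from oracles import assert_fisher_matches_enumeration

        assert assert_fisher_matches_enumeration(25) > 20000

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if a + b + c + d == 0:
                continue
            _, p_ref = sps.fisher_exact([[a, b], [c, d]])
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            assert math.isclose(p, p_ref, rel_tol=1e-6)


class TestKruskalWallis:
    def test_complete_ties(self):
        h, p = kruskal_wallis([[3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert round(h, 3) == 3.857

    def test_rank_invariance_under_shift(self):
        h1, p1 = kruskal_wallis([[1, 2, 9], [4, 5, 6], [7, 8, 3]])
        h2, p2 = kruskal_wallis([[101, 102, 109], [104, 105, 106], [107, 108, 103]])
        assert h1 == h2 and p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_exact_permutation_matches_statistic_and_bounds(self):
        h_exact, p_exact = kruskal_wallis([[1, 2, 3], [4, 5, 6]], exact=True)
        h_chi2, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert math.isclose(h_exact, h_chi2, rel_tol=1e-12)
        # 6!/(3!3!) = 20 distinct splits; only the two extreme ones reach H
        assert math.isclose(p_exact, 2 / 20, rel_tol=1e-9)

    def test_null_p_values_uniform(self):
        """Under exchangeability the chi-square p-values are uniform
        (Kolmogorov-Smirnov at alpha = 0.01, seeded)."""
        rng = np.random.default_rng(2026)
        pvals = []
        for _ in range(2000):
            g = rng.normal(size=(3, 25))
            _, p = kruskal_wallis([g[0], g[1], g[2]])
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCarrierFrequency:
    @pytest.mark.parametrize("k,n,display", [(9, 727, 0.012), (5, 727, 0.007), (0, 727, 0.0)])
    def test_printed_display_values(self, k, n, display):
        f = carrier_frequency(k, n)
        assert f.exact == Fraction(k, n)
        assert f.display == display

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency(0, 0)

    def test_threshold_comparison_uses_exact_fraction(self):
        # 11/727 = 0.0151...: above 1.5% despite displaying 0.015
        f = carrier_frequency(11, 727)
        assert f.display == 0.015 and f.exact > Fraction(15, 1000)


class TestCarrierSpouseComparison:
    def test_no_pairs_is_an_error(self):
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        with pytest.raises(ValueError, match="no comparable"):
            carrier_spouse_comparison({"F": ped}, [], {})

    def test_everyone_diagnosed_gives_p_one(self, fixture_data, fixture_result):
        clinical = {
            iid: ["label"]
            for ped in fixture_data.peds.values()
            for iid in ped.members
        }
        _, p, _ = carrier_spouse_comparison(
            fixture_data.peds, fixture_result.retained, clinical
        )
        assert p == 1.0

    def test_carrier_carrier_couples_excluded(self, fixture_data, fixture_result):
        # make one spouse a carrier by adding them to a retained candidate
        retained = fixture_result.retained
        cand = next(c for c in retained if c.family_id == "7745")
        cand = type(cand)(**{**cand.__dict__})
        cand.married_in_carriers = list(cand.married_in_carriers) + ["7745_s1"]
        others = [c for c in retained if c.family_id != "7745"]
        table, _, diag = carrier_spouse_comparison(
            fixture_data.peds, others + [cand], fixture_data.clinical
        )
        assert ("7745_b1", "7745_s1") in diag["excluded_pairs"]
        assert table.total < 40
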