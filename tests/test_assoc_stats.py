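import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from linedrop.assoc import (allele_frequencies, association_report,
                            chi2_test, fisher_exact_2x2,
                            haplotype_association, hwe_test,
                            odds_ratio_woolf, round_half_up)
from linedrop.cohort import HaplotypeCountTable, load_study_counts


def enumerate_fisher_p(a, b, c, d):
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities
    of all tables with the observed margins that are no more likely."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestAlleleFrequencies:
    @pytest.mark.parametrize("counts,f_alt", [
        ((54, 88, 25), 138 / 334),   # control Ins frequency 0.413
        ((50, 56, 16), 88 / 244),    # case 148M frequency 0.361
        ((7, 0, 0), 0.0),
    ])
    def test_alt_frequency(self, counts, f_alt):
        f_ref, got = allele_frequencies(counts)
        assert got == pytest.approx(f_alt)
        assert f_ref + got == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies((0, 0, 0))


class TestHwe:
    def test_control_i148m_in_equilibrium(self):
        res = hwe_test((94, 61, 12))
        assert res.chi2 == pytest.approx(0.233, abs=0.005)
        assert res.p > 0.05
        assert sum(res.expected) == pytest.approx(167)

    def test_exact_proportions_give_zero(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_no_heterozygotes_extreme(self):
        # q = 0.5, zero hets: chi2 collapses to n
        res = hwe_test((50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-6

    def test_monomorphic_is_trivial_equilibrium(self):
        res = hwe_test((42, 0, 0))
        assert (res.chi2, res.p) == (0.0, 1.0)


class TestChi2:
    def test_allele_table_reproduces_published_p(self):
        _, df, p = chi2_test(((156, 88), (249, 85)))
        assert df == 1
        assert round_half_up(p, 3) == 0.006

    def test_genotype_table_reproduces_published_p(self):
        _, df, p = chi2_test(((45, 60, 17), (54, 88, 25)))
        assert df == 2
        assert round_half_up(p, 3) == 0.723

    def test_identical_rows_give_p_one(self):
        chi2, _, p = chi2_test(((10, 20, 30), (10, 20, 30)))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_test(((0, 5), (0, 7)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_2x2_matches_closed_form(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        expected = (n * (a * d - b * c) ** 2
                    / ((a + b) * (c + d) * (a + c) * (b + d)))
        chi2, _, _ = chi2_test(((a, b), (c, d)))
        assert chi2 == pytest.approx(expected, rel=1e-9)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        (((3, 1), (1, 3)), 34 / 70),
        (((5, 0), (0, 5)), 2 / 252),
        (((2, 2), (2, 2)), 1.0),
    ])
    def test_known_enumerations(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_brute_force_enumeration(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact_2x2(((a, b), (c, d))) == pytest.approx(
            enumerate_fisher_p(a, b, c, d), rel=1e-9)


class TestOddsRatioWoolf:
    def test_i148m_allele_table(self):
        res = odds_ratio_woolf(((156, 88), (249, 85)))
        assert res.or_str() == "0.61 [0.42-0.87]"

    def test_wt148m_haplotype_table(self):
        res = odds_ratio_woolf(((88, 156), (85, 249)))
        assert res.or_str() == "1.65 [1.15-2.37]"

    def test_balanced_table_symmetric_about_one(self):
        res = odds_ratio_woolf(((10, 10), (10, 10)))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_zero_cell_is_undefined_not_corrected(self):
        res = odds_ratio_woolf(((0, 244), (0, 334)))
        assert res.odds_ratio is None and res.ci_low is None
        assert res.or_str() == "na"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_row_swap_inverts_or_and_preserves_p(self, cells):
        a, b, c, d = cells
        r1 = odds_ratio_woolf(((a, b), (c, d)))
        r2 = odds_ratio_woolf(((c, d), (a, b)))
        assert r2.odds_ratio == pytest.approx(1 / r1.odds_ratio)
        assert r2.p_chi2 == pytest.approx(r1.p_chi2)
        assert r2.p_fisher == pytest.approx(r1.p_fisher)
        assert r1.ci_low <= r1.odds_ratio <= r1.ci_high

    def test_ci_narrows_as_counts_scale_up(self):
        widths = []
        for k in (1, 2, 5, 10):
            r = odds_ratio_woolf(((8 * k, 5 * k), (6 * k, 9 * k)))
            widths.append(math.log(r.ci_high) - math.log(r.ci_low))
        assert widths == sorted(widths, reverse=True)


class TestHaplotypeAssociation:
    def test_study_fixture_values(self):
        res = haplotype_association(load_study_counts("haplotypes"))
        assert res["WT-M"].or_str() == "1.65 [1.15-2.37]"
        assert round_half_up(res["WT-M"].p_chi2, 3) == 0.006
        assert round_half_up(res["Ins-I"].odds_ratio, 2) == 0.89
        assert res["Ins-M"] is None  # absent haplotype reported "na"

    def test_identical_groups_give_unit_ors(self):
        hap = HaplotypeCountTable({"case": (10, 20, 30, 40),
                                   "control": (10, 20, 30, 40)})
        for name, res in haplotype_association(hap).items():
            assert res.odds_ratio == pytest.approx(1.0)
            assert res.p_chi2 == pytest.approx(1.0)


class TestAssociationReport:
    def test_reproduces_published_lines(self):
        report = association_report()
        assert report.allele["I148M"].or_str() == "0.61 [0.42-0.87]"
        assert report.allele["WT/Ins"].or_str() == "1.12 [0.80-1.57]"
        assert round_half_up(report.genotype["I148M"][2], 3) == 0.025
        assert all(r.p > 0.05 for r in report.hwe_control.values())
        assert "I148M" in report.to_text()

    def test_null_contrast_all_p_one(self):
        from linedrop.cohort import GenotypeCountTable
        same = {"case": (30, 40, 30), "control": (30, 40, 30)}
        gt = GenotypeCountTable("snp", ("I/I", "I/M", "M/M"), same)
        gt2 = GenotypeCountTable("ins", ("WT/WT", "WT/Ins", "Ins/Ins"), same)
        hap = HaplotypeCountTable({"case": (50, 50, 50, 50),
                                   "control": (50, 50, 50, 50)})
        report = association_report(gt, gt2, hap)
        assert all(res.p_chi2 == pytest.approx(1.0)
                   for res in report.allele.values())
        assert all(p == pytest.approx(1.0)
                   for _, _, p in report.genotype.values())
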