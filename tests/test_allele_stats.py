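"""Allele frequencies, heterozygosity, and the exact Hardy-Weinberg test.

The independent oracle for the exact test is the closed-form Levene
distribution for two alleles (heterozygote-count enumeration), plus the
package's exhaustive table enumerator for three and four alleles, which is
itself validated against the closed form.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from hla_popgen.allele_stats import (
    allele_frequencies,
    count_tables,
    enumerate_tables,
    heterozygosity,
    hwe_enumeration_p,
    hwe_exact_test,
)
from hla_popgen.cohort import from_genotypes
from hla_popgen.nomenclature import AlleleName
from hla_popgen.simulate import SimulationConfig, equifrequent_pool, simulate_cohort

from conftest import filler_loci, single_locus_cohort


def levene_biallelic_p(naa: int, nab: int, nbb: int) -> float:
    """Closed-form exact p for two alleles by enumerating heterozygote counts."""
    n = naa + nab + nbb
    m_a = 2 * naa + nab
    hs = range(m_a % 2, min(m_a, 2 * n - m_a) + 1, 2)
    logw = {}
    for h in hs:
        paa, pbb = (m_a - h) // 2, (2 * n - m_a - h) // 2
        logw[h] = h * math.log(2) - (
            math.lgamma(paa + 1) + math.lgamma(h + 1) + math.lgamma(pbb + 1)
        )
    mx = max(logw.values())
    total = sum(math.exp(w - mx) for w in logw.values())
    tail = sum(math.exp(w - mx) for w in logw.values() if w <= logw[nab] + 1e-9)
    return tail / total


class TestAlleleFrequencies:
    def test_direct_counting(self):
        c = single_locus_cohort({(0, 1): 1, (0, 0): 1})
        table = allele_frequencies(c, "A")
        assert table.frequency(AlleleName("A", 1, 1)) == Fraction(3, 4)
        assert table.frequency(AlleleName("A", 2, 1)) == Fraction(1, 4)

    def test_monomorphic(self):
        c = single_locus_cohort({(0, 0): 5})
        table = allele_frequencies(c, "A")
        assert len(table.entries) == 1
        assert table.frequency(AlleleName("A", 1, 1)) == 1

    def test_frequencies_sum_to_one_exactly(self, rng):
        for _ in range(10):
            tbl = {}
            k = int(rng.integers(2, 6))
            for i in range(k):
                for j in range(i + 1):
                    tbl[(i, j)] = int(rng.integers(0, 5))
            if sum(tbl.values()) == 0:
                tbl[(0, 0)] = 1
            c = single_locus_cohort(tbl)
            table = allele_frequencies(c, "A")
            assert sum(f for _, f in table.entries.values()) == 1

    def test_sorted_by_descending_frequency(self):
        c = single_locus_cohort({(0, 0): 1, (1, 1): 5, (2, 2): 3})
        table = allele_frequencies(c, "A")
        copies = [c for c, _ in table.entries.values()]
        assert copies == sorted(copies, reverse=True)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(from_genotypes([]), "A")

    def test_simulated_marginals_match_pool(self, national_pool):
        cohort = simulate_cohort(
            national_pool, SimulationConfig(n={"China": 5000}, seed=17)
        )
        table = allele_frequencies(cohort, "A")
        # pool marginal for A*30:01 in the national pool
        truth = sum(
            f for hap, f in national_pool.regions["China"]
            if hap[0] == AlleleName("A", 30, 1)
        )
        est = float(table.frequency(AlleleName("A", 30, 1)))
        se = math.sqrt(truth * (1 - truth) / 10000)
        assert abs(est - truth) < 3 * se


class TestHeterozygosity:
    def test_monomorphic_is_zero(self):
        c = single_locus_cohort({(0, 0): 10})
        assert heterozygosity(c, "A") == (0.0, 0.0)

    def test_two_heterozygotes_closed_form(self):
        c = single_locus_cohort({(0, 1): 2})
        h_obs, h_exp = heterozygosity(c, "A")
        assert h_obs == 1.0
        assert h_exp == pytest.approx(4 / 3 * 0.5)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            heterozygosity(single_locus_cohort({(0, 1): 1}), "A")

    def test_equifrequent_simulation(self):
        pool = equifrequent_pool(10)
        c = simulate_cohort(pool, SimulationConfig(n={"NE": 3000}, seed=9))
        h_obs, h_exp = heterozygosity(c, "A")
        se = math.sqrt(0.9 * 0.1 / 3000)
        assert abs(h_obs - 0.9) < 3 * se
        assert abs(h_exp - 0.9) < 3 * se


class TestEnumerator:
    def test_counts_match_combinatorics(self):
        # two alleles, counts (4, 4): het count in {0, 2, 4} -> 3 tables
        m = np.array([4, 4])
        assert count_tables(m) == 3
        tables = list(enumerate_tables(m))
        assert len(tables) == 3
        for t in tables:
            assert 2 * t[0, 0] + t[1, 0] == 4
            assert 2 * t[1, 1] + t[1, 0] == 4

    def test_enumeration_matches_levene_closed_form(self):
        for counts in [(10, 5, 10), (3, 4, 3), (7, 2, 1), (0, 10, 0)]:
            c = single_locus_cohort({(0, 0): counts[0], (1, 0): counts[1],
                                     (1, 1): counts[2]})
            res = hwe_exact_test(c, "A", method="enumerate")
            assert res.p_value == pytest.approx(levene_biallelic_p(*counts), abs=1e-12)


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        c = single_locus_cohort({(0, 0): 20})
        res = hwe_exact_test(c, "A")
        assert res.p_value == 1.0 and res.mc_se == 0.0

    def test_balanced_biallelic_table_is_modal(self):
        # AA=25, Aa=50, aa=25 is the most probable table, so every table
        # qualifies for the tail and p = 1
        c = single_locus_cohort({(0, 0): 25, (1, 0): 50, (1, 1): 25})
        res = hwe_exact_test(c, "A", method="enumerate")
        assert res.p_value == pytest.approx(1.0)
        mcmc = hwe_exact_test(c, "A", steps=100_000, seed=3, method="mcmc")
        assert abs(mcmc.p_value - res.p_value) <= max(4 * mcmc.mc_se, 1e-12)

    def test_total_heterozygote_deficit_rejected(self):
        c = single_locus_cohort({(0, 0): 50, (1, 1): 50})
        res = hwe_exact_test(c, "A", method="enumerate")
        assert res.p_value < 0.001

    @pytest.mark.parametrize("counts", [(10, 5, 10), (3, 4, 3), (12, 20, 8)])
    def test_mcmc_agrees_with_enumeration(self, counts):
        c = single_locus_cohort({(0, 0): counts[0], (1, 0): counts[1],
                                 (1, 1): counts[2]})
        exact = hwe_exact_test(c, "A", method="enumerate").p_value
        mcmc = hwe_exact_test(c, "A", steps=200_000, seed=11, method="mcmc")
        assert abs(mcmc.p_value - exact) <= 4 * max(mcmc.mc_se, 1e-4)

    def test_auto_uses_enumeration_when_small(self):
        c = single_locus_cohort({(0, 0): 10, (1, 0): 5, (1, 1): 10})
        assert hwe_exact_test(c, "A").method == "enumeration"

    def test_p_invariant_to_allele_relabeling(self):
        tbl = {(0, 0): 6, (1, 0): 2, (1, 1): 4, (2, 0): 3, (2, 1): 1, (2, 2): 2}
        relabeled = {}  # swap allele indices 0 and 2
        swap = {0: 2, 1: 1, 2: 0}
        for (i, j), v in tbl.items():
            a, b = swap[i], swap[j]
            relabeled[(max(a, b), min(a, b))] = v
        p1 = hwe_exact_test(single_locus_cohort(tbl), "A", method="enumerate").p_value
        p2 = hwe_exact_test(single_locus_cohort(relabeled), "A",
                            method="enumerate").p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_null_calibration_small(self):
        # 30 cohorts simulated in HWE: p-values should not pile up near 0
        pool = equifrequent_pool(8)
        rejections = 0
        for i in range(30):
            c = simulate_cohort(pool, SimulationConfig(n={"NE": 200}, seed=800 + i))
            res = hwe_exact_test(c, "A", steps=50_000, seed=i, method="mcmc")
            rejections += res.p_value <= 0.05
        assert rejections <= 7  # P(X > 7) < 1e-4 for Binomial(30, 0.05)
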