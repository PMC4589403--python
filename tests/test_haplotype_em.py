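"""EM haplotype-frequency estimation, its likelihood, and the LD test.

The independent oracle for the EM is a dense grid search of the likelihood
over the haplotype-frequency simplex on a four-haplotype problem.
"""

import math
from itertools import product

import numpy as np
import pytest

from hla_popgen.allele_stats import allele_frequencies
from hla_popgen.cohort import LOCI, from_genotypes
from hla_popgen.haplotype_em import (
    em_estimate,
    enumerate_phases,
    independence_table,
    ld_lrt,
    log_likelihood,
    report_common,
    assign_most_likely_pairs,
    HaplotypeFreqTable,
)
from hla_popgen.nomenclature import AlleleName
from hla_popgen.simulate import SimulationConfig, default_pool, simulate_cohort

from conftest import filler_loci, two_locus_cohort


def _hap(locus_alleles):
    return tuple(AlleleName(locus, i + 1, 1) for locus, i in locus_alleles)


class TestEnumeratePhases:
    def _genotype(self, het_loci):
        g = {}
        for locus in LOCI:
            if locus in het_loci:
                g[locus] = (AlleleName(locus, 1, 1), AlleleName(locus, 2, 1))
            else:
                g[locus] = (AlleleName(locus, 1, 1), AlleleName(locus, 1, 1))
        return g

    @pytest.mark.parametrize(
        "het_loci,loci,expected",
        [
            ((), ("A", "B"), 1),
            (("A",), ("A", "B"), 1),
            (("A", "B"), ("A", "B"), 2),
            (("A", "C", "B", "DRB1", "DQB1"), LOCI, 16),
            (("A", "B"), LOCI, 2),
        ],
    )
    def test_phase_counts(self, het_loci, loci, expected):
        phases = enumerate_phases(self._genotype(het_loci), loci)
        assert len(phases) == expected
        for h1, h2 in phases:
            assert h1 <= h2  # canonical pair order


class TestEmEstimate:
    def test_unambiguous_homozygotes_exact(self):
        pairs = [((0, 0), (0, 0))] * 50 + [((1, 1), (1, 1))] * 50
        c = two_locus_cohort(pairs)
        table = em_estimate(c, ("A", "B"), seed=0)
        assert table.frequency(_hap([("A", 0), ("B", 0)])) == pytest.approx(0.5, abs=1e-9)
        assert table.frequency(_hap([("A", 1), ("B", 1)])) == pytest.approx(0.5, abs=1e-9)
        assert table.converged

    def test_single_double_heterozygote_symmetric_maxima(self):
        c = two_locus_cohort([((0, 0), (1, 1))])
        table = em_estimate(c, ("A", "B"), seed=0)
        # either phase resolution is a global maximum with the same likelihood
        assert table.log_likelihood == pytest.approx(math.log(0.5), abs=1e-6)
        top = sorted(table.entries.values(), reverse=True)[:2]
        assert sum(top) == pytest.approx(1.0, abs=1e-9)

    def test_em_matches_grid_search_oracle(self, rng):
        # four two-locus haplotypes at (0.4, 0.3, 0.2, 0.1)
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        probs = [0.4, 0.3, 0.2, 0.1]
        draws = rng.choice(4, size=(200, 2), p=probs)
        c = two_locus_cohort([(haps[i], haps[j]) for i, j in draws])
        table = em_estimate(c, ("A", "B"), seed=1)

        # oracle: dense grid over the 3-simplex at resolution 0.005,
        # evaluated vectorised over all grid points at once
        hap_objs = [_hap([("A", i), ("B", j)]) for i, j in haps]
        hap_pos = {h: i for i, h in enumerate(hap_objs)}
        patterns: dict = {}
        for ind in c:
            key = (ind.genotype["A"], ind.genotype["B"])
            patterns[key] = patterns.get(key, 0) + 1
        expansions = []  # (count, [(i, j, mult), ...])
        for (ga, gb), cnt in patterns.items():
            terms = []
            for h1, h2 in enumerate_phases({"A": ga, "B": gb}, ("A", "B")):
                terms.append((hap_pos[h1], hap_pos[h2], 2.0 if h1 != h2 else 1.0))
            expansions.append((cnt, terms))

        step = 0.005
        g = np.arange(0.0, 1.0 + step / 2, step)
        f1, f2, f3 = np.meshgrid(g, g, g, indexing="ij")
        f4 = 1.0 - f1 - f2 - f3
        valid = f4 > -1e-12
        fgrid = np.stack(
            [f1[valid], f2[valid], f3[valid], np.clip(f4[valid], 0.0, None)]
        )
        ll = np.zeros(fgrid.shape[1])
        for cnt, terms in expansions:
            mass = np.zeros(fgrid.shape[1])
            for i, j, mult in terms:
                mass += mult * fgrid[i] * fgrid[j]
            with np.errstate(divide="ignore"):
                ll += cnt * np.log(mass)
        best = int(np.argmax(ll))
        best_ll, best_f = ll[best], fgrid[:, best]
        assert table.log_likelihood >= best_ll - 1e-6
        est = [table.frequency(h) for h in hap_objs]
        assert max(abs(e - b) for e, b in zip(est, best_f)) < 0.005

    def test_empty_loci_rejected(self):
        c = two_locus_cohort([((0, 0), (0, 0))])
        with pytest.raises(ValueError):
            em_estimate(c, ())

    def test_marginal_consistency_five_locus(self, national_pool):
        cohort = simulate_cohort(
            national_pool, SimulationConfig(n={"China": 800}, seed=23)
        )
        table = em_estimate(cohort, LOCI, seed=0, restarts=2)
        direct = allele_frequencies(cohort, "A")
        summed: dict = {}
        for hap, f in table.entries.items():
            summed[hap[0]] = summed.get(hap[0], 0.0) + f
        for allele, total in summed.items():
            assert total == pytest.approx(float(direct.frequency(allele)),
                                          abs=1e-4)


class TestLogLikelihood:
    def test_certain_homozygote_is_zero(self):
        c = two_locus_cohort([((0, 0), (0, 0))])
        hap = _hap([("A", 0), ("B", 0)])
        tbl = HaplotypeFreqTable(loci=("A", "B"), entries={hap: 1.0}, n=1,
                                 log_likelihood=np.nan, iterations=0,
                                 converged=True, seed=0)
        assert log_likelihood(tbl, c) == pytest.approx(0.0)

    def test_double_het_hand_expansion(self):
        # two haplotypes at 0.5 each covering one phase: mass = 2 * 0.25 = 0.5
        c = two_locus_cohort([((0, 0), (1, 1))])
        entries = {_hap([("A", 0), ("B", 0)]): 0.5, _hap([("A", 1), ("B", 1)]): 0.5}
        tbl = HaplotypeFreqTable(loci=("A", "B"), entries=entries, n=1,
                                 log_likelihood=np.nan, iterations=0,
                                 converged=True, seed=0)
        assert log_likelihood(tbl, c) == pytest.approx(math.log(0.5))

    def test_zero_mass_flags_minus_inf(self):
        c = two_locus_cohort([((0, 0), (0, 0))])
        tbl = HaplotypeFreqTable(
            loci=("A", "B"), entries={_hap([("A", 1), ("B", 1)]): 1.0}, n=1,
            log_likelihood=np.nan, iterations=0, converged=True, seed=0)
        assert log_likelihood(tbl, c) == -np.inf

    def test_joint_model_nests_independence(self, rng):
        draws = rng.choice(4, size=(100, 2), p=[0.4, 0.3, 0.2, 0.1])
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        c = two_locus_cohort([(haps[i], haps[j]) for i, j in draws])
        joint = em_estimate(c, ("A", "B"), seed=0)
        indep = independence_table(c, ("A", "B"))
        assert joint.log_likelihood >= indep.log_likelihood - 1e-9


class TestReportCommon:
    def test_permille_rendering_and_threshold(self):
        h1 = _hap([(locus, 0) for locus in LOCI])
        h2 = _hap([(locus, 1) for locus in LOCI])
        tbl = HaplotypeFreqTable(loci=LOCI, entries={h1: 0.0370, h2: 0.0009},
                                 n=100, log_likelihood=0.0, iterations=1,
                                 converged=True, seed=0)
        df = report_common(tbl)
        assert len(df) == 1
        assert df.iloc[0]["permille"] == 37.00
        empty = report_common(
            HaplotypeFreqTable(loci=LOCI, entries={}, n=0, log_likelihood=0.0,
                               iterations=0, converged=True, seed=0))
        assert empty.empty

    def test_assignment_covers_cohort(self, national_pool):
        c = simulate_cohort(national_pool, SimulationConfig(n={"NE": 50}, seed=3))
        tbl = em_estimate(c, LOCI, seed=0, restarts=1)
        assign = assign_most_likely_pairs(tbl, c)
        assert len(assign) == c.n
        for (h1, h2), ind in zip(assign, c):
            # assigned pair must be a valid phase resolution of the genotype
            assert (h1, h2) in enumerate_phases(ind.genotype, LOCI)


class TestLdLrt:
    def test_monomorphic_pair_is_null(self):
        pairs = [((0, 0), (0, 0))] * 10
        c = two_locus_cohort(pairs)
        res = ld_lrt(c, "A", "B", n_perm=9, seed=0)
        assert res.lrt_stat == 0.0 and res.p_value == 1.0

    def test_perfect_association_minimal_p(self, rng):
        draws = rng.integers(0, 2, size=(100, 2))
        pairs = [((int(i), int(i)), (int(j), int(j))) for i, j in draws]
        c = two_locus_cohort(pairs)
        res = ld_lrt(c, "A", "B", n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.lrt_stat > 50

    def test_null_p_not_small(self, rng):
        # independent loci: p should rarely be extreme (checked over 5 draws)
        small = 0
        for i in range(5):
            local = np.random.default_rng(100 + i)
            draws_a = local.integers(0, 3, size=(120, 2))
            draws_b = local.integers(0, 3, size=(120, 2))
            pairs = [((int(a1), int(b1)), (int(a2), int(b2)))
                     for (a1, a2), (b1, b2) in zip(draws_a, draws_b)]
            c = two_locus_cohort(pairs)
            res = ld_lrt(c, "A", "B", n_perm=39, seed=i)
            small += res.p_value <= 0.05
        assert small <= 2
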