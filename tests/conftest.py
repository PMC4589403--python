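"""Shared fixtures and cohort builders for the test suite.

All fixture data is generated programmatically; no external files.
"""

from __future__ import annotations

import numpy as np
import pytest

from hla_popgen.cohort import LOCI, from_genotypes
from hla_popgen.nomenclature import AlleleName


def filler_loci(except_loci=()):
    """Homozygous placeholder genotypes for loci not under study."""
    return {
        locus: (AlleleName(locus, 1, 1), AlleleName(locus, 1, 1))
        for locus in LOCI
        if locus not in except_loci
    }


def single_locus_cohort(table: dict[tuple[int, int], int], locus: str = "A"):
    """Cohort whose `locus` genotype counts follow `table` (allele-index pairs
    -> count); all other loci are monomorphic placeholders."""
    rest = filler_loci((locus,))
    genotypes = []
    for (i, j), count in table.items():
        pair = (AlleleName(locus, i + 1, 1), AlleleName(locus, j + 1, 1))
        for _ in range(count):
            genotypes.append({locus: pair, **rest})
    return from_genotypes(genotypes)


def two_locus_cohort(hap_pairs, locus_a: str = "A", locus_b: str = "B"):
    """Cohort built from explicit haplotype pairs ((ia, ib), (ja, jb)) so the
    phased truth is known; indices are 0-based allele indices per locus."""
    rest = filler_loci((locus_a, locus_b))
    genotypes = []
    for (ia, ib), (ja, jb) in hap_pairs:
        genotypes.append(
            {
                locus_a: (AlleleName(locus_a, ia + 1, 1), AlleleName(locus_a, ja + 1, 1)),
                locus_b: (AlleleName(locus_b, ib + 1, 1), AlleleName(locus_b, jb + 1, 1)),
                **rest,
            }
        )
    return from_genotypes(genotypes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150930)


@pytest.fixture(scope="session")
def national_pool():
    from hla_popgen.simulate import default_pool

    return default_pool()
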