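"""10/10 donor-matching probabilities within and between regional cohorts.

Two individuals are a 10/10 match when their unordered allele pairs are
identical at all five loci.  The match probability between two populations is
the inner product of their five-locus genotype distributions,
``sum_g dA(g) dB(g)`` — the probability that a random member of one matches a
random member of the other.  On empirical distributions this equals
cross-pair counting exactly; the within-population variant including
self-pairs relates to distinct-pair counting by ``(2 M + n) / n^2``.  All
rates are kept as exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, REGIONS
from .nomenclature import AlleleName, LOCI

HIGH_THRESHOLD = 3e-5  # exclusive lower bound for "high"
MEDIUM_THRESHOLD = 2e-5  # inclusive lower bound for "medium"

GenotypeKey = tuple[tuple[AlleleName, AlleleName], ...]


@dataclass(frozen=True)
class GenotypeDistribution:
    n: int
    counts: Mapping[GenotypeKey, int]

    @property
    def entries(self) -> dict[GenotypeKey, Fraction]:
        return {g: Fraction(c, self.n) for g, c in self.counts.items()}


def _genotype_key(ind) -> GenotypeKey:
    # per-locus pairs are stored canonically sorted, so the key is orientation-free
    return tuple(ind.genotype[locus] for locus in LOCI)


def genotype_distribution(cohort: Cohort) -> GenotypeDistribution:
    """Empirical distribution of full five-locus unphased genotypes."""
    if cohort.n < 1:
        raise ValueError("empty cohort")
    counts: dict[GenotypeKey, int] = {}
    for ind in cohort:
        key = _genotype_key(ind)
        counts[key] = counts.get(key, 0) + 1
    assert sum(counts.values()) == cohort.n
    return GenotypeDistribution(n=cohort.n, counts=counts)


def expected_matching_rate(
    da: GenotypeDistribution, db: GenotypeDistribution
) -> Fraction:
    """Inner product of two genotype distributions (exact rational)."""
    if len(da.counts) > len(db.counts):
        da, db = db, da
    total = Fraction(0)
    for g, ca in da.counts.items():
        cb = db.counts.get(g)
        if cb:
            total += Fraction(ca, da.n) * Fraction(cb, db.n)
    return total


def brute_force_matching_rate(ca: Cohort, cb: Cohort) -> Fraction:
    """Direct pair counting: cross pairs for two cohorts, unordered distinct
    pairs when a cohort is compared with itself."""
    if ca.n < 1 or cb.n < 1:
        raise ValueError("empty cohort")
    keys_a = [_genotype_key(ind) for ind in ca]
    if ca is cb:
        m = 0
        for i in range(ca.n):
            for j in range(i + 1, ca.n):
                if keys_a[i] == keys_a[j]:
                    m += 1
        return Fraction(m, ca.n * (ca.n - 1) // 2)
    keys_b = [_genotype_key(ind) for ind in cb]
    m = sum(1 for x in keys_a for y in keys_b if x == y)
    return Fraction(m, ca.n * cb.n)


def bin_rate(rate) -> str:
    """Bin a matching rate: high > 3e-5; medium in [2e-5, 3e-5]; low < 2e-5."""
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if rate > HIGH_THRESHOLD:
        return "high"
    if rate >= MEDIUM_THRESHOLD:
        return "medium"
    return "low"


@dataclass(frozen=True)
class MatchingMatrix:
    regions: tuple[str, ...]
    rates: pd.DataFrame  # float rates, regions x regions
    exact: dict[tuple[str, str], Fraction]
    categories: pd.DataFrame

    def rate(self, r: str, s: str) -> Fraction:
        key = (r, s) if (r, s) in self.exact else (s, r)
        return self.exact[key]


def matching_matrix(regional_cohorts: Mapping[str, Cohort]) -> MatchingMatrix:
    """All within/between matching rates for the regional cohorts.

    Symmetric by construction; every cell also satisfies the Cauchy-Schwarz
    bound ``rate(r,s)^2 <= rate(r,r) rate(s,s)``.
    """
    regions = tuple(r for r in REGIONS if r in regional_cohorts)
    for r in regions:
        if regional_cohorts[r].n == 0:
            raise ValueError(f"region {r} is empty")
    dists = {r: genotype_distribution(regional_cohorts[r]) for r in regions}
    exact: dict[tuple[str, str], Fraction] = {}
    for i, r in enumerate(regions):
        for s in regions[i:]:
            exact[(r, s)] = expected_matching_rate(dists[r], dists[s])
    rates = pd.DataFrame(0.0, index=regions, columns=regions)
    cats = pd.DataFrame("", index=regions, columns=regions)
    for (r, s), v in exact.items():
        f = float(v)
        rates.loc[r, s] = rates.loc[s, r] = f
        cats.loc[r, s] = cats.loc[s, r] = bin_rate(v)
    return MatchingMatrix(regions=regions, rates=rates, exact=exact, categories=cats)
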