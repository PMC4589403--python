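"""EM estimation of multi-locus haplotype frequencies from unphased genotypes,
and the likelihood-ratio test of linkage disequilibrium.

The model: each diploid carries two haplotypes drawn independently from a
haplotype frequency vector ``f`` (random union of gametes).  An unphased
genotype heterozygous at ``h`` of the requested loci is compatible with
``2^(h-1)`` unordered haplotype pairs; its likelihood is

    P(g | f) = sum over compatible pairs (h1, h2) of f(h1) f(h2) (2 if h1 != h2)

EM alternates distributing each individual's mass over its phase resolutions
(E) and renormalising expected haplotype counts (M); the log-likelihood never
decreases.  Haplotype support is built from observed genotypes only, keeping
memory linear in the phase expansions rather than in the astronomically large
global haplotype space of five highly polymorphic loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .allele_stats import allele_frequencies
from .cohort import Cohort
from .nomenclature import AlleleName

Haplotype = tuple[AlleleName, ...]

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 1000
DEFAULT_RESTARTS = 3
PRUNE_EPS = 1e-12


@dataclass
class HaplotypeFreqTable:
    """EM-estimated haplotype frequencies with fit provenance."""

    loci: tuple[str, ...]
    entries: dict[Haplotype, float]
    n: int
    log_likelihood: float
    iterations: int
    converged: bool
    seed: int

    def frequency(self, hap: Haplotype) -> float:
        return self.entries.get(hap, 0.0)


@dataclass(frozen=True)
class LdResult:
    locus_pair: tuple[str, str]
    lrt_stat: float
    p_value: float
    n_perm: int
    seed: int


def haplotype_label(hap: Haplotype) -> str:
    return "-".join(a.render() for a in hap)


def enumerate_phases(
    genotype: dict[str, tuple[AlleleName, AlleleName]], loci: Sequence[str]
) -> set[frozenset | tuple]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    Returns a set of canonically ordered pairs ``(h1, h2)`` with ``h1 <= h2``;
    the count is ``2^(h-1)`` for ``h`` heterozygous loci (1 when ``h <= 1``).
    """
    pairs = [genotype[locus] for locus in loci]
    het_idx = [i for i, (a, b) in enumerate(pairs) if a != b]
    out = set()
    # fix the first heterozygous locus's orientation to halve the expansion
    n_free = max(len(het_idx) - 1, 0)
    for bits in product((0, 1), repeat=n_free):
        h1 = []
        h2 = []
        flips = dict(zip(het_idx[1:], bits))
        for i, (a, b) in enumerate(pairs):
            if i in flips and flips[i]:
                h1.append(b)
                h2.append(a)
            else:
                h1.append(a)
                h2.append(b)
        t1, t2 = tuple(h1), tuple(h2)
        out.add((t1, t2) if t1 <= t2 else (t2, t1))
    return out


def _expand_cohort(cohort: Cohort, loci: Sequence[str]):
    """Group individuals by genotype pattern and expand phase resolutions.

    Returns (haplotype list, pair arrays h1/h2/mult, segment ids, pattern
    counts) where each "segment" is one distinct genotype pattern.
    """
    pattern_counts: dict[tuple, int] = {}
    for ind in cohort:
        key = tuple(ind.genotype[locus] for locus in loci)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    hap_index: dict[Haplotype, int] = {}
    h1_idx, h2_idx, mult, seg = [], [], [], []
    counts = []
    for s, (key, cnt) in enumerate(pattern_counts.items()):
        genotype = dict(zip(loci, key))
        for hap1, hap2 in sorted(enumerate_phases(genotype, loci)):
            for hap in (hap1, hap2):
                if hap not in hap_index:
                    hap_index[hap] = len(hap_index)
            h1_idx.append(hap_index[hap1])
            h2_idx.append(hap_index[hap2])
            mult.append(2.0 if hap1 != hap2 else 1.0)
            seg.append(s)
        counts.append(cnt)
    haplotypes = list(hap_index)
    return (
        haplotypes,
        np.asarray(h1_idx),
        np.asarray(h2_idx),
        np.asarray(mult),
        np.asarray(seg),
        np.asarray(counts, dtype=float),
    )


def _product_start(
    cohort: Cohort, loci: Sequence[str], haplotypes: list[Haplotype]
) -> np.ndarray:
    marginals = {locus: allele_frequencies(cohort, locus) for locus in loci}
    f0 = np.array(
        [
            math.prod(float(marginals[locus].frequency(a))
                      for locus, a in zip(loci, hap))
            for hap in haplotypes
        ]
    )
    total = f0.sum()
    if total <= 0:
        return np.full(len(haplotypes), 1.0 / len(haplotypes))
    return f0 / total


def _run_em(f, h1, h2, mult, seg, counts, n, tol, max_iter):
    """One EM run from start ``f``; returns (f, loglik, iterations, converged)."""
    n_seg = len(counts)
    loglik = -np.inf
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        w = f[h1] * f[h2] * mult
        denom = np.bincount(seg, weights=w, minlength=n_seg)
        new_loglik = float(np.dot(counts, np.log(denom)))
        # EM monotonicity, allowing for floating-point slack
        assert new_loglik >= loglik - 1e-8, "EM log-likelihood decreased"
        loglik = new_loglik
        r = w / denom[seg] * counts[seg]
        acc = np.bincount(h1, weights=r, minlength=len(f))
        acc += np.bincount(h2, weights=r, minlength=len(f))
        f_new = acc / (2.0 * n)
        f_new[f_new < PRUNE_EPS] = 0.0
        f_new /= f_new.sum()
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break
    return f, loglik, iterations, converged


def em_estimate(
    cohort: Cohort,
    loci: Sequence[str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> HaplotypeFreqTable:
    """Maximum-likelihood haplotype frequencies at the requested loci.

    The first start is the linkage-equilibrium product of allele frequencies;
    the remaining ``restarts - 1`` starts are Dirichlet perturbations of it.
    The best-likelihood solution across restarts is returned.
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("loci tuple must be non-empty")
    if cohort.n < 1:
        raise ValueError("empty cohort")
    haplotypes, h1, h2, mult, seg, counts = _expand_cohort(cohort, loci)
    f0 = _product_start(cohort, loci, haplotypes)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(restarts, 1)):
        if r == 0:
            f_start = f0
        else:
            f_start = rng.dirichlet(1.0 + 100.0 * f0)
            f_start = np.clip(f_start, 1e-12, None)
            f_start /= f_start.sum()
        result = _run_em(f_start, h1, h2, mult, seg, counts, cohort.n, tol, max_iter)
        if best is None or result[1] > best[1]:
            best = result
    f, loglik, iterations, converged = best
    entries = {
        hap: float(freq)
        for hap, freq in sorted(
            zip(haplotypes, f), key=lambda kv: (-kv[1], haplotype_label(kv[0]))
        )
        if freq > 0.0
    }
    return HaplotypeFreqTable(
        loci=loci,
        entries=entries,
        n=cohort.n,
        log_likelihood=loglik,
        iterations=iterations,
        converged=converged,
        seed=seed,
    )


def log_likelihood(table: HaplotypeFreqTable, cohort: Cohort) -> float:
    """Cohort log-likelihood of a haplotype frequency table.

    Sums, per individual, the log of the phase-resolved genotype probability.
    Returns ``-inf`` when some individual has zero mass under the table.
    """
    loci = table.loci
    total = 0.0
    for ind in cohort:
        mass = 0.0
        for hap1, hap2 in enumerate_phases(ind.genotype, loci):
            term = table.frequency(hap1) * table.frequency(hap2)
            if hap1 != hap2:
                term *= 2.0
            mass += term
        if mass <= 0.0:
            return -np.inf
        total += math.log(mass)
    return total


def independence_table(cohort: Cohort, loci: Sequence[str]) -> HaplotypeFreqTable:
    """Haplotype table under linkage equilibrium (product of allele freqs),
    restricted to the haplotypes observable in the cohort's phase expansions."""
    loci = tuple(loci)
    haplotypes, *_ = _expand_cohort(cohort, loci)
    marginals = {locus: allele_frequencies(cohort, locus) for locus in loci}
    entries = {
        hap: math.prod(float(marginals[locus].frequency(a))
                       for locus, a in zip(loci, hap))
        for hap in haplotypes
    }
    table = HaplotypeFreqTable(
        loci=loci, entries=entries, n=cohort.n, log_likelihood=np.nan,
        iterations=0, converged=True, seed=0,
    )
    table.log_likelihood = log_likelihood(table, cohort)
    return table


def report_common(table: HaplotypeFreqTable, threshold_permille: float = 1.0):
    """Haplotypes above the reporting threshold, in per mille.

    Returns a DataFrame with one allele column per locus, ``frequency`` and
    ``permille`` (2 decimals), ranked by descending frequency with ties broken
    by haplotype label.
    """
    import pandas as pd

    rows = []
    for hap, freq in table.entries.items():
        permille = freq * 1000.0
        if permille > threshold_permille:
            rows.append(
                {**{locus: a.render() for locus, a in zip(table.loci, hap)},
                 "frequency": freq, "permille": round(permille, 2),
                 "_label": haplotype_label(hap)}
            )
    rows.sort(key=lambda r: (-r["frequency"], r["_label"]))
    for rank, r in enumerate(rows, start=1):
        r["rank"] = rank
        del r["_label"]
    cols = ["rank", *table.loci, "frequency", "permille"]
    return pd.DataFrame(rows, columns=cols)


def assign_most_likely_pairs(
    table: HaplotypeFreqTable, cohort: Cohort
) -> list[tuple[Haplotype, Haplotype]]:
    """Per-individual most probable phase resolution under the EM posterior.

    Ties are broken by haplotype label for determinism.
    """
    out = []
    for ind in cohort:
        best_pair = None
        best_w = -1.0
        for hap1, hap2 in sorted(enumerate_phases(ind.genotype, table.loci)):
            w = table.frequency(hap1) * table.frequency(hap2)
            if hap1 != hap2:
                w *= 2.0
            if w > best_w:
                best_w = w
                best_pair = (hap1, hap2)
        out.append(best_pair)
    return out


def ld_lrt(
    cohort: Cohort,
    locus_a: str,
    locus_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LdResult:
    """Likelihood-ratio test of linkage disequilibrium between two loci.

    The statistic is ``2 (logL_joint - logL_independent)`` where the joint
    model is the two-locus EM fit and the independent model the product of
    single-locus allele frequencies (whose likelihood factorises over loci
    and is invariant to the permutations).  Significance is assessed by
    permuting the second locus's genotypes across individuals, which
    preserves both marginals while destroying the association; the observed
    and permuted statistics use the identical EM procedure (product start),
    keeping the permutation distribution exchangeable.
    """
    fa = allele_frequencies(cohort, locus_a)
    fb = allele_frequencies(cohort, locus_b)
    if len(fa.entries) == 1 or len(fb.entries) == 1:
        return LdResult((locus_a, locus_b), 0.0, 1.0, n_perm, seed)

    n = cohort.n
    # intern per-locus genotype pairs and allele ids
    a_alleles = list(fa.entries)
    b_alleles = list(fb.entries)
    a_index = {al: i for i, al in enumerate(a_alleles)}
    b_index = {al: i for i, al in enumerate(b_alleles)}
    pa = np.array([float(fa.frequency(al)) for al in a_alleles])
    pb = np.array([float(fb.frequency(al)) for al in b_alleles])
    ga = np.empty((n, 2), dtype=np.int64)
    gb = np.empty((n, 2), dtype=np.int64)
    for i, ind in enumerate(cohort):
        ga[i] = [a_index[x] for x in ind.genotype[locus_a]]
        gb[i] = [b_index[x] for x in ind.genotype[locus_b]]

    # independence log-likelihood factorises over loci: single-locus HWE mass
    def hwe_mass(g, p):
        mass = p[g[:, 0]] * p[g[:, 1]]
        mass[g[:, 0] != g[:, 1]] *= 2.0
        return float(np.log(mass).sum())

    indep_ll = hwe_mass(ga, pa) + hwe_mass(gb, pb)

    # haplotype and genotype-pattern interning with cached phase expansions
    n_b_alleles = len(b_alleles)
    hap_ids: dict[tuple[int, int], int] = {}
    f0_list: list[float] = []

    def hid(ia: int, ib: int) -> int:
        key = (ia, ib)
        h = hap_ids.get(key)
        if h is None:
            h = len(hap_ids)
            hap_ids[key] = h
            f0_list.append(pa[ia] * pb[ib])
        return h

    pattern_cache: dict[tuple[int, int, int, int], tuple] = {}

    def expansion(a1, a2, b1, b2):
        key = (a1, a2, b1, b2)
        cached = pattern_cache.get(key)
        if cached is None:
            if a1 != a2 and b1 != b2:
                pairs = [(hid(a1, b1), hid(a2, b2)), (hid(a1, b2), hid(a2, b1))]
            else:
                pairs = [(hid(a1, b1), hid(a2, b2))]
            h1 = np.array([p[0] for p in pairs])
            h2 = np.array([p[1] for p in pairs])
            mult = np.where(h1 != h2, 2.0, 1.0)
            cached = (h1, h2, mult)
            pattern_cache[key] = cached
        return cached

    pat_a = ga[:, 0] * len(a_alleles) + ga[:, 1]

    def stat(order: np.ndarray) -> float:
        gbp = gb[order]
        pat_b = gbp[:, 0] * n_b_alleles + gbp[:, 1]
        keys = pat_a * (n_b_alleles * n_b_alleles) + pat_b
        uniq, inv_first, counts = np.unique(
            keys, return_index=True, return_counts=True
        )
        h1_parts, h2_parts, mult_parts, seg_parts = [], [], [], []
        for s, (idx, cnt) in enumerate(zip(inv_first, counts)):
            a1, a2 = ga[idx]
            b1, b2 = gbp[idx]
            h1c, h2c, multc = expansion(int(a1), int(a2), int(b1), int(b2))
            h1_parts.append(h1c)
            h2_parts.append(h2c)
            mult_parts.append(multc)
            seg_parts.append(np.full(len(h1c), s))
        h1 = np.concatenate(h1_parts)
        h2 = np.concatenate(h2_parts)
        mult = np.concatenate(mult_parts)
        seg = np.concatenate(seg_parts)
        cnt = counts.astype(float)
        support = np.unique(np.concatenate([h1, h2]))
        remap = np.full(len(hap_ids), -1, dtype=np.int64)
        remap[support] = np.arange(len(support))
        h1 = remap[h1]
        h2 = remap[h2]
        f = np.asarray(f0_list)[support]
        f = f / f.sum()
        f, loglik, _, _ = _run_em(f, h1, h2, mult, seg, cnt, n, tol, max_iter)
        return max(2.0 * (loglik - indep_ll), 0.0)

    observed = stat(np.arange(n))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(n)) >= observed - 1e-9:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return LdResult((locus_a, locus_b), observed, p, n_perm, seed)
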