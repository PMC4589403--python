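"""Direct-count allele frequencies, gene diversity, and the exact test of
Hardy-Weinberg equilibrium.

The HWE test is the exact test conditional on allele counts: under the null,
the probability of an unordered genotype table ``{n_ij}`` with allele counts
``m_i`` among ``n`` diploids is (Levene)

    P(table) = n! * 2^h * prod_i m_i! / ( (2n)! * prod_{i<=j} n_ij! )

with ``h`` the number of heterozygotes.  The p-value is the total null
probability of tables no more probable than the observed one.  For small
tables the distribution is enumerated exhaustively; otherwise the
Guo-Thompson Markov chain with margin-preserving allele "switch" proposals
estimates the p-value, with a Monte-Carlo standard error from batch means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numba import njit

from .cohort import Cohort
from .nomenclature import AlleleName

DEFAULT_STEPS = 1_000_000
DEFAULT_DEMEM = 2_000
DEFAULT_SEED = 20150930
ENUMERATION_LIMIT = 100_000

_LOG_TIE_TOL = 1e-9


@dataclass(frozen=True)
class AlleleFreqTable:
    """Direct-count allele frequencies at one locus.

    ``entries`` maps each observed allele to ``(copies, frequency)`` with
    ``frequency = copies / (2n)``; frequencies are exact rationals so the
    table sums to 1 identically.  Entries are ordered by descending frequency
    then allele name.
    """

    locus: str
    n: int
    entries: dict[AlleleName, tuple[int, Fraction]]

    @property
    def alleles(self) -> list[AlleleName]:
        return list(self.entries)

    def frequency(self, a: AlleleName) -> Fraction:
        return self.entries[a][1]

    def copies(self, a: AlleleName) -> int:
        return self.entries.get(a, (0, Fraction(0)))[0]


@dataclass(frozen=True)
class HweResult:
    locus: str
    p_value: float
    mc_se: float
    h_obs: float
    h_exp: float
    steps: int
    demem: int
    seed: int
    method: str  # "enumeration" or "mcmc"


def allele_frequencies(cohort: Cohort, locus: str) -> AlleleFreqTable:
    """Count allele copies at a locus; frequency = copies / 2n."""
    if cohort.n < 1:
        raise ValueError("empty cohort")
    counts: dict[AlleleName, int] = {}
    for ind in cohort:
        for a in ind.genotype[locus]:
            counts[a] = counts.get(a, 0) + 1
    two_n = 2 * cohort.n
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = {a: (c, Fraction(c, two_n)) for a, c in ordered}
    assert sum(c for c, _ in entries.values()) == two_n
    return AlleleFreqTable(locus=locus, n=cohort.n, entries=entries)


def heterozygosity(cohort: Cohort, locus: str) -> tuple[float, float]:
    """Observed heterozygote fraction and unbiased expected heterozygosity.

    ``h_exp`` is the gene-diversity estimator ``2n/(2n-1) * (1 - sum p^2)``.
    """
    if cohort.n < 2:
        raise ValueError("need at least 2 individuals")
    het = sum(1 for ind in cohort if ind.genotype[locus][0] != ind.genotype[locus][1])
    h_obs = het / cohort.n
    freqs = allele_frequencies(cohort, locus)
    two_n = 2 * cohort.n
    sum_p2 = sum(float(f) ** 2 for _, f in freqs.entries.values())
    h_exp = two_n / (two_n - 1) * (1.0 - sum_p2)
    return h_obs, h_exp


# ---------------------------------------------------------------------------
# Exact-test machinery


def _genotype_counts(cohort: Cohort, locus: str):
    """Index alleles and return per-individual genotype index pairs (i >= j)."""
    freqs = allele_frequencies(cohort, locus)
    alleles = freqs.alleles
    index = {a: i for i, a in enumerate(alleles)}
    g1 = np.empty(cohort.n, dtype=np.int64)
    g2 = np.empty(cohort.n, dtype=np.int64)
    for k, ind in enumerate(cohort):
        i, j = (index[a] for a in ind.genotype[locus])
        g1[k], g2[k] = (i, j) if i >= j else (j, i)
    m = np.zeros(len(alleles), dtype=np.int64)
    for k in range(cohort.n):
        m[g1[k]] += 1
        m[g2[k]] += 1
    return alleles, m, g1, g2


def _log_weight(table: np.ndarray) -> float:
    """log(2^h / prod n_ij!) — the table-dependent part of the Levene mass."""
    k = table.shape[0]
    h = 0
    s = 0.0
    for i in range(k):
        for j in range(i + 1):
            nij = int(table[i, j])
            if i != j:
                h += nij
            s += math.lgamma(nij + 1)
    return h * math.log(2.0) - s


def enumerate_tables(m: np.ndarray):
    """Yield all genotype tables (lower-triangular count matrices) with allele
    counts ``m``.  Off-diagonal cells are enumerated recursively; diagonals are
    forced by the margins."""
    k = len(m)
    pairs = [(i, j) for i in range(k) for j in range(i)]
    table = np.zeros((k, k), dtype=np.int64)
    used = np.zeros(k, dtype=np.int64)

    def rec(idx: int):
        if idx == len(pairs):
            ok = True
            for i in range(k):
                rem = m[i] - used[i]
                if rem < 0 or rem % 2 != 0:
                    ok = False
                    break
                table[i, i] = rem // 2
            if ok:
                yield table.copy()
            return
        i, j = pairs[idx]
        cap = min(m[i] - used[i], m[j] - used[j])
        for nij in range(int(cap) + 1):
            table[i, j] = nij
            used[i] += nij
            used[j] += nij
            yield from rec(idx + 1)
            used[i] -= nij
            used[j] -= nij
        table[i, j] = 0

    yield from rec(0)


def count_tables(m: np.ndarray, cap: int = ENUMERATION_LIMIT) -> int:
    """Number of reachable tables, stopping early once ``cap`` is exceeded."""
    count = 0
    for _ in enumerate_tables(m):
        count += 1
        if count > cap:
            return count
    return count


def hwe_enumeration_p(g1: np.ndarray, g2: np.ndarray, k: int) -> float:
    """Exact p by full enumeration of the conditional null distribution."""
    obs = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(g1, g2):
        obs[a, b] += 1
    m = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i + 1):
            m[i] += obs[i, j]
            m[j] += obs[i, j]
    lw_obs = _log_weight(obs)
    lws = np.array([_log_weight(t) for t in enumerate_tables(m)])
    shift = lws.max()
    w = np.exp(lws - shift)
    p = w[lws <= lw_obs + _LOG_TIE_TOL].sum() / w.sum()
    return float(p)


@njit(cache=True)
def _gt_chain(g1, g2, k, steps, demem, seed, n_batches):  # pragma: no cover
    """Margin-preserving allele-switch chain.  Returns per-batch
    tail-indicator means.

    A step picks two distinct individuals and one allele copy from each
    (slots uniform) and exchanges them.  On labeled gamete arrangements this
    is a symmetric proposal with a uniform stationary law, which induces the
    Levene distribution on genotype tables, so every swap is accepted: the
    individual-proportional cell selection makes the Metropolis-Hastings
    ratio of the table-level switch chain identically one.
    """
    np.random.seed(seed)
    n = g1.shape[0]
    counts = np.zeros((k, k), dtype=np.int64)
    h = 0
    s = 0.0  # sum of log(n_ij!)
    for t in range(n):
        counts[g1[t], g2[t]] += 1
    for i in range(k):
        for j in range(i + 1):
            c = counts[i, j]
            if i != j:
                h += c
            s += math.lgamma(c + 1.0)
    log2 = math.log(2.0)
    logp = h * log2 - s
    logp_obs = logp
    batch = np.zeros(n_batches)
    batch_size = steps // n_batches
    total = demem + n_batches * batch_size
    for step in range(total):
        u = np.random.randint(0, n)
        v = np.random.randint(0, n - 1)
        if v >= u:
            v += 1
        a, b = g1[u], g2[u]
        c, d = g1[v], g2[v]
        # pick one allele from each individual to exchange
        if np.random.randint(0, 2) == 0:
            su, ou = a, b
        else:
            su, ou = b, a
        if np.random.randint(0, 2) == 0:
            sv, ov = c, d
        else:
            sv, ov = d, c
        if su != sv:
            # removed cells (canonical i >= j)
            r1i, r1j = (a, b) if a >= b else (b, a)
            r2i, r2j = (c, d) if c >= d else (d, c)
            # added cells: u keeps ou gains sv; v keeps ov gains su
            n1i, n1j = (ou, sv) if ou >= sv else (sv, ou)
            n2i, n2j = (ov, su) if ov >= su else (su, ov)
            c1 = counts[r1i, r1j]
            c2 = counts[r2i, r2j]
            if r2i == r1i and r2j == r1j:
                c2 -= 1
            a1 = counts[n1i, n1j]
            if n1i == r1i and n1j == r1j:
                a1 -= 1
            if n1i == r2i and n1j == r2j:
                a1 -= 1
            a2 = counts[n2i, n2j]
            if n2i == r1i and n2j == r1j:
                a2 -= 1
            if n2i == r2i and n2j == r2j:
                a2 -= 1
            if n2i == n1i and n2j == n1j:
                a2 += 1
            d_s = (
                math.log(a1 + 1.0)
                + math.log(a2 + 1.0)
                - math.log(c1 * 1.0)
                - math.log(c2 * 1.0)
            )
            d_h = (
                (1 if n1i != n1j else 0)
                + (1 if n2i != n2j else 0)
                - (1 if r1i != r1j else 0)
                - (1 if r2i != r2j else 0)
            )
            counts[r1i, r1j] -= 1
            counts[r2i, r2j] -= 1
            counts[n1i, n1j] += 1
            counts[n2i, n2j] += 1
            g1[u], g2[u] = n1i, n1j
            g1[v], g2[v] = n2i, n2j
            h += d_h
            s += d_s
            logp = h * log2 - s
        if (step & 0xFFFF) == 0xFFFF:
            # refresh the running log-probability to cancel float drift
            h = 0
            s = 0.0
            for i in range(k):
                for j in range(i + 1):
                    c0 = counts[i, j]
                    if i != j:
                        h += c0
                    s += math.lgamma(c0 + 1.0)
            logp = h * log2 - s
        if step >= demem:
            if logp <= logp_obs + 1e-9:
                b_idx = (step - demem) // batch_size
                batch[b_idx] += 1.0
    return batch / batch_size


def hwe_exact_test(
    cohort: Cohort,
    locus: str,
    steps: int = DEFAULT_STEPS,
    demem: int = DEFAULT_DEMEM,
    seed: int = DEFAULT_SEED,
    method: str = "auto",
) -> HweResult:
    """Exact Hardy-Weinberg test at one locus.

    ``method`` is ``"auto"`` (enumerate when the table space is small, at most
    :data:`ENUMERATION_LIMIT` tables, otherwise MCMC), ``"enumerate"`` or
    ``"mcmc"``.  A monomorphic locus returns p = 1 with zero error.
    """
    if cohort.n < 2:
        raise ValueError("need at least 2 individuals")
    alleles, m, g1, g2 = _genotype_counts(cohort, locus)
    h_obs, h_exp = heterozygosity(cohort, locus)
    k = len(alleles)
    if k == 1:
        return HweResult(locus, 1.0, 0.0, h_obs, h_exp, 0, 0, seed, "degenerate")
    if method not in ("auto", "enumerate", "mcmc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        bound = 1.0
        for i in range(k):
            for j in range(i):
                bound *= min(m[i], m[j]) + 1
                if bound > 20 * ENUMERATION_LIMIT:
                    break
            if bound > 20 * ENUMERATION_LIMIT:
                break
        if bound <= 20 * ENUMERATION_LIMIT and count_tables(m) <= ENUMERATION_LIMIT:
            method = "enumerate"
        else:
            method = "mcmc"
    if method == "enumerate":
        p = hwe_enumeration_p(g1, g2, k)
        return HweResult(locus, p, 0.0, h_obs, h_exp, 0, 0, seed, "enumeration")
    n_batches = 100
    batch_means = _gt_chain(
        g1.copy(), g2.copy(), k, int(steps), int(demem), int(seed) % (2**31), n_batches
    )
    p = float(batch_means.mean())
    mc_se = float(batch_means.std(ddof=1) / math.sqrt(n_batches))
    return HweResult(locus, p, mc_se, h_obs, h_exp, int(steps), int(demem), seed, "mcmc")
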