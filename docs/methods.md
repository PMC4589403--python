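# Methods

This note documents the statistical models, numerical choices and known
limitations of `hla-popgen`. Notation: `n` individuals, `2n` allele copies
per locus, two-field alleles at the loci A, C, B, DRB1, DQB1 (always in this
order), haplotype frequencies `f`, allele frequencies `p`.

## Allele names and merging

Typing chemistries resolve different exon sets per locus, so registry data
is reported at two-field ("protein") resolution: synonymous and non-coding
fields are dropped (`A*01:01:01:01 → A*01:01`). Names differing
non-synonymously *outside* the typed exons must not be collapsed; these are
carried on a merge-exception list shipped as an editable text resource
(`data/merge_exceptions.tsv`, default entry A*02:253, which is separated
from A*02:03 only by exon 4). Expression suffixes (N/L/Q/S) are preserved
and make alleles distinct — null alleles are clinically different — though
registry-style data normally carries none. Equality of `AlleleName` ignores
synonymous fields by design, which makes reduction idempotent and the
two-field form canonical.

## Allele statistics

Allele frequencies are direct counts, kept as exact rationals
(`copies / 2n`), so each table sums to one identically. Observed
heterozygosity is the heterozygote fraction; expected heterozygosity is the
unbiased gene diversity `(2n/(2n−1)) (1 − Σ p̂²)` — the convention of the
standard population-genetics packages; the sample-size correction matters
only for small cohorts.

### Exact Hardy-Weinberg test

Conditional on the allele counts `m_i`, the null probability of an
unordered genotype table `{n_ij}` is Levene's

    P(table) = n! · 2^h · Π_i m_i! / ( (2n)! · Π_{i≤j} n_ij! ),  h = Σ_{i<j} n_ij.

The p-value is the total probability of tables no more probable than the
observed one (the standard conditional-probability ordering; ties count at a
log-tolerance of 1e-9).

*Enumeration.* Tables are enumerated recursively over the off-diagonal cells
with the diagonals forced by the margins. When the reachable space holds at
most 1e5 tables (`method="auto"`), the p-value is computed exhaustively and
`mc_se = 0`.

*Markov chain.* Otherwise a margin-preserving switch chain is run: pick two
distinct individuals uniformly, pick one allele copy from each (slot chosen
uniformly), and exchange them. On labeled gamete arrangements this proposal
is symmetric and its uniform stationary law induces exactly the Levene
distribution on tables, so every swap is accepted — equivalently, the
individual-proportional cell selection makes the Metropolis–Hastings ratio
of the classical table-level switch chain identically one. The chain starts
at the observed table; defaults are 1e6 steps after 2e3 dememorization
steps (the conventional settings for registry-scale data; tests and the
pipeline use shorter chains where noted in their configuration). The
Monte-Carlo standard error comes from batch means over 100 batches, and the
running log-probability is refreshed from the counts every 2^16 steps to
cancel float drift. A zero-count tail estimate carries `mc_se = 0`; its
resolution is still only ~3/steps (rule of three), which is how the
oracle-agreement tests bound it. Monomorphic loci return p = 1 by
convention.

## Haplotype frequency estimation (EM)

The model is random union of gametes: an individual's two haplotypes are
i.i.d. draws from `f`. A genotype heterozygous at `h` of the requested loci
has `2^(h−1)` unordered phase resolutions (1 if `h ≤ 1`), and likelihood
`P(g|f) = Σ_{(h1,h2)~g} f(h1) f(h2) (2 if h1≠h2)`. EM distributes each
individual's mass over its resolutions proportionally to the current
`f(h1)f(h2)` products (E) and renormalises expected counts (M); the
log-likelihood is asserted non-decreasing at every iteration.

Numerical choices:

- Haplotype support is built only from observed genotypes' phase
  expansions, never the cross product of the cohort's allele sets — with
  five highly polymorphic loci the global space is astronomically large
  while the per-individual expansion is at most 16 pairs.
- Individuals are grouped by distinct genotype pattern; the E-step is a
  vectorised segment-sum over the pooled expansions.
- Convergence when `max |Δf| < 1e-7` (tighter than the 0.01‰ reporting
  precision), at most 1000 iterations. Frequencies below 1e-12 are pruned
  between iterations; this cannot affect the >1‰ report.
- Restarts: the first start is the linkage-equilibrium product of allele
  frequencies; the remaining `restarts − 1` (default 3 total) are Dirichlet
  perturbations of it (`Dirichlet(1 + 100 f₀)`). The best-likelihood
  solution wins. On a four-haplotype test problem the EM optimum matches a
  dense grid search of the likelihood over the frequency simplex.

Reported tables keep haplotypes above 1‰, in per mille to two decimals,
ranked by descending frequency with lexicographic tie-break.

### Linkage disequilibrium

The LD statistic for a locus pair is `2(logL_joint − logL_indep)`, joint
model = two-locus EM fit, independent model = product of single-locus
allele frequencies (whose likelihood factorises over loci). Significance is
by permutation: the second locus's genotypes are shuffled across
individuals, preserving both single-locus marginals while destroying the
association; `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`. A permutation test
was preferred over a χ² approximation because the degrees of freedom are
ill-defined with many rare alleles. Observed and permuted statistics use
the identical EM procedure (product start, tolerance 1e-6) so the
permutation distribution is exchangeable; phase expansions are cached
across permutations for speed. Monomorphic pairs return statistic 0, p = 1.

## CWD classification

Rules, applied in order per allele: **common** if frequency > 0.001
(strict) and the reference cohort has ≥ 1500 individuals; else
**well-documented** if ≥ 5 copies in unrelated individuals, or 3–4 copies
that all reside on the same assigned five-locus haplotype; else **rare**;
alleles with zero copies in a sub-population are **not observed** there.
"Sharing a haplotype" is operationalised through each carrier's most likely
EM phase resolution — the only phased context available for registry data —
and all donors are treated as unrelated, as registry volunteers are. The
3–4-copy window is exact because ≥ 5 copies already qualify regardless of
haplotype context. Regional summaries count, per region × locus, the
national allele universe split into CWD / rare / not-observed (a partition,
asserted), plus shared-in-all-regions and unique-in-one-region alleles;
`sample_pct` is the carrier percentage (individuals with ≥ 1 allele of the
category), the only reading under which the percentages stay ≤ 100.

## Region-specific haplotypes

From the ranked cross-region table, a haplotype is called region-specific
when the *smallest* contiguous region set (size 1, then 2, then 3)
satisfies `min(inside ‰) ≥ 2 × max(outside ‰)`, ratio inclusive; among
equal-size qualifying sets the highest ratio wins with lexicographic
tie-break, and at most one call is made per haplotype. Contiguity uses the
adjacency NE–NC, NC–NW, NC–CC, NC–EC, NW–SW, NW–CC, EC–CC, EC–SC, CC–SC,
CC–SW, SC–SW. Zero outside frequency yields an infinite ratio (called
whenever the inside minimum is positive). Calls are scale-invariant and
deterministic. On the bundled reference table this recovers three South
China singles, two Southwest singles and the SC+SW pair, and makes no call
for the one haplotype with near-uniform frequencies everywhere.

## Matching probabilities

A 10/10 match is identity of the unordered allele pairs at all five loci.
The match probability between populations A and B is the inner product of
their empirical five-locus genotype distributions, `Σ_g d_A(g) d_B(g)`,
computed in exact rational arithmetic. On empirical distributions this
equals brute-force cross-pair counting *algebraically*; within one cohort
it includes self-pairs and relates to distinct-pair counting by
`(2M + n)/n²` — both estimators are exposed, and they differ by O(1/n).
Every matrix is symmetric and satisfies the Cauchy–Schwarz bound
`rate(r,s)² ≤ rate(r,r)·rate(s,s)`. Bins follow the registry convention:
high > 3e-5 (exclusive), medium 2e-5–3e-5 (both inclusive), low < 2e-5.

## Synthetic cohorts

The generator defines the study conditions for every simulation-based test.
Each region's pool holds the bundled published top-20 five-locus haplotypes
at their printed per-mille values (a national pool under the key `"China"`
likewise), plus 200 filler haplotypes absorbing the residual ~80% of mass.
Filler alleles use pseudo allele-group numbers (field1 ≥ 900, tagged per
region) outside real nomenclature, so planted truth never collides with
reference alleles. Sampling: haplotype h1 ~ pool; with probability F
(inbreeding coefficient) h2 = h1, else h2 independent; the unphased
genotype is the per-locus union. `allele_independent` mode draws each
locus's alleles from the pool marginals instead, destroying LD while
preserving single-locus frequencies. Cohorts are deterministic in
(pool, config).

Filler shape: frequencies decay geometrically at 0.995 per rank,
renormalised. The near-flat choice is deliberate — a real registry's
residual mass is spread over a far larger tail than 200 haplotypes can
represent, and a strongly decaying filler would concentrate enough mass to
dominate the genotype concentration Σf², swamping the seeded regional
structure. With the diffuse filler the South China pool, whose seeded
haplotypes carry the most mass, is the most concentrated, making the
within-SC cell the designed maximum of the matching matrix. At n = 5000
per region the single-seed margin over the runner-up (within-EC) is about
1.7e-5 against per-seed noise of similar size, so maximality is asserted on
the matrix averaged over 8 seeds, where the margin is ~4 standard errors.

What the generator does *not* emulate: allelic richness (a few hundred
haplotypes versus tens of thousands; simulated matching rates are
correspondingly a factor ~3–5 above registry scale), ethnic substructure
and admixture, mutation/recombination, genotyping error, and missing data.
Passing tests therefore demonstrate correctness of the estimators under the
declared sampling model, not registry-scale effect sizes.

Test problem sizes (n = 5000 national cohort for EM recovery, 200 cohorts
of n = 500 for Hardy-Weinberg calibration, 100 replicates of n = 500 plus
one n = 2000 run for LD calibration, 8 seeds × 7 × 5000 for the matching
matrix) were chosen as the scale at which each property is statistically
identified on a single CPU.

## Pipeline

`run_full_analysis` chains the stages (frequencies → HWE → EM/LD → CWD →
regional comparison → matching) from one `AnalysisConfig`, with a run
manifest recording version, seeds and settings, per-stage logging, and
warnings for monomorphic loci and empty regions. Hardy-Weinberg p-values
below 0.05 are flagged significant with no multiple-testing correction
across the five loci — a fidelity choice, documented here as a caveat.
All randomness is seeded explicitly; identical configurations produce
byte-identical bundles.

## Known limitations

- The EM returns a point estimate; no frequency standard errors or
  bootstrap are provided.
- The 3–4-copy haplotype-sharing CWD rule depends on the EM phase
  assignment, which is itself an estimate; with very rare alleles the
  assignment can be ambiguous.
- The region-specific detector generalises the published single-region rule
  to contiguous multi-region sets; only six of the nine published calls are
  verifiable from the bundled 38-haplotype reference (the remaining three
  involve haplotypes whose full frequency rows are not part of the bundled
  table).
- Matching ignores mismatch grades (9/10 etc.) and permissive mismatching;
  it is the strict 10/10 criterion only.
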