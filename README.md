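# hla-popgen

Population genetics of HLA alleles and haplotypes in a multi-region
stem-cell donor registry.

Unrelated hematopoietic stem-cell transplantation needs donors matched to
the patient at the allelic ("two-field") level of the five classical loci
HLA-A, -C, -B, -DRB1 and -DQB1 — a *10/10 match*. How likely a patient is to
find such a donor depends on the allele and haplotype frequency structure of
the registry's source populations. This package implements the complete
analysis chain a registry uses to characterise that structure across
geographic regions, here the seven traditional regions of mainland China
(NE, NC, NW, EC, CC, SC, SW, covering 31 provinces):

- **Nomenclature** — parsing and two-field reduction of WHO allele names,
  with a merge-exception list for alleles that differ outside the routinely
  typed exons (e.g. A*02:253 vs A*02:03).
- **Allele statistics** — direct-count allele frequencies (`copies / 2n`),
  unbiased gene diversity `2n/(2n−1) · (1 − Σp̂²)`, and the exact
  Hardy-Weinberg test conditional on allele counts: exhaustive enumeration of
  the Levene distribution for small tables, a margin-preserving allele-switch
  Markov chain (with Monte-Carlo standard errors) otherwise.
- **Haplotype frequencies** — maximum-likelihood estimation from unphased
  genotypes by EM over the `2^(h−1)` phase resolutions per individual, for
  any 2–5 locus subset; linkage disequilibrium by a likelihood-ratio
  permutation test of the joint haplotype model against locus independence.
- **CWD classification** — each allele is *common* (frequency > 0.001 in a
  reference sample of ≥ 1500 individuals), *well-documented* (≥ 5 unrelated
  observations, or 3–4 observations sharing an assigned five-locus
  haplotype) or *rare*, with national and per-region category summaries.
- **Regional analysis** — ranked cross-region haplotype comparison and
  detection of region-specific haplotypes: frequency in one region (or a
  contiguous set of 2–3 regions) at least 2× the maximum elsewhere.
- **Matching** — 10/10 matching probabilities within and between regions as
  the inner product of five-locus genotype distributions `Σ_g d_A(g)·d_B(g)`,
  kept in exact rational arithmetic, binned high (> 3·10⁻⁵) / medium
  (2–3·10⁻⁵) / low (< 2·10⁻⁵).
- **Synthetic cohorts** — a generator that draws registry-like diploid
  cohorts from per-region five-locus haplotype pools (bundled published
  frequencies plus a diffuse filler tail), with optional inbreeding and a
  linkage-equilibrium mode, so every stage is testable without any download.

## Worked example

Region-specific haplotype detection runs directly on the bundled published
per-region frequencies (no simulation involved):

```sh
python examples/05_region_specific_haplotypes.py
```

```
6 region-specific haplotypes among the 38 bundled reference haplotypes:

                                    haplotype region_set  min_inside_permille  max_outside_permille     ratio
A*02:07-C*01:02-B*46:01-DRB1*14:54-DQB1*05:02      SC+SW                 7.49                  3.51  2.133903
A*02:03-C*07:02-B*38:02-DRB1*16:02-DQB1*05:02         SC                10.11                  3.78  2.674603
A*11:01-C*03:04-B*13:01-DRB1*16:02-DQB1*05:02         SC                 7.71                  2.88  2.677083
A*24:02-C*04:03-B*15:25-DRB1*12:02-DQB1*03:01         SW                 7.90                  0.72 10.972222
A*02:03-C*07:02-B*52:01-DRB1*14:04-DQB1*05:03         SW                 5.11                  1.26  4.055556
A*24:02-C*03:04-B*13:01-DRB1*15:01-DQB1*06:01         SC                 3.91                  1.62  2.413580
```

Each `ratio` is the lowest per-mille frequency inside the called region set
divided by the highest frequency outside it; a call requires ratio ≥ 2. The
A\*02:03-C\*07:02-B\*38:02-DRB1\*16:02-DQB1\*05:02 haplotype, for example, is
2.7× more frequent in South China than anywhere else, while the
DRB1\*14:54-bearing haplotype is concentrated in the contiguous South +
Southwest pair.

The other scripts in `examples/` walk through the remaining capabilities —
simulation, allele frequencies and Hardy-Weinberg tests, EM haplotype
estimation with the LD test, CWD classification, and the matching matrix —
each printing a small annotated result.

There is also a thin CLI over the same library functions:

```sh
hla-popgen simulate --regions NE,SC --n 500 --seed 1 --out cohort.tsv
hla-popgen hwe cohort.tsv --steps 100000
hla-popgen em cohort.tsv --loci A,C,B --min-permille 1
hla-popgen match cohort.tsv
```

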