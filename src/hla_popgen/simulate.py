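"""Synthetic registry cohorts with the statistical structure the analyses
assume.

Each region has a haplotype pool: the top five-locus haplotypes of the
bundled frequency reference at their published per-mille values, plus
deterministic low-frequency "filler" haplotypes absorbing the residual mass
(~80%) with geometric decay.  Filler alleles use pseudo allele-group numbers
(field1 >= 900, tagged by region) outside real nomenclature so the seeded
truth never collides with reference alleles.

Sampling: a diploid in region r draws haplotype h1 from pool(r); with
probability F (inbreeding coefficient) h2 = h1, otherwise h2 is drawn
independently; its unphased genotype is the per-locus union.  The
``allele_independent`` mode instead draws each locus's two alleles from the
pool's marginal allele frequencies, destroying linkage disequilibrium while
preserving single-locus marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import Cohort, Individual, REGIONS, default_partition
from .haplotype_em import Haplotype
from .nomenclature import LOCI, AlleleName
from .regional import load_reference_frequencies
from .nomenclature import parse_allele

FILLER_COUNT = 200
# Near-flat geometric decay: the residual ~80% of haplotype mass in a real
# registry is spread over a vastly larger tail than 200 haplotypes can carry,
# so the filler must stay diffuse; a strongly decaying filler would dominate
# the genotype concentration (sum of squared frequencies) and distort the
# designed regional ordering of matching rates.
FILLER_DECAY = 0.995
FILLER_FIELD1_BASE = 900
PLANTED_FIELD1 = 980


@dataclass(frozen=True)
class HaplotypePool:
    """Per-region lists of (haplotype, frequency); frequencies sum to 1."""

    regions: Mapping[str, tuple[tuple[Haplotype, float], ...]]

    def __post_init__(self) -> None:
        for region, entries in self.regions.items():
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pool for {region} sums to {total}, not 1")
            if any(f <= 0 for _, f in entries):
                raise ValueError(f"pool for {region} has non-positive frequencies")

    def seeded(self, region: str, n_seeded: int = 20):
        """The leading (non-filler) entries of a region's pool."""
        return self.regions[region][:n_seeded]


@dataclass(frozen=True)
class SimulationConfig:
    n: Mapping[str, int]
    seed: int = 0
    inbreeding_f: float = 0.0
    mode: str = "haplotype"  # or "allele_independent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding F must be in [0, 1]")
        if self.mode not in ("haplotype", "allele_independent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(v < 0 for v in self.n.values()):
            raise ValueError("region sizes must be >= 0")


def _filler_haplotypes(region_tag: int, count: int = FILLER_COUNT) -> list[Haplotype]:
    f1 = FILLER_FIELD1_BASE + region_tag
    return [
        tuple(AlleleName(locus, f1, k) for locus in LOCI)
        for k in range(1, count + 1)
    ]


def _with_filler(
    seeded: Sequence[tuple[Haplotype, float]], region_tag: int
) -> tuple[tuple[Haplotype, float], ...]:
    seeded_mass = sum(f for _, f in seeded)
    residual = 1.0 - seeded_mass
    if residual < 0:
        raise ValueError("seeded frequencies exceed 1")
    weights = np.power(FILLER_DECAY, np.arange(1, FILLER_COUNT + 1))
    weights *= residual / weights.sum()
    filler = list(zip(_filler_haplotypes(region_tag), weights))
    return tuple(list(seeded) + filler)


def default_pool(n_seeded: int = 20) -> HaplotypePool:
    """Pools seeded from the bundled reference: each region's top ``n_seeded``
    haplotypes at their published per mille, plus a national pool under the
    key ``"China"``."""
    df = load_reference_frequencies()
    haps = [
        tuple(parse_allele(f"{locus}*{row[locus]}") for locus in LOCI)
        for _, row in df.iterrows()
    ]

    def top(col: str) -> list[tuple[Haplotype, float]]:
        order = sorted(
            zip(haps, df[col]),
            key=lambda kv: (-kv[1], "-".join(a.render() for a in kv[0])),
        )[:n_seeded]
        return [(hap, permille / 1000.0) for hap, permille in order]

    pools = {}
    for tag, region in enumerate(REGIONS):
        pools[region] = _with_filler(top(region), tag)
    pools["China"] = _with_filler(top("China"), len(REGIONS))
    return HaplotypePool(regions=pools)


def equifrequent_pool(
    n_haplotypes: int = 8, regions: Sequence[str] = REGIONS
) -> HaplotypePool:
    """A pool of equifrequent fully distinct haplotypes (calibration studies):
    every locus has ``n_haplotypes`` equifrequent alleles and loci are in
    complete association."""
    haps = [
        tuple(AlleleName(locus, 1, k) for locus in LOCI)
        for k in range(1, n_haplotypes + 1)
    ]
    entries = tuple((h, 1.0 / n_haplotypes) for h in haps)
    return HaplotypePool(regions={r: entries for r in regions})


def _marginals(entries) -> dict[str, tuple[list[AlleleName], np.ndarray]]:
    out = {}
    for i, locus in enumerate(LOCI):
        acc: dict[AlleleName, float] = {}
        for hap, f in entries:
            acc[hap[i]] = acc.get(hap[i], 0.0) + f
        alleles = sorted(acc)
        probs = np.array([acc[a] for a in alleles])
        out[locus] = (alleles, probs / probs.sum())
    return out


def simulate_cohort(pool: HaplotypePool, cfg: SimulationConfig) -> Cohort:
    """Draw a multi-region cohort from the pool; deterministic under
    (pool, cfg)."""
    partition = default_partition()
    rng = np.random.default_rng(cfg.seed)
    individuals = []
    for region in cfg.n:
        if region not in pool.regions:
            raise ValueError(f"region {region!r} absent from pool")
        entries = pool.regions[region]
        n = cfg.n[region]
        province = (
            partition.provinces(region)[0] if region in REGIONS else region
        )
        region_code = region if region in REGIONS else REGIONS[0]
        if cfg.mode == "haplotype":
            haps = [h for h, _ in entries]
            probs = np.array([f for _, f in entries])
            probs = probs / probs.sum()
            i1 = rng.choice(len(haps), size=n, p=probs)
            i2 = rng.choice(len(haps), size=n, p=probs)
            if cfg.inbreeding_f > 0:
                same = rng.random(n) < cfg.inbreeding_f
                i2[same] = i1[same]
            for t in range(n):
                h1, h2 = haps[i1[t]], haps[i2[t]]
                genotype = {
                    locus: (h1[i], h2[i]) for i, locus in enumerate(LOCI)
                }
                individuals.append(
                    Individual(
                        id=f"{region}-{t:06d}", province=province,
                        region=region_code, genotype=genotype,
                    )
                )
        else:
            marg = _marginals(entries)
            draws = {}
            for locus in LOCI:
                alleles, probs = marg[locus]
                a1 = rng.choice(len(alleles), size=n, p=probs)
                a2 = rng.choice(len(alleles), size=n, p=probs)
                draws[locus] = (alleles, a1, a2)
            for t in range(n):
                genotype = {
                    locus: (draws[locus][0][draws[locus][1][t]],
                            draws[locus][0][draws[locus][2][t]])
                    for locus in LOCI
                }
                individuals.append(
                    Individual(
                        id=f"{region}-{t:06d}", province=province,
                        region=region_code, genotype=genotype,
                    )
                )
    return Cohort(individuals=individuals)


@dataclass(frozen=True)
class PlantedAllele:
    allele: AlleleName
    copies: int
    placements: tuple[tuple[str, str, int], ...]  # (individual id, locus, slot)


def inject_rare(
    cohort: Cohort,
    spec: Sequence[tuple[str, int]],
    seed: int = 0,
) -> tuple[Cohort, list[PlantedAllele]]:
    """Replace random allele copies with novel planted alleles.

    ``spec`` is a list of (locus, copies) requests; each request creates one
    novel allele planted at that many copies (in distinct individuals, so the
    planted copies are unrelated observations).  Returns the modified cohort
    and a truth manifest.
    """
    rng = np.random.default_rng(seed)
    total_by_locus: dict[str, int] = {}
    for locus, copies in spec:
        total_by_locus[locus] = total_by_locus.get(locus, 0) + copies
    for locus, total in total_by_locus.items():
        if total > cohort.n:
            raise ValueError(
                f"cannot plant {total} copies at {locus} in {cohort.n} individuals"
            )
    genotypes = [dict(ind.genotype) for ind in cohort]
    used: dict[str, set[int]] = {locus: set() for locus in total_by_locus}
    manifest = []
    for k, (locus, copies) in enumerate(spec):
        allele = AlleleName(locus, PLANTED_FIELD1, k + 1)
        placements = []
        available = [i for i in range(cohort.n) if i not in used[locus]]
        chosen = rng.choice(len(available), size=copies, replace=False)
        for c in chosen:
            idx = available[int(c)]
            used[locus].add(idx)
            slot = int(rng.integers(0, 2))
            pair = list(genotypes[idx][locus])
            pair[slot] = allele
            genotypes[idx][locus] = tuple(pair)
            placements.append((cohort.individuals[idx].id, locus, slot))
        manifest.append(
            PlantedAllele(allele=allele, copies=copies,
                          placements=tuple(placements))
        )
    individuals = [
        Individual(id=ind.id, province=ind.province, region=ind.region,
                   genotype=g)
        for ind, g in zip(cohort.individuals, genotypes)
    ]
    return Cohort(individuals=individuals), manifest
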