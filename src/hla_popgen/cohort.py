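"""Cohort containers and genotype-table I/O.

A cohort is a list of donors, each with an id, a province of birth, the
geographic region the province belongs to, and an unphased two-field genotype
at the five classical loci A, C, B, DRB1, DQB1 (column order follows the
haplotype presentation order used throughout the package).  Genotype tables
are plain TSV with header::

    id  province  A_1  A_2  C_1  C_2  B_1  B_2  DRB1_1  DRB1_2  DQB1_1  DQB1_2

No missing values are allowed: registry typing is complete at all five loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .nomenclature import (
    LOCI,
    AlleleName,
    AlleleParseError,
    MergeExceptionList,
    default_exceptions,
    parse_allele,
    reduce_to_two_field,
)

REGIONS: tuple[str, ...] = ("NE", "NC", "NW", "EC", "CC", "SC", "SW")

# Province -> region assignment for mainland China's 31 provinces, autonomous
# regions and municipalities, grouped into the seven traditional geographic
# regions from north to south.
DEFAULT_PROVINCE_REGIONS: dict[str, str] = {
    # Northeast
    "Heilongjiang": "NE", "Jilin": "NE", "Liaoning": "NE",
    # North
    "Beijing": "NC", "Tianjin": "NC", "Hebei": "NC", "Shanxi": "NC",
    "Inner Mongolia": "NC",
    # Northwest
    "Xinjiang": "NW", "Qinghai": "NW", "Gansu": "NW", "Ningxia": "NW",
    "Shaanxi": "NW",
    # East
    "Shanghai": "EC", "Shandong": "EC", "Jiangsu": "EC", "Anhui": "EC",
    "Zhejiang": "EC", "Jiangxi": "EC", "Fujian": "EC",
    # Central
    "Henan": "CC", "Hubei": "CC", "Hunan": "CC",
    # South
    "Guangdong": "SC", "Guangxi": "SC", "Hainan": "SC",
    # Southwest
    "Chongqing": "SW", "Tibet": "SW", "Yunnan": "SW", "Sichuan": "SW",
    "Guizhou": "SW",
}

Genotype = dict[str, tuple[AlleleName, AlleleName]]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class RegionPartition:
    """Mapping from province name to region code."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.mapping.values())
        if missing:
            raise CohortError(f"regions with no province: {sorted(missing)}")
        bad = {r for r in self.mapping.values() if r not in REGIONS}
        if bad:
            raise CohortError(f"unknown region codes: {sorted(bad)}")

    def region_of(self, province: str) -> str:
        try:
            return self.mapping[province]
        except KeyError:
            raise CohortError(f"unknown province {province!r}") from None

    def provinces(self, region: str) -> list[str]:
        return sorted(p for p, r in self.mapping.items() if r == region)

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionPartition":
        """Load a partition from YAML (province: region) or two-column TSV."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            return cls(mapping=dict(yaml.safe_load(text)))
        mapping = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            prov, _, region = line.partition("\t")
            mapping[prov.strip()] = region.strip()
        return cls(mapping=mapping)


def default_partition() -> RegionPartition:
    return RegionPartition(mapping=dict(DEFAULT_PROVINCE_REGIONS))


def _canonical_pair(a: AlleleName, b: AlleleName) -> tuple[AlleleName, AlleleName]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Individual:
    id: str
    province: str
    region: str
    genotype: Genotype = field(compare=False)

    def __post_init__(self) -> None:
        if set(self.genotype) != set(LOCI):
            raise CohortError(
                f"individual {self.id!r}: genotype must cover loci {LOCI}"
            )
        fixed = {}
        for locus, pair in self.genotype.items():
            if len(pair) != 2:
                raise CohortError(f"individual {self.id!r}: need two alleles at {locus}")
            for a in pair:
                if a.locus != locus:
                    raise CohortError(
                        f"individual {self.id!r}: allele {a} filed under locus {locus}"
                    )
            fixed[locus] = _canonical_pair(*pair)
        object.__setattr__(self, "genotype", fixed)


@dataclass
class Cohort:
    """An ordered collection of individuals with unique ids."""

    individuals: list[Individual]
    loci: tuple[str, ...] = LOCI

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate individual ids: {dupes[:5]}")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.loci != other.loci or self.n != other.n:
            return False
        return all(
            a.id == b.id and a.province == b.province and a.region == b.region
            and a.genotype == b.genotype
            for a, b in zip(self.individuals, other.individuals)
        )


_HEADER = ["id", "province"] + [f"{locus}_{i}" for locus in LOCI for i in (1, 2)]


def read_cohort(
    path: str | Path,
    partition: Optional[RegionPartition] = None,
    exceptions: Optional[MergeExceptionList] = None,
) -> Cohort:
    """Read a genotype TSV, two-field-reduce every allele, attach regions.

    Errors report the offending row and column.  Row order is preserved.
    """
    partition = partition or default_partition()
    exceptions = exceptions if exceptions is not None else default_exceptions()
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise CohortError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header != _HEADER:
        missing = [c for c in _HEADER if c not in header]
        raise CohortError(f"{path}: bad header; missing columns {missing}")
    individuals = []
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(_HEADER):
            raise CohortError(f"{path}:{row_no}: expected {len(_HEADER)} columns")
        rec = dict(zip(_HEADER, cells))
        region = partition.region_of(rec["province"])
        genotype: Genotype = {}
        for locus in LOCI:
            pair = []
            for i in (1, 2):
                col = f"{locus}_{i}"
                try:
                    a = parse_allele(rec[col], expected_locus=locus)
                except AlleleParseError as e:
                    raise CohortError(f"{path}:{row_no} column {col}: {e}") from e
                pair.append(reduce_to_two_field(a, exceptions))
            genotype[locus] = (pair[0], pair[1])
        individuals.append(
            Individual(id=rec["id"], province=rec["province"], region=region,
                       genotype=genotype)
        )
    return Cohort(individuals=individuals)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    rows = ["\t".join(_HEADER)]
    for ind in cohort:
        cells = [ind.id, ind.province]
        for locus in LOCI:
            a, b = ind.genotype[locus]
            cells += [a.render(), b.render()]
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


def partition_by_region(cohort: Cohort) -> dict[str, Cohort]:
    """Split a cohort into the seven regional sub-cohorts (possibly empty)."""
    buckets: dict[str, list[Individual]] = {r: [] for r in REGIONS}
    for ind in cohort:
        buckets[ind.region].append(ind)
    out = {r: Cohort(individuals=inds) for r, inds in buckets.items()}
    assert sum(c.n for c in out.values()) == cohort.n
    return out


def from_genotypes(
    genotypes: Iterable[Genotype],
    region: str = "NE",
    province: Optional[str] = None,
    id_prefix: str = "d",
) -> Cohort:
    """Build a cohort from bare genotypes (testing / simulation convenience)."""
    if province is None:
        province = default_partition().provinces(region)[0]
    individuals = [
        Individual(id=f"{id_prefix}{i:06d}", province=province, region=region,
                   genotype=g)
        for i, g in enumerate(genotypes)
    ]
    return Cohort(individuals=individuals)
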