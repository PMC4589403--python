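"""Ranked cross-region haplotype comparison and region-specific haplotype calls.

A haplotype is region-specific when its frequency inside one region — or a
small contiguous set of regions — is at least twice its frequency everywhere
else.  Contiguity is judged on the adjacency of the seven geographic regions:

    NE-NC, NC-NW, NC-CC, NC-EC, NW-SW, NW-CC, EC-CC, EC-SC, CC-SC, CC-SW, SC-SW
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import REGIONS
from .haplotype_em import Haplotype, HaplotypeFreqTable, haplotype_label
from .nomenclature import LOCI, AlleleName, parse_allele

ADJACENCY: frozenset[frozenset[str]] = frozenset(
    frozenset(pair)
    for pair in [
        ("NE", "NC"), ("NC", "NW"), ("NC", "CC"), ("NC", "EC"),
        ("NW", "SW"), ("NW", "CC"), ("EC", "CC"), ("EC", "SC"),
        ("CC", "SC"), ("CC", "SW"), ("SC", "SW"),
    ]
)

RATIO_THRESHOLD = 2.0
MAX_SET_SIZE = 3


@dataclass(frozen=True)
class RankedHaplotype:
    haplotype: Haplotype
    national_rank: int
    national_permille: float
    regional: Mapping[str, tuple[int, float]]  # region -> (rank, permille)

    @property
    def label(self) -> str:
        return haplotype_label(self.haplotype)


@dataclass(frozen=True)
class RegionSpecificCall:
    haplotype: Haplotype
    region_set: tuple[str, ...]
    min_inside_permille: float
    max_outside_permille: float
    ratio: float  # inf when no mass outside

    @property
    def label(self) -> str:
        return haplotype_label(self.haplotype)


def _ranked_entries(table: HaplotypeFreqTable) -> list[tuple[Haplotype, float]]:
    return sorted(
        table.entries.items(), key=lambda kv: (-kv[1], haplotype_label(kv[0]))
    )


def rank_table(
    national: HaplotypeFreqTable,
    regional: Mapping[str, HaplotypeFreqTable],
    top_k: int = 20,
) -> list[RankedHaplotype]:
    """The top-k national haplotypes with each one's rank and per mille in
    every region.  A haplotype absent from a region gets frequency 0 and a
    rank just after all the haplotypes present there."""
    for region, table in regional.items():
        if table.loci != national.loci:
            raise ValueError(f"loci mismatch for region {region}")
    regional_ranks: dict[str, dict[Haplotype, int]] = {}
    for region, table in regional.items():
        regional_ranks[region] = {
            hap: rank
            for rank, (hap, _) in enumerate(_ranked_entries(table), start=1)
        }
    out = []
    for rank, (hap, freq) in enumerate(_ranked_entries(national)[:top_k], start=1):
        per_region = {}
        for region in regional:
            table = regional[region]
            f = table.frequency(hap)
            r = regional_ranks[region].get(hap, len(table.entries) + 1)
            per_region[region] = (r, f * 1000.0)
        out.append(
            RankedHaplotype(
                haplotype=hap,
                national_rank=rank,
                national_permille=freq * 1000.0,
                regional=per_region,
            )
        )
    return out


def _contiguous_sets(regions: Sequence[str], max_size: int,
                     adjacency: frozenset[frozenset[str]]):
    """All connected region subsets of size 1..max_size, smaller first,
    deterministic order."""
    def connected(rs: tuple[str, ...]) -> bool:
        if len(rs) == 1:
            return True
        todo = {rs[0]}
        seen = set()
        while todo:
            cur = todo.pop()
            seen.add(cur)
            for other in rs:
                if other not in seen and frozenset((cur, other)) in adjacency:
                    todo.add(other)
        return seen == set(rs)

    for size in range(1, max_size + 1):
        for combo in combinations(sorted(regions), size):
            if connected(combo):
                yield combo


def detect_region_specific(
    ranked: Sequence[RankedHaplotype],
    ratio_threshold: float = RATIO_THRESHOLD,
    max_set_size: int = MAX_SET_SIZE,
    adjacency: frozenset[frozenset[str]] = ADJACENCY,
) -> list[RegionSpecificCall]:
    """Call region-specific haplotypes from a ranked comparison.

    For each haplotype the smallest contiguous region set whose minimum
    inside frequency is at least ``ratio_threshold`` times the maximum
    outside frequency is called (size 1 first); among equal-size qualifying
    sets the one with the highest ratio wins, ties broken lexicographically.
    At most one call per haplotype.  A zero outside frequency gives an
    infinite ratio.
    """
    calls = []
    for rh in ranked:
        regions = list(rh.regional)
        best: Optional[RegionSpecificCall] = None
        best_size = None
        for region_set in _contiguous_sets(regions, max_set_size, adjacency):
            if best_size is not None and len(region_set) > best_size:
                break
            inside = [rh.regional[r][1] for r in region_set]
            outside = [rh.regional[r][1] for r in regions if r not in region_set]
            min_in = min(inside)
            max_out = max(outside) if outside else 0.0
            if max_out == 0.0:
                ratio = math.inf
                qualifies = min_in > 0.0
            else:
                ratio = min_in / max_out
                qualifies = ratio >= ratio_threshold
            if qualifies:
                cand = RegionSpecificCall(
                    haplotype=rh.haplotype,
                    region_set=region_set,
                    min_inside_permille=min_in,
                    max_outside_permille=max_out,
                    ratio=ratio,
                )
                if best is None or cand.ratio > best.ratio:
                    best = cand
                    best_size = len(region_set)
        if best is not None:
            calls.append(best)
    return calls


def ranked_to_frame(ranked: Sequence[RankedHaplotype]) -> pd.DataFrame:
    rows = []
    for rh in ranked:
        row: dict = {locus: a.render() for locus, a in zip(LOCI, rh.haplotype)}
        row["national_rank"] = rh.national_rank
        row["national_permille"] = round(rh.national_permille, 2)
        for region, (rank, permille) in rh.regional.items():
            row[f"{region}_rank"] = rank
            row[f"{region}_permille"] = round(permille, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[RegionSpecificCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "haplotype": c.label,
                "region_set": "+".join(c.region_set),
                "min_inside_permille": c.min_inside_permille,
                "max_outside_permille": c.max_outside_permille,
                "ratio": c.ratio,
            }
            for c in calls
        ]
    )


def load_reference_frequencies() -> pd.DataFrame:
    """The bundled per-region five-locus haplotype frequency reference.

    Columns: ``rank`` (national), the five locus allele columns, ``China``
    and the seven region codes (all per mille).
    """
    with resources.as_file(
        resources.files("hla_popgen.data") / "registry_top_haplotypes.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={locus: str for locus in LOCI})


def reference_ranked_haplotypes() -> list[RankedHaplotype]:
    """The bundled reference as RankedHaplotype records (ranks within the
    reference table itself; regional ranks by regional per mille)."""
    df = load_reference_frequencies()
    haps = [
        tuple(parse_allele(f"{locus}*{row[locus]}") for locus in LOCI)
        for _, row in df.iterrows()
    ]
    regional_rank: dict[str, dict[Haplotype, int]] = {}
    for region in REGIONS:
        order = sorted(
            zip(haps, df[region]), key=lambda kv: (-kv[1], haplotype_label(kv[0]))
        )
        regional_rank[region] = {hap: i + 1 for i, (hap, _) in enumerate(order)}
    out = []
    for hap, (_, row) in zip(haps, df.iterrows()):
        out.append(
            RankedHaplotype(
                haplotype=hap,
                national_rank=int(row["rank"]),
                national_permille=float(row["China"]),
                regional={
                    region: (regional_rank[region][hap], float(row[region]))
                    for region in REGIONS
                },
            )
        )
    return out
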