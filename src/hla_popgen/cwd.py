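"""Common / Well-Documented / Rare (CWD) allele classification.

Operational criteria (following the CWD catalogue convention used by donor
registries):

* **common** — frequency strictly above 0.001 in a reference sample of at
  least 1500 individuals;
* **well-documented** — otherwise, observed at least five times in unrelated
  individuals, or exactly three or four times with every copy residing on the
  same assigned five-locus haplotype;
* **rare** — everything else that was observed;
* **not observed** — zero copies (used for the regional category summaries).

"Sharing a haplotype" is operationalised via each carrier's most likely
EM-assigned five-locus haplotype pair, the only phased context available for
registry data.  All registry donors are treated as unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

from .allele_stats import AlleleFreqTable, allele_frequencies
from .cohort import Cohort, REGIONS
from .haplotype_em import Haplotype
from .nomenclature import LOCI, AlleleName

COMMON_FREQ_THRESHOLD = 0.001
COMMON_MIN_N = 1500
WD_MIN_COPIES = 5
WD_SHARED_COPIES = (3, 4)

CATEGORIES = ("common", "well_documented", "rare", "not_observed")


@dataclass(frozen=True)
class CwdRecord:
    allele: AlleleName
    copies: int
    frequency: float
    category: str
    basis: str

    @property
    def is_cwd(self) -> bool:
        return self.category in ("common", "well_documented")


def classify_alleles(
    freqs: AlleleFreqTable,
    hap_assign: Optional[Sequence[tuple[Haplotype, Haplotype]]] = None,
    n: Optional[int] = None,
) -> list[CwdRecord]:
    """Classify every allele in a frequency table.

    ``hap_assign`` is the per-individual most-likely five-locus haplotype
    pair (same order as the cohort the frequencies came from); without it the
    3-4-copy shared-haplotype rule cannot fire and such alleles fall to rare.
    """
    n = n if n is not None else freqs.n
    locus_pos = LOCI.index(freqs.locus) if freqs.locus in LOCI else None
    # map allele -> set of distinct haplotypes its copies were assigned to
    contexts: dict[AlleleName, set] = {}
    if hap_assign is not None and locus_pos is not None:
        for hap1, hap2 in hap_assign:
            for hap in (hap1, hap2):
                contexts.setdefault(hap[locus_pos], set()).add(hap)
    records = []
    for allele, (copies, frequency) in freqs.entries.items():
        freq = float(frequency)
        if freq > COMMON_FREQ_THRESHOLD and n >= COMMON_MIN_N:
            cat, basis = "common", f"frequency {freq:.5f} > 0.001 in n={n}"
        elif copies >= WD_MIN_COPIES:
            cat, basis = "well_documented", f"{copies} copies in unrelated individuals"
        elif copies in WD_SHARED_COPIES and len(contexts.get(allele, set())) == 1:
            cat = "well_documented"
            basis = f"{copies} copies sharing one assigned haplotype"
        else:
            cat, basis = "rare", f"{copies} copies, no rule fired"
        records.append(CwdRecord(allele, copies, freq, cat, basis))
    return records


def national_summary(records_by_locus: dict[str, list[CwdRecord]]) -> pd.DataFrame:
    """Per-locus counts of common / well-documented alleles and the CWD ratio."""
    rows = []
    for locus, records in records_by_locus.items():
        c = sum(1 for r in records if r.category == "common")
        wd = sum(1 for r in records if r.category == "well_documented")
        total = len(records)
        rows.append(
            {"locus": locus, "C": c, "WD": wd, "Total_CWD": c + wd,
             "n_alleles": total,
             "ratio_pct": round(100.0 * (c + wd) / total, 1) if total else 0.0}
        )
    df = pd.DataFrame(rows)
    totals = {
        "locus": "TOTAL",
        "C": int(df["C"].sum()),
        "WD": int(df["WD"].sum()),
        "Total_CWD": int(df["Total_CWD"].sum()),
        "n_alleles": int(df["n_alleles"].sum()),
    }
    totals["ratio_pct"] = round(100.0 * totals["Total_CWD"] / totals["n_alleles"], 1)
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def _carrier_percent(cohort: Cohort, locus: str, alleles: set[AlleleName]) -> float:
    """Percent of individuals carrying at least one allele of the set."""
    if cohort.n == 0 or not alleles:
        return 0.0
    carriers = sum(
        1 for ind in cohort if any(a in alleles for a in ind.genotype[locus])
    )
    return 100.0 * carriers / cohort.n


def regional_summary(
    regional_cohorts: dict[str, Cohort],
    national_universe: dict[str, set[AlleleName]],
    hap_assign: Optional[dict[str, Sequence]] = None,
) -> pd.DataFrame:
    """Per region x locus category counts against the national allele universe.

    Every nationally observed allele is, per region, CWD / rare (by the
    region's own classification) or not observed; additionally counts
    shared-in-all-regions and unique-in-one-region alleles.  ``sample_pct``
    is the percentage of the region's individuals carrying at least one
    allele of the category.
    """
    presence: dict[str, dict[AlleleName, set[str]]] = {
        locus: {} for locus in national_universe
    }
    per_region: dict[tuple[str, str], dict[AlleleName, CwdRecord]] = {}
    for region, cohort in regional_cohorts.items():
        for locus in national_universe:
            if cohort.n == 0:
                per_region[(region, locus)] = {}
                continue
            freqs = allele_frequencies(cohort, locus)
            assign = hap_assign.get(region) if hap_assign else None
            recs = classify_alleles(freqs, hap_assign=assign, n=cohort.n)
            per_region[(region, locus)] = {r.allele: r for r in recs}
            for allele in freqs.entries:
                presence[locus].setdefault(allele, set()).add(region)

    rows = []
    regions = [r for r in REGIONS if r in regional_cohorts]
    for locus, universe in national_universe.items():
        universe_size = len(universe)
        for region in regions:
            cohort = regional_cohorts[region]
            recs = per_region[(region, locus)]
            cwd = {a for a, r in recs.items() if r.is_cwd}
            rare = {a for a, r in recs.items() if r.category == "rare"}
            not_obs = universe - set(recs)
            assert len(cwd) + len(rare) + len(not_obs) == universe_size
            shared = {
                a for a in universe if presence[locus].get(a, set()) == set(regions)
            }
            unique = {
                a for a in recs if presence[locus].get(a, set()) == {region}
            }
            for cat, members in [
                ("CWD", cwd), ("rare", rare), ("not_observed", not_obs),
                ("shared_in_all_regions", shared & set(recs)),
                ("unique_in_one_region", unique),
            ]:
                rows.append(
                    {
                        "locus": locus,
                        "region": region,
                        "category": cat,
                        "allele_count": len(members),
                        "allele_pct": round(100.0 * len(members) / universe_size, 1)
                        if universe_size else 0.0,
                        "sample_pct": round(
                            _carrier_percent(cohort, locus, members), 2
                        ),
                    }
                )
    return pd.DataFrame(rows)
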