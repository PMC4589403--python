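"""End-to-end orchestration: frequencies -> HWE -> EM/LD -> CWD -> regional
comparison -> matching, from a single configuration, with deterministic seeds
and a run manifest."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .allele_stats import (
    DEFAULT_DEMEM,
    DEFAULT_SEED,
    DEFAULT_STEPS,
    allele_frequencies,
    hwe_exact_test,
)
from .cohort import Cohort, RegionPartition, default_partition, partition_by_region, read_cohort
from .cwd import classify_alleles, national_summary, regional_summary
from .haplotype_em import assign_most_likely_pairs, em_estimate, ld_lrt, report_common
from .matching import matching_matrix
from .nomenclature import LOCI
from .regional import calls_to_frame, detect_region_specific, rank_table, ranked_to_frame

log = logging.getLogger("hla_popgen")

LD_PAIRS = (("A", "C"), ("C", "B"), ("DRB1", "DQB1"))
SIGNIFICANCE_ALPHA = 0.05

# haplotype tables reported by the full pipeline, from locus pairs up to the
# full five-locus haplotype
HAPLOTYPE_SETS: tuple[tuple[str, ...], ...] = (
    ("A", "C"),
    ("C", "B"),
    ("DRB1", "DQB1"),
    ("A", "C", "B"),
    ("A", "C", "B", "DRB1"),
    ("A", "C", "B", "DRB1", "DQB1"),
)


@dataclass
class AnalysisConfig:
    input_path: Optional[str] = None
    partition_path: Optional[str] = None
    seed: int = DEFAULT_SEED
    hwe_steps: int = DEFAULT_STEPS
    hwe_demem: int = DEFAULT_DEMEM
    em_tol: float = 1e-7
    em_max_iter: int = 1000
    em_restarts: int = 3
    ld_n_perm: int = 1000
    report_min_permille: float = 1.0
    top_k: int = 20
    ratio_threshold: float = 2.0
    per_region_em: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_full_analysis(
    cfg: AnalysisConfig, cohort: Optional[Cohort] = None
) -> dict:
    """Run every stage on a cohort (loaded from ``cfg.input_path`` if not
    given).  Returns a bundle of DataFrames plus a run manifest recording
    versions, seeds, and settings; HWE p-values below 0.05 are flagged
    significant."""
    t0 = time.time()
    if cohort is None:
        if cfg.input_path is None:
            raise ValueError("no cohort and no input_path configured")
        partition = (
            RegionPartition.from_file(cfg.partition_path)
            if cfg.partition_path
            else default_partition()
        )
        cohort = read_cohort(cfg.input_path, partition=partition)
    regional_cohorts = partition_by_region(cohort)
    active_regions = [r for r, c in regional_cohorts.items() if c.n > 0]
    for r, c in regional_cohorts.items():
        if c.n == 0:
            log.warning("region %s is empty; regional stages will skip it", r)

    bundle: dict = {}

    # allele frequencies + HWE (national)
    freq_rows = []
    hwe_rows = []
    freq_tables = {}
    for locus in LOCI:
        table = allele_frequencies(cohort, locus)
        freq_tables[locus] = table
        for allele, (copies, frequency) in table.entries.items():
            freq_rows.append(
                {"locus": locus, "allele": allele.render(), "copies": copies,
                 "frequency": round(float(frequency), 5),
                 "permille": round(float(frequency) * 1000, 2)}
            )
        if len(table.entries) == 1:
            log.warning("locus %s is monomorphic", locus)
        res = hwe_exact_test(cohort, locus, steps=cfg.hwe_steps,
                             demem=cfg.hwe_demem, seed=cfg.seed)
        hwe_rows.append(
            {"locus": locus, "p_value": res.p_value, "mc_se": res.mc_se,
             "h_obs": round(res.h_obs, 4), "h_exp": round(res.h_exp, 4),
             "significant": res.p_value < SIGNIFICANCE_ALPHA,
             "method": res.method}
        )
    bundle["allele_frequencies"] = pd.DataFrame(freq_rows)
    bundle["allele_counts"] = pd.DataFrame(
        [{"locus": locus, "n_alleles": len(freq_tables[locus].entries)}
         for locus in LOCI]
    )
    bundle["hwe"] = pd.DataFrame(hwe_rows)
    log.info("allele stats done (%.1fs)", time.time() - t0)

    # EM haplotypes: pairs up to the full five loci nationally, plus the
    # five-locus tables per region
    national_em = None
    for loci_set in HAPLOTYPE_SETS:
        table = em_estimate(cohort, loci_set, tol=cfg.em_tol,
                            max_iter=cfg.em_max_iter,
                            restarts=cfg.em_restarts, seed=cfg.seed)
        name = "haplotypes_" + "_".join(loci_set)
        bundle[name] = report_common(
            table, threshold_permille=cfg.report_min_permille)
        if loci_set == LOCI:
            national_em = table
    bundle["haplotypes_national"] = bundle["haplotypes_" + "_".join(LOCI)]
    regional_em = {}
    for region in active_regions:
        regional_em[region] = em_estimate(
            regional_cohorts[region], LOCI, tol=cfg.em_tol,
            max_iter=cfg.em_max_iter, restarts=cfg.em_restarts, seed=cfg.seed,
        )
    log.info("EM done (%.1fs)", time.time() - t0)

    # LD tests
    ld_rows = []
    for a, b in LD_PAIRS:
        res = ld_lrt(cohort, a, b, n_perm=cfg.ld_n_perm, seed=cfg.seed)
        ld_rows.append(
            {"pair": f"{a}-{b}", "lrt_stat": res.lrt_stat,
             "p_value": res.p_value, "n_perm": res.n_perm,
             "significant": res.p_value < SIGNIFICANCE_ALPHA}
        )
    bundle["ld"] = pd.DataFrame(ld_rows)
    log.info("LD done (%.1fs)", time.time() - t0)

    # CWD classification
    national_assign = assign_most_likely_pairs(national_em, cohort)
    records = {
        locus: classify_alleles(freq_tables[locus], hap_assign=national_assign)
        for locus in LOCI
    }
    bundle["cwd_national"] = national_summary(records)
    universe = {locus: set(freq_tables[locus].entries) for locus in LOCI}
    regional_assign = {
        region: assign_most_likely_pairs(regional_em[region],
                                         regional_cohorts[region])
        for region in active_regions
    }
    bundle["cwd_regional"] = regional_summary(
        {r: regional_cohorts[r] for r in active_regions}, universe,
        hap_assign=regional_assign,
    )
    log.info("CWD done (%.1fs)", time.time() - t0)

    # regional ranked comparison + region-specific calls
    ranked = rank_table(national_em, regional_em, top_k=max(cfg.top_k, 100))
    bundle["ranked_haplotypes"] = ranked_to_frame(ranked[: cfg.top_k])
    calls = detect_region_specific(ranked, ratio_threshold=cfg.ratio_threshold)
    bundle["region_specific_calls"] = calls_to_frame(calls)

    # matching matrix
    matrix = matching_matrix({r: regional_cohorts[r] for r in active_regions})
    bundle["matching_rates"] = matrix.rates.round(7)
    bundle["matching_categories"] = matrix.categories
    log.info("matching done (%.1fs)", time.time() - t0)

    bundle["manifest"] = {
        "package_version": __version__,
        "n_individuals": cohort.n,
        "regions": {r: regional_cohorts[r].n for r in active_regions},
        "seed": cfg.seed,
        "settings": {
            "hwe_steps": cfg.hwe_steps, "hwe_demem": cfg.hwe_demem,
            "em_tol": cfg.em_tol, "em_max_iter": cfg.em_max_iter,
            "em_restarts": cfg.em_restarts, "ld_n_perm": cfg.ld_n_perm,
            "report_min_permille": cfg.report_min_permille,
            "top_k": cfg.top_k, "ratio_threshold": cfg.ratio_threshold,
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t",
                       index=name.startswith("matching"))
        else:
            (out / f"{name}.yaml").write_text(yaml.safe_dump(obj))
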