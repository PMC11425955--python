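"""End-to-end pipeline driver.

Runs phenomics -> GWAS -> linkage -> BSA -> integration on a study (a
synthetic one generated in place, or user-supplied genotype/phenotype
files), writing every intermediate table under an output directory. One
global seed fans out deterministically to per-stage child seeds, so an
identical config + seed reproduces a byte-identical result bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsa as bsa_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import integrate as integrate_mod
from . import linkage as linkage_mod
from . import phenotype as pheno_mod
from . import simulate as sim_mod
from .datatypes import GenotypeData, QtlRecord, SimulationTruth, qtl_records_frame

log = logging.getLogger("csslmap")


@dataclass
class StudyConfig:
    """All pipeline tunables; defaults follow the study design."""

    seed: int = 0
    # synthetic-study shape (used when no input paths are given)
    simulate: bool = True
    n_lines: int = 319
    markers_per_chrom: int = 400
    n_years: int = 2
    n_reps: int = 2
    effect_frac: float = 0.06
    # input paths (optional; override simulation)
    genotype_path: str | None = None
    phenotype_path: str | None = None
    # marker filters
    maf_min: float = 0.05
    missing_max: float = 0.5
    # phenomics
    basis_traits: tuple[str, ...] = sim_mod.BASIS_TRAITS
    grade_cutoffs: tuple[float, float, float, float] | None = None
    # GWAS
    qtl_merge_bp: int = 1_000_000
    flank_bp: int = 300_000
    ld_r2_min: float = 0.8
    # linkage
    p_enter: float = 0.01
    p_exit: float = 0.02
    lod_min: float = 2.5
    cofactor_exclusion_bp: int = 5_000_000
    # BSA
    pool_size: int = 30
    mean_depth: float = 50.0
    window_bp: int = 1_500_000
    step_bp: int = 100_000
    band_level: float = 0.99
    band_sims: int = 10_000
    min_pool_depth: int = 10
    min_window_sites: int = 5  # matched to the default marker density
    run_bsa: bool = True
    # integration
    min_overlap_bp: int = 1


def scan_traits(config: StudyConfig) -> list[str]:
    """Phenotypes scanned by GWAS/linkage: DRC of the basis traits + MFVD."""
    return [f"DRC_{t}" for t in config.basis_traits] + ["MFVD"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recovery_by_method(
    records: list[QtlRecord], truth: SimulationTruth, tol_bp: int = 2_000_000
) -> pd.DataFrame:
    """Distance from every planted QTL to the nearest reported interval,
    per method; recovered = within ``tol_bp``."""
    rows = []
    methods = sorted({r.method for r in records}) or ["gwas", "linkage", "bsa"]
    for q in truth.qtl:
        for m in methods:
            best = np.inf
            best_name = ""
            for r in records:
                if r.method != m or r.chromosome != q.chromosome:
                    continue
                d = max(r.start_bp - q.position_bp, q.position_bp - r.end_bp, 0)
                if d < best:
                    best, best_name = d, r.name
            rows.append(
                {
                    "trait": q.trait,
                    "chromosome": q.chromosome,
                    "position_bp": q.position_bp,
                    "method": m,
                    "distance_bp": best if np.isfinite(best) else np.nan,
                    "nearest_qtl": best_name,
                    "recovered": bool(best <= tol_bp),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    log.info("config: %s", json.dumps(asdict(config), default=str))
    s_sim, s_bsa_depth, s_bsa_band = _child_seeds(config.seed, 3)

    bundle: dict = {"config": config}

    # ---- stage 0: inputs -------------------------------------------------
    study = None
    if config.genotype_path and config.phenotype_path:
        if str(config.genotype_path).endswith(".vcf"):
            geno, _ = io_mod.read_vcf(config.genotype_path)
        else:
            geno = io_mod.read_dosage_tsv(config.genotype_path)
        obs = io_mod.read_observations(config.phenotype_path)
    elif config.simulate:
        study = sim_mod.default_study(
            seed=s_sim,
            n_lines=config.n_lines,
            markers_per_chrom=config.markers_per_chrom,
            n_years=config.n_years,
            n_reps=config.n_reps,
            effect_frac=config.effect_frac,
        )
        geno, obs = study.genotypes, study.observations
        io_mod.write_dosage_tsv(geno, out / "genotypes.tsv")
        io_mod.write_table(obs, out / "phenotypes.tsv")
        io_mod.write_truth(study.truth, out / "truth.yaml")
    else:
        raise ValueError("either provide genotype/phenotype paths or enable simulation")
    bundle["genotypes"], bundle["observations"], bundle["study"] = geno, obs, study

    # ---- stage 1: phenomics ---------------------------------------------
    log.info("phenomics: BLUP + DRC + MFVD on %d observations", len(obs))
    trial = pheno_mod.DroughtTrial(
        obs, basis_traits=config.basis_traits, cutoffs=config.grade_cutoffs
    ).fit()
    bundle["phenomics"] = trial
    blup_flat = trial.blups.copy()
    blup_flat.columns = [f"{t}_{c}" for t, c in blup_flat.columns]
    io_mod.write_table(blup_flat.reset_index(), out / "blups.tsv")
    io_mod.write_table(trial.summaries, out / "trait_summaries.tsv")
    io_mod.write_table(trial.drc.reset_index(), out / "drc.tsv")
    mf = trial.mfvd.copy()
    mf["grade"] = trial.grades.astype(str)
    io_mod.write_table(mf.reset_index(), out / "mfvd.tsv")
    io_mod.write_table(trial.edges, out / "correlation_edges.tsv")

    scores = trial.drc.add_prefix("DRC_")
    scores["MFVD"] = trial.mfvd["mfvd"]

    # ---- stage 2: marker filtering + kinship ----------------------------
    fgeno, freport = gwas_mod.filter_markers(geno, config.maf_min, config.missing_max)
    log.info("marker filter: %s", freport)
    K = gwas_mod.compute_kinship(fgeno)
    suggestive, significant = gwas_mod.association_thresholds(fgeno.n_markers)
    bundle["filtered_genotypes"], bundle["filter_report"] = fgeno, freport
    bundle["kinship"] = K

    all_records: list[QtlRecord] = []

    # ---- stage 3: GWAS ---------------------------------------------------
    gwas_results = {}
    for trait in scan_traits(config):
        y = scores[trait].rename(trait)
        res = gwas_mod.MixedLMM(y, fgeno, kinship=K).fit()
        res.trait = trait
        gwas_results[trait] = res
        io_mod.write_table(res.records, out / f"gwas_{trait}.tsv")
        all_records.extend(res.qtl(trait=trait, p_max=suggestive, merge_bp=config.qtl_merge_bp))
    log.info("GWAS: %d QTL at suggestive p=%.3g", sum(r.method == "gwas" for r in all_records), suggestive)
    bundle["gwas"] = gwas_results

    # ---- stage 4: linkage scan ------------------------------------------
    binmap = linkage_mod.build_bin_map(fgeno)
    io_mod.write_table(binmap.bins, out / "bins.tsv")
    linkage_results = {}
    for trait in scan_traits(config):
        scan = linkage_mod.StepwiseLRTScan(
            binmap,
            scores[trait].rename(trait),
            p_enter=config.p_enter,
            p_exit=config.p_exit,
            exclusion_bp=config.cofactor_exclusion_bp,
        ).fit()
        linkage_results[trait] = scan
        io_mod.write_table(scan.records, out / f"linkage_{trait}.tsv")
        all_records.extend(scan.qtl(trait=trait, lod_min=config.lod_min))
    log.info("linkage: %d QTL at LOD>=%.2f", sum(r.method == "linkage" for r in all_records), config.lod_min)
    bundle["linkage"] = linkage_results

    # ---- stage 5: BSA ----------------------------------------------------
    if config.run_bsa:
        resistant, sensitive = bsa_mod.select_extreme_pools(scores["MFVD"], k=config.pool_size)
        pd.DataFrame(
            {"line_id": resistant + sensitive,
             "pool": ["resistant"] * len(resistant) + ["sensitive"] * len(sensitive)}
        ).to_csv(out / "pools.tsv", sep="\t", index=False)
        depths = sim_mod.simulate_pool_depths(
            geno, resistant, sensitive, mean_depth=config.mean_depth, seed=s_bsa_depth
        )
        io_mod.write_table(depths, out / "pool_depths.tsv")
        bres = bsa_mod.DeltaIndexScan(
            depths,
            pool_size=config.pool_size,
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            level=config.band_level,
            min_depth=config.min_pool_depth,
            min_sites=config.min_window_sites,
            n_sims=config.band_sims,
        ).fit(seed=s_bsa_band)
        io_mod.write_table(bres.windows, out / "bsa_windows.tsv")
        all_records.extend(bres.intervals)
        log.info("BSA: %d intervals beyond the %.0f%% band", len(bres.intervals), 100 * config.band_level)
        bundle["bsa"] = bres
    else:
        log.info("BSA stage skipped (run_bsa=False)")
        bundle["bsa"] = None

    # ---- stage 6: integration -------------------------------------------
    named = integrate_mod.name_qtl(all_records)
    io_mod.write_table(qtl_records_frame(named), out / "qtl_all.tsv")
    io_mod.write_table(io_mod.qtl_to_bed(named), out / "qtl_all.bed.tsv")
    groups, gsummary = integrate_mod.colocalize(named, min_overlap_bp=config.min_overlap_bp)
    grows = []
    for gi, g in enumerate(groups):
        chrom, pos = g.anchor_snp(fgeno)
        grows.append(
            {
                "group": gi,
                "chromosome": g.chromosome,
                "start_bp": g.start_bp,
                "end_bp": g.end_bp,
                "n_records": len(g.records),
                "methods": ",".join(sorted(g.methods)),
                "traits": ",".join(sorted(g.traits)),
                "anchor_chrom": chrom,
                "anchor_pos": pos,
                "members": ";".join(r.name for r in g.records),
            }
        )
    io_mod.write_table(pd.DataFrame(grows), out / "qtl_groups.tsv")
    bundle["qtl"], bundle["groups"], bundle["group_summary"] = named, groups, gsummary
    log.info("co-localization: %s", gsummary)

    # haplotype + pyramiding over multi-method groups (fall back to all
    # groups when few are multi-method)
    hap_groups = [g for g in groups if g.support >= 2] or groups
    hap_records = []
    per_qtl_trait = {}
    for gi, g in enumerate(hap_groups):
        chrom, pos = g.anchor_snp(fgeno)
        best = max(g.records, key=lambda r: r.statistic)
        rec = QtlRecord(
            name=f"group{gi}",
            method="group",
            trait=best.trait,
            chromosome=chrom,
            start_bp=g.start_bp,
            end_bp=g.end_bp,
            peak_bp=pos,
            statistic=best.statistic,
        )
        hap_records.append(rec)
        per_qtl_trait[rec.name] = best.trait if best.trait in scores.columns else "MFVD"
    calls = integrate_mod.classify_haplotypes(fgeno, hap_records)
    io_mod.write_table(calls.reset_index(), out / "haplotype_calls.tsv")
    choices = integrate_mod.choose_resistant_haplotype(calls, scores, per_qtl_trait)
    io_mod.write_table(
        pd.DataFrame([vars(c) for c in choices]), out / "resistant_haplotypes.tsv"
    )
    pyramid = None
    if sum(c.resistant is not None for c in choices) >= 2:
        pyramid = integrate_mod.pyramiding_analysis(calls, choices, scores["MFVD"])
        ptab = pd.concat(
            [pyramid.counts.rename("resistant_locus_count"), scores["MFVD"].rename("mfvd")],
            axis=1,
        )
        io_mod.write_table(ptab.reset_index(), out / "pyramiding.tsv")
        log.info("pyramiding: r=%.3f p=%.3g over %d QTL", pyramid.r, pyramid.p, pyramid.n_qtl_scored)
    bundle["haplotype_calls"], bundle["haplotype_choices"], bundle["pyramiding"] = calls, choices, pyramid

    # ---- recovery metrics (synthetic studies only) -----------------------
    if study is not None:
        rec = recovery_by_method(named, study.truth)
        io_mod.write_table(rec, out / "recovery.tsv")
        bundle["recovery"] = rec
        log.info(
            "recovery: %s",
            rec.groupby("method")["recovered"].sum().to_dict(),
        )
    return bundle
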