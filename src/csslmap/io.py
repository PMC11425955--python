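"""File formats and conversions.

Positions are 1-based inclusive everywhere inside the package; BED-like
output intervals are 0-based half-open (converted here, tested both ways).
VCFs are written as plain text with GT and AD fields and read back through
cyvcf2; dosage coding against the named donor/recurrent parent samples
happens at read time, so externally produced bi-parental VCFs work too.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING, GenotypeData, QtlRecord, SimulationTruth, recompute_marker_stats

FLOAT_FMT = "%.10g"

DONOR_DEFAULT = "3-79"
RECURRENT_DEFAULT = "E22"


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    geno: GenotypeData,
    path: str | Path,
    donor: str = DONOR_DEFAULT,
    recurrent: str = RECURRENT_DEFAULT,
    include_parents: bool = True,
    nominal_depth: int = 30,
) -> None:
    """Write the dosage matrix as a diploid VCF.

    REF is the recurrent-parent allele, ALT the donor allele. AD carries a
    nominal GT-consistent depth (real sampled depths exist only for pools).
    Parent samples are appended so the file is self-describing for
    bi-parental recoding on read.
    """
    half = nominal_depth // 2
    gt_ad = {
        0: (f"0/0:{nominal_depth},0"),
        1: (f"0/1:{half},{half}"),
        2: (f"1/1:0,{nominal_depth}"),
        MISSING: "./.:.,.",
    }
    samples = list(geno.line_ids) + ([recurrent, donor] if include_parents else [])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=csslmap\n")
        for chrom in dict.fromkeys(geno.info["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        m = geno.matrix
        for j in range(geno.n_markers):
            row = geno.info.iloc[j]
            fields = [
                str(row["chromosome"]),
                str(int(row["position_bp"])),
                str(row["marker_id"]),
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            fields += [gt_ad[int(v)] for v in m[:, j]]
            if include_parents:
                fields += [gt_ad[0], gt_ad[2]]
            fh.write("\t".join(fields) + "\n")


def read_vcf(
    path: str | Path,
    donor: str = DONOR_DEFAULT,
    recurrent: str = RECURRENT_DEFAULT,
) -> tuple[GenotypeData, dict]:
    """Read a VCF into donor-dosage coding.

    The donor allele at each site is the allele carried homozygously by the
    donor parent sample; sites where the parents are not homozygous for
    different alleles are dropped (reported). GT ./. maps to missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in (donor, recurrent):
        if p not in samples:
            raise ValueError(f"parent sample {p!r} absent from VCF")
    di, ri = samples.index(donor), samples.index(recurrent)
    line_idx = [i for i, s in enumerate(samples) if s not in (donor, recurrent)]
    line_ids = [samples[i] for i in line_idx]

    rows, cols = [], []
    n_dropped = 0
    for var in vcf:
        g = var.genotype.array()[:, :2]
        dg, rg = g[di], g[ri]
        if (dg < 0).any() or (rg < 0).any() or dg[0] != dg[1] or rg[0] != rg[1] or dg[0] == rg[0]:
            n_dropped += 1
            continue
        donor_allele = dg[0]
        sub = g[line_idx]
        dosage = np.where(
            (sub < 0).any(axis=1), MISSING, (sub == donor_allele).sum(axis=1)
        ).astype(np.int8)
        rows.append(
            {
                "marker_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                "chromosome": var.CHROM,
                "position_bp": int(var.POS),
            }
        )
        cols.append(dosage)
    if not rows:
        raise ValueError("no parent-informative sites in VCF")
    info = pd.DataFrame(rows)
    matrix = np.column_stack(cols)
    maf, miss = recompute_marker_stats(matrix)
    info["maf"] = maf
    info["missing_rate"] = miss
    return GenotypeData(matrix, info, line_ids), {
        "n_sites": len(rows),
        "n_parent_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# dosage / table TSVs


def write_dosage_tsv(geno: GenotypeData, path: str | Path) -> None:
    """Markers as rows: marker_id, chromosome, position_bp, then one
    dosage column per line (donor-allele count; NA missing)."""
    m = geno.matrix.astype(float)
    m[geno.matrix == MISSING] = np.nan
    df = pd.concat(
        [
            geno.info[["marker_id", "chromosome", "position_bp"]],
            pd.DataFrame(m.T, columns=geno.line_ids, index=geno.info.index),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def read_dosage_tsv(path: str | Path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t")
    meta = ["marker_id", "chromosome", "position_bp"]
    line_ids = [c for c in df.columns if c not in meta]
    m = df[line_ids].to_numpy(float).T
    matrix = np.where(np.isnan(m), MISSING, m).astype(np.int8)
    info = df[meta].copy()
    maf, miss = recompute_marker_stats(matrix)
    info["maf"] = maf
    info["missing_rate"] = miss
    return GenotypeData(matrix, info, line_ids)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path, sep="\t")
    need = {"line_id", "trait", "condition", "year", "replicate", "value"}
    if not need.issubset(obs.columns):
        raise ValueError(f"phenotype table must have columns {sorted(need)}")
    return obs


# ---------------------------------------------------------------------------
# BED-like interval conversion (internal 1-based inclusive <-> 0-based half-open)


def qtl_to_bed(records: list[QtlRecord]) -> pd.DataFrame:
    """QTL records as a BED-like frame (0-based half-open start/end)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chromosome,
                "chromStart": r.start_bp - 1,
                "chromEnd": r.end_bp,
                "name": r.name,
                "score": r.statistic,
                "method": r.method,
                "trait": r.trait,
                "peak_pos0": r.peak_bp - 1,
            }
            for r in records
        ]
    )


def bed_to_qtl(df: pd.DataFrame) -> list[QtlRecord]:
    """Inverse of :func:`qtl_to_bed`."""
    return [
        QtlRecord(
            name=str(row["name"]),
            method=str(row["method"]),
            trait=str(row["trait"]),
            chromosome=str(row["chrom"]),
            start_bp=int(row["chromStart"]) + 1,
            end_bp=int(row["chromEnd"]),
            peak_bp=int(row["peak_pos0"]) + 1,
            statistic=float(row["score"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# truth / config


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "qtl": [
            {
                "chromosome": q.chromosome,
                "position_bp": q.position_bp,
                "trait": q.trait,
                "effect_control": q.effect_control,
                "effect_drought": q.effect_drought,
            }
            for q in truth.qtl
        ],
        "variance_components": truth.variance_components,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth(path: str | Path) -> SimulationTruth:
    from .datatypes import QtlEffect

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return SimulationTruth(
        qtl=[QtlEffect(**q) for q in payload["qtl"]],
        variance_components=payload["variance_components"],
        seed=int(payload["seed"]),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg
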