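"""Cross-method QTL integration and haplotype pyramiding.

Brings the three mapping strategies together: a shared naming convention
(q.<TRAIT>.<Chr>.<ordinal>), single-linkage co-localization of intervals,
haplotype classification of every line at each QTL's highlighted SNP
(donor-parent vs recurrent-parent state), selection of the
drought-resistant haplotype by the larger mean DRC, and the pyramiding
analysis — does carrying more resistant haplotypes raise a line's MFVD?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeData, QtlRecord

__all__ = [
    "name_qtl",
    "QtlGroup",
    "colocalize",
    "classify_haplotypes",
    "choose_resistant_haplotype",
    "HaplotypeChoice",
    "pyramiding_analysis",
    "PyramidingSummary",
]

HAP_DONOR = "hap_donor"
HAP_RECURRENT = "hap_recurrent"
HET = "het"
UNKNOWN = "unknown"


def name_qtl(records: list[QtlRecord]) -> list[QtlRecord]:
    """Assign names q.<TRAIT>.<Chr>.<k>, k the 1-based positional ordinal
    of the record among its trait's records on that chromosome. Idempotent:
    existing names are recomputed from scratch."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].trait, records[i].chromosome, records[i].start_bp, records[i].peak_bp),
    )
    counters: dict[tuple[str, str], int] = {}
    named: list[QtlRecord | None] = [None] * len(records)
    for i in order:
        r = records[i]
        key = (r.trait, r.chromosome)
        counters[key] = counters.get(key, 0) + 1
        named[i] = QtlRecord(
            name=f"q.{r.trait}.{r.chromosome}.{counters[key]}",
            method=r.method,
            trait=r.trait,
            chromosome=r.chromosome,
            start_bp=r.start_bp,
            end_bp=r.end_bp,
            peak_bp=r.peak_bp,
            statistic=r.statistic,
        )
    return [r for r in named if r is not None]


@dataclass
class QtlGroup:
    """One co-localization group (a connected overlap component)."""

    chromosome: str
    records: list[QtlRecord]
    start_bp: int
    end_bp: int

    @property
    def methods(self) -> set[str]:
        return {r.method for r in self.records}

    @property
    def traits(self) -> set[str]:
        return {r.trait for r in self.records}

    @property
    def support(self) -> int:
        return len(self.methods)

    def anchor_snp(self, geno: GenotypeData | None = None) -> tuple[str, int]:
        """Highlighted SNP for haplotyping: the best GWAS peak if the group
        has one, else the genotyped marker nearest the group's peak
        midpoint."""
        gwas = [r for r in self.records if r.method == "gwas"]
        if gwas:
            best = max(gwas, key=lambda r: r.statistic)
            return best.chromosome, best.peak_bp
        mid = int(np.mean([r.peak_bp for r in self.records]))
        if geno is not None:
            sub = geno.info[geno.info["chromosome"] == self.chromosome]
            if len(sub):
                j = (sub["position_bp"] - mid).abs().idxmin()
                return self.chromosome, int(geno.info.loc[j, "position_bp"])
        return self.chromosome, mid


def colocalize(
    records: list[QtlRecord], min_overlap_bp: int = 1
) -> tuple[list[QtlGroup], dict]:
    """Single-linkage grouping of same-chromosome intervals that overlap by
    at least ``min_overlap_bp``. Groups partition the records; the summary
    counts groups supported by >= 2 and exactly 3 distinct methods."""
    groups: list[QtlGroup] = []
    by_chrom: dict[str, list[QtlRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start_bp, r.end_bp))
        current: list[QtlRecord] = []
        reach = -1
        for r in recs:
            if current and r.start_bp <= reach - min_overlap_bp + 1:
                current.append(r)
                reach = max(reach, r.end_bp)
            else:
                if current:
                    groups.append(
                        QtlGroup(
                            chromosome=chrom,
                            records=current,
                            start_bp=min(x.start_bp for x in current),
                            end_bp=max(x.end_bp for x in current),
                        )
                    )
                current = [r]
                reach = r.end_bp
        if current:
            groups.append(
                QtlGroup(
                    chromosome=chrom,
                    records=current,
                    start_bp=min(x.start_bp for x in current),
                    end_bp=max(x.end_bp for x in current),
                )
            )
    summary = {
        "n_records": len(records),
        "n_groups": len(groups),
        "n_ge2_methods": sum(1 for g in groups if g.support >= 2),
        "n_eq3_methods": sum(1 for g in groups if g.support == 3),
    }
    return groups, summary


def classify_haplotypes(
    geno: GenotypeData, qtl: list[QtlRecord], snp_overrides: dict[str, tuple[str, int]] | None = None
) -> pd.DataFrame:
    """Haplotype call of every line at each QTL's highlighted SNP.

    Dosage 2 -> hap_donor, 0 -> hap_recurrent, 1 -> het, missing -> unknown.
    ``snp_overrides`` maps QTL name -> (chromosome, position) to anchor a
    QTL on a different SNP (e.g. a co-localized group's GWAS peak). A QTL
    whose SNP is not genotyped yields all-unknown calls with a warning.
    """
    out = {}
    overrides = snp_overrides or {}
    code_map = {0: HAP_RECURRENT, 1: HET, 2: HAP_DONOR, MISSING: UNKNOWN}
    for r in qtl:
        chrom, pos = overrides.get(r.name, (r.chromosome, r.peak_bp))
        hit = geno.info[
            (geno.info["chromosome"] == chrom) & (geno.info["position_bp"] == pos)
        ]
        if hit.empty:
            warnings.warn(f"highlighted SNP {chrom}:{pos} for {r.name} not genotyped")
            out[r.name] = pd.Series(UNKNOWN, index=geno.line_ids)
            continue
        col = geno.matrix[:, hit.index[0]]
        out[r.name] = pd.Series([code_map[int(v)] for v in col], index=geno.line_ids)
    calls = pd.DataFrame(out)
    calls.index.name = "line_id"
    return calls


@dataclass
class HaplotypeChoice:
    """Which haplotype is drought-resistant at one QTL, with the contrast."""

    qtl_name: str
    trait: str
    resistant: str | None  # hap_donor / hap_recurrent / None if unscorable
    mean_donor: float
    mean_recurrent: float
    n_donor: int
    n_recurrent: int
    p_value: float
    note: str = ""


def choose_resistant_haplotype(
    calls: pd.DataFrame,
    scores: pd.DataFrame | pd.Series,
    per_qtl_trait: dict[str, str] | None = None,
) -> list[HaplotypeChoice]:
    """Label the haplotype with the larger mean DRC (or MFVD) as resistant.

    ``scores`` is the per-line DRC table (columns = traits) or a single
    score Series used for every QTL; ``per_qtl_trait`` maps QTL name ->
    trait column. Heterozygous and unknown calls are excluded; a QTL with
    an empty group is flagged unscorable; an exact tie gets no label.
    The contrast p-value is Welch's two-sided t test.
    """
    choices: list[HaplotypeChoice] = []
    for q in calls.columns:
        if isinstance(scores, pd.Series):
            trait = str(scores.name or "score")
            s = scores
        else:
            trait = (per_qtl_trait or {}).get(q)
            if trait is None or trait not in scores.columns:
                choices.append(
                    HaplotypeChoice(q, trait or "?", None, np.nan, np.nan, 0, 0, np.nan, "no trait mapping")
                )
                continue
            s = scores[trait]
        c = calls[q]
        donor = s[(c == HAP_DONOR) & s.notna()]
        recur = s[(c == HAP_RECURRENT) & s.notna()]
        if len(donor) == 0 or len(recur) == 0:
            choices.append(
                HaplotypeChoice(q, trait, None, np.nan, np.nan, len(donor), len(recur), np.nan, "empty group")
            )
            continue
        md, mr = float(donor.mean()), float(recur.mean())
        if len(donor) > 1 and len(recur) > 1:
            _, p = stats.ttest_ind(donor, recur, equal_var=False)
            p = float(p)
        else:
            p = np.nan
        if md == mr:
            label, note = None, "tie"
        else:
            label, note = (HAP_DONOR, "") if md > mr else (HAP_RECURRENT, "")
        choices.append(HaplotypeChoice(q, trait, label, md, mr, len(donor), len(recur), p, note))
    return choices


@dataclass
class PyramidingSummary:
    """Per-line resistant-locus counts and their relation to MFVD."""

    counts: pd.Series
    r: float
    p: float
    n_qtl_scored: int
    full_stack_lines: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Pyramiding analysis",
            f"  QTL scored: {self.n_qtl_scored}",
            f"  resistant-locus count vs MFVD: r={self.r:.3f}, p={self.p:.3g}",
            f"  lines stacking every resistant haplotype: {len(self.full_stack_lines)}",
        ]
        if self.full_stack_lines:
            lines.append("    " + ", ".join(self.full_stack_lines[:10]))
        return "\n".join(lines)


def pyramiding_analysis(
    calls: pd.DataFrame,
    choices: list[HaplotypeChoice],
    mfvd: pd.Series,
) -> PyramidingSummary:
    """Count resistant haplotypes per line and correlate with MFVD.

    Only QTL with a chosen resistant label contribute; het/unknown calls do
    not count. Pearson r is NaN-flagged when the counts are constant.
    """
    scored = [c for c in choices if c.resistant is not None]
    if len(scored) < 2:
        raise ValueError("need at least 2 scorable QTL for pyramiding")
    counts = pd.Series(0, index=calls.index, dtype=int)
    for c in scored:
        counts += (calls[c.qtl_name] == c.resistant).astype(int)
    joined = pd.concat([counts.rename("count"), mfvd.rename("mfvd")], axis=1).dropna()
    if joined["count"].nunique() < 2 or joined["mfvd"].nunique() < 2:
        warnings.warn("constant counts or scores: correlation undefined")
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(joined["count"], joined["mfvd"])
    full = counts.index[counts == len(scored)].tolist()
    return PyramidingSummary(
        counts=counts,
        r=float(r),
        p=float(p),
        n_qtl_scored=len(scored),
        full_stack_lines=full,
    )
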