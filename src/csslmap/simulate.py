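"""Synthetic CSSL study generator.

Generates complete drought-trial studies — introgression-segment genotypes,
condition-dependent phenotypes, and pooled sequencing depths — with known
ground truth, so every downstream stage (phenomics scoring, GWAS, linkage
scan, BSA) can be exercised and its recovery measured without external data.

The default study mirrors a real interspecific introgression experiment at
reduced marker density: 319 lines over 26 chromosomes (~10 400 markers),
14 traits scored under control and drought irrigation in 2 years x 2
replicates, and 30 + 30 extreme pools sequenced at mean depth 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    MISSING,
    ChromosomeMap,
    GenotypeData,
    QtlEffect,
    Segment,
    SegmentAssignment,
    SimulationTruth,
    recompute_marker_stats,
)

# ---------------------------------------------------------------------------
# study-shape defaults

#: 13 A-subgenome + 13 D-subgenome chromosomes, 80 Mb each
DEFAULT_CHROMOSOMES: tuple[ChromosomeMap, ...] = tuple(
    ChromosomeMap(f"{sub}{i:02d}", 80_000_000)
    for sub in ("A", "D")
    for i in range(1, 14)
)

#: trait -> (control mean, drought mean); units follow field convention
#: (cm, days, counts, g, %, mm, cN/tex, micronaire units)
TRAIT_MEANS: dict[str, tuple[float, float]] = {
    "PH": (65.507, 37.541),
    "FT": (60.0, 58.0),
    "WGP": (131.665, 128.522),
    "FFSH": (20.0, 16.0),
    "FFSBN": (6.0, 5.2),
    "FSBN": (7.804, 4.999),
    "EBN": (5.539, 2.997),
    "BW": (5.293, 5.215),
    "LW": (2.420, 2.375),
    "LP": (39.0, 39.5),
    "FUHML": (26.973, 26.427),
    "FU": (83.829, 83.507),
    "FS": (25.985, 26.301),
    "MV": (4.633, 5.405),
}

TRAITS: tuple[str, ...] = tuple(TRAIT_MEANS)

#: the 8 yield + fiber-quality traits whose DRC feeds the composite score
BASIS_TRAITS: tuple[str, ...] = ("BW", "LW", "LP", "EBN", "FUHML", "FS", "MV", "FU")

#: traits carrying a planted condition-specific QTL in the default study
DEFAULT_QTL_TRAITS: tuple[str, ...] = ("BW", "LW", "FUHML", "FS", "FU")

# variance components as coefficients of variation on the control mean
GENETIC_CV = 0.02
YEAR_CV = 0.01
REP_CV = 0.005
RESIDUAL_CV = 0.03


def default_variance_components(traits=TRAITS) -> dict[str, dict[str, float]]:
    comps = {}
    for t in traits:
        mc = TRAIT_MEANS[t][0]
        comps[t] = {
            "genetic": (GENETIC_CV * mc) ** 2,
            "year": (YEAR_CV * mc) ** 2,
            "rep": (REP_CV * mc) ** 2,
            "residual": (RESIDUAL_CV * mc) ** 2,
        }
    return comps


# ---------------------------------------------------------------------------
# genotypes


def _marker_positions(length_bp: int, n_markers: int) -> np.ndarray:
    """Evenly spaced 1-based positions, strictly increasing."""
    pos = np.linspace(1, length_bp, n_markers).round().astype(np.int64)
    # guard against rounding collisions on tiny chromosomes
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if len(pos) and pos[-1] > length_bp:
        raise ValueError("too many markers for chromosome length")
    return pos


@dataclass
class SegmentSpec:
    """Distributional spec for per-line donor segments.

    ``mean_segments`` is the mean count (>=1 enforced per line);
    ``mean_length_bp`` the exponential mean length; lengths are clipped to
    ``[min_length_bp, chromosome length]``; the per-line donor fraction is
    capped at ``donor_cap`` by dropping excess segments.
    """

    mean_segments: float = 4.0
    mean_length_bp: float = 30_000_000.0
    min_length_bp: int = 2_000_000
    donor_cap: float = 0.10
    het_fraction: float = 0.0  # probability a segment is heterozygous

    def __post_init__(self) -> None:
        if not 0 < self.donor_cap <= 1:
            raise ValueError("donor_cap must be in (0, 1]")
        if self.mean_segments * self.mean_length_bp <= 0:
            raise ValueError("segment spec must be positive")


def simulate_cssl_genotypes(
    chrom_map: list[ChromosomeMap] | tuple[ChromosomeMap, ...],
    n_lines: int,
    markers_per_chrom: int,
    segment_spec: SegmentSpec | None = None,
    seed: int = 0,
    missing_rate: float = 0.01,
) -> tuple[GenotypeData, list[SegmentAssignment]]:
    """Draw introgression segments and code the marker dosage matrix.

    Every marker inside a line's donor segment is coded per the segment
    dosage (2 hom donor / 1 het); all other markers are 0 (recurrent
    homozygote). Segment endpoints snap to marker positions. Missing
    genotypes are injected at ``missing_rate`` to exercise downstream
    filters.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if markers_per_chrom < 2:
        raise ValueError("need at least 2 markers per chromosome")
    spec = segment_spec or SegmentSpec()
    chroms = list(chrom_map)
    names = [c.name for c in chroms]
    if len(set(names)) != len(names):
        raise ValueError("chromosome names must be unique")
    genome_bp = sum(c.length_bp for c in chroms)
    expected_per_line = spec.mean_segments * min(
        spec.mean_length_bp, max(c.length_bp for c in chroms)
    )
    if expected_per_line > spec.donor_cap * genome_bp * 3:
        raise ValueError("segment spec exceeds the donor-fraction cap by far")

    rng = np.random.default_rng(seed)
    positions = {c.name: _marker_positions(c.length_bp, markers_per_chrom) for c in chroms}
    chrom_offsets = {}
    off = 0
    for c in chroms:
        chrom_offsets[c.name] = off
        off += markers_per_chrom
    n_markers = off

    matrix = np.zeros((n_lines, n_markers), dtype=np.int8)
    assignments: list[SegmentAssignment] = []
    digits = max(3, len(str(n_lines)))
    for i in range(n_lines):
        line_id = f"M{i + 1:0{digits}d}"
        n_seg = max(1, rng.poisson(max(spec.mean_segments - 1, 0.0)) + 1)
        segs: list[Segment] = []
        occupied: dict[str, list[tuple[int, int]]] = {}
        donor_total = 0
        attempts = 0
        while len(segs) < n_seg and attempts < 20 * n_seg:
            attempts += 1
            c = chroms[rng.integers(len(chroms))]
            length = float(rng.exponential(spec.mean_length_bp))
            length = int(min(max(length, spec.min_length_bp), c.length_bp))
            start = int(rng.integers(1, c.length_bp - length + 2))
            end = start + length - 1
            # snap endpoints to marker positions
            pos = positions[c.name]
            lo = int(pos[np.argmin(np.abs(pos - start))])
            hi = int(pos[np.argmin(np.abs(pos - end))])
            if hi < lo:
                lo, hi = hi, lo
            if any(not (hi < s or lo > e) for s, e in occupied.get(c.name, [])):
                continue
            if donor_total + (hi - lo + 1) > spec.donor_cap * genome_bp:
                break
            dosage = 1 if rng.random() < spec.het_fraction else 2
            segs.append(Segment(c.name, lo, hi, dosage))
            occupied.setdefault(c.name, []).append((lo, hi))
            donor_total += hi - lo + 1
        assignments.append(SegmentAssignment(line_id, sorted(segs, key=lambda s: (s.chromosome, s.start_bp))))
        for s in segs:
            pos = positions[s.chromosome]
            j0 = chrom_offsets[s.chromosome]
            inside = (pos >= s.start_bp) & (pos <= s.end_bp)
            matrix[i, j0 + np.flatnonzero(inside)] = s.dosage

    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        matrix[mask] = MISSING

    info = pd.DataFrame(
        {
            "marker_id": [
                f"{c.name}_{p}" for c in chroms for p in positions[c.name]
            ],
            "chromosome": np.repeat(names, markers_per_chrom),
            "position_bp": np.concatenate([positions[c.name] for c in chroms]),
        }
    )
    maf, miss = recompute_marker_stats(matrix)
    info["maf"] = maf
    info["missing_rate"] = miss
    geno = GenotypeData(matrix, info, [a.line_id for a in assignments])
    return geno, assignments


def truth_dosage(
    assignments: list[SegmentAssignment], chromosome: str, position_bp: int
) -> np.ndarray:
    """Uncorrupted dosage of every line at a position, from the segments."""
    out = np.zeros(len(assignments), dtype=np.int8)
    for i, a in enumerate(assignments):
        for s in a.segments:
            if s.chromosome == chromosome and s.start_bp <= position_bp <= s.end_bp:
                out[i] = s.dosage
                break
    return out


# ---------------------------------------------------------------------------
# phenotypes


def default_truth(
    geno: GenotypeData,
    assignments: list[SegmentAssignment],
    seed: int,
    qtl_traits: tuple[str, ...] = DEFAULT_QTL_TRAITS,
    effect_frac: float = 0.06,
    freq_window: tuple[float, float] = (0.08, 0.35),
) -> SimulationTruth:
    """Plant one drought-specific QTL per designated trait.

    Positions are chosen at existing markers, spread across the genome, at
    loci whose realized donor-homozygote frequency falls inside
    ``freq_window`` so that every planted QTL actually segregates (and
    survives the MAF filter). The per-allele drought effect is
    ``effect_frac`` x the trait's control mean; the control effect is 0 —
    the QTL exist only as drought-resistance loci.
    """
    chrom_names = list(dict.fromkeys(geno.info["chromosome"]))
    step = max(1, len(chrom_names) // len(qtl_traits))
    qtl: list[QtlEffect] = []
    for k, trait in enumerate(qtl_traits):
        cname = chrom_names[(k * step + 2) % len(chrom_names)]
        sub = geno.info[geno.info["chromosome"] == cname].reset_index(drop=True)
        pos = sub["position_bp"].to_numpy()
        freqs = np.array(
            [
                (truth_dosage(assignments, cname, int(p)) == 2).mean()
                for p in pos
            ]
        )
        mid = pos[len(pos) // 2]
        ok = np.flatnonzero((freqs >= freq_window[0]) & (freqs <= freq_window[1]))
        if len(ok):
            j = ok[np.argmin(np.abs(pos[ok] - mid))]
        else:  # fall back to the locus closest to the window centre
            j = int(np.argmin(np.abs(freqs - np.mean(freq_window))))
        qtl.append(
            QtlEffect(
                chromosome=cname,
                position_bp=int(pos[j]),
                trait=trait,
                effect_control=0.0,
                effect_drought=effect_frac * TRAIT_MEANS[trait][0],
            )
        )
    return SimulationTruth(
        qtl=qtl, variance_components=default_variance_components(), seed=seed
    )


def simulate_phenotypes(
    assignments: list[SegmentAssignment],
    truth: SimulationTruth,
    n_years: int = 2,
    n_reps: int = 2,
    traits: tuple[str, ...] = TRAITS,
    trait_means: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the long-format trial table.

    value = trait-condition mean + sum(QTL dosage x condition effect)
            + polygenic line effect + year effect + rep-within-year effect
            + residual,
    with year/rep effects shared across lines (they are environmental) and
    the polygenic line effect shared across conditions and years.
    """
    means = trait_means or TRAIT_MEANS
    for q in truth.qtl:
        if q.trait not in traits:
            raise ValueError(f"QTL trait {q.trait!r} not in the trait list")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_lines = len(assignments)
    line_ids = [a.line_id for a in assignments]

    qtl_dosage = {
        (q.trait, q.chromosome, q.position_bp): truth_dosage(
            assignments, q.chromosome, q.position_bp
        )
        for q in truth.qtl
    }

    rows = {k: [] for k in ("line_id", "trait", "condition", "year", "replicate", "value")}
    years = [2018 + y for y in range(n_years)]
    for trait in traits:
        comps = truth.variance_components[trait]
        sd_g, sd_y, sd_r, sd_e = (
            np.sqrt(comps["genetic"]),
            np.sqrt(comps["year"]),
            np.sqrt(comps["rep"]),
            np.sqrt(comps["residual"]),
        )
        g = rng.normal(0.0, sd_g, n_lines) if sd_g > 0 else np.zeros(n_lines)
        qtl_part = {c: np.zeros(n_lines) for c in CONDITIONS}
        for q in truth.qtl:
            if q.trait != trait:
                continue
            d = qtl_dosage[(q.trait, q.chromosome, q.position_bp)].astype(float)
            qtl_part["control"] += d * q.effect_control
            qtl_part["drought"] += d * q.effect_drought
        for ci, cond in enumerate(CONDITIONS):
            mu = means[trait][ci]
            for y in years:
                ye = rng.normal(0.0, sd_y) if sd_y > 0 else 0.0
                for r in range(1, n_reps + 1):
                    re_ = rng.normal(0.0, sd_r) if sd_r > 0 else 0.0
                    eps = rng.normal(0.0, sd_e, n_lines) if sd_e > 0 else np.zeros(n_lines)
                    vals = mu + qtl_part[cond] + g + ye + re_ + eps
                    rows["line_id"].extend(line_ids)
                    rows["trait"].extend([trait] * n_lines)
                    rows["condition"].extend([cond] * n_lines)
                    rows["year"].extend([y] * n_lines)
                    rows["replicate"].extend([r] * n_lines)
                    rows["value"].extend(vals.tolist())
    return pd.DataFrame(rows)


def simulate_polygenic_phenotype(
    geno: GenotypeData, h2: float, seed: int
) -> np.ndarray:
    """A purely polygenic (no major QTL) line-level phenotype.

    Every marker contributes a small normal effect; the total is rescaled so
    the realized genetic fraction of variance equals ``h2``. Used for null
    calibration of the association scan.
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    w = np.where(geno.matrix == MISSING, 0, geno.matrix).astype(float)
    w -= w.mean(axis=0)
    b = rng.normal(0.0, 1.0, geno.n_markers)
    gv = w @ b
    sg = gv.std()
    if sg > 0 and h2 > 0:
        gv *= np.sqrt(h2) / sg
    e = rng.normal(0.0, np.sqrt(1.0 - h2), geno.n_lines)
    return gv + e


# ---------------------------------------------------------------------------
# pooled depths


def simulate_pool_depths(
    geno: GenotypeData,
    pool_a: list[str],
    pool_b: list[str],
    mean_depth: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially sampled pooled read depths for two extreme pools.

    Per site the pool donor-allele frequency is the mean dosage / 2 over the
    pool's (non-missing) members; read depth is Poisson(mean_depth) and the
    donor-read count Binomial(depth, frequency), independently per pool.
    Returns a table with one row per site and read counts for pools "a"
    (resistant by convention) and "b" (sensitive).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    sa, sb = set(pool_a), set(pool_b)
    if not sa or not sb:
        raise ValueError("pools must be non-empty")
    if sa & sb:
        raise ValueError("pools must be disjoint")
    rng = np.random.default_rng(seed)
    idx = {lid: i for i, lid in enumerate(geno.line_ids)}
    rows_a = [idx[l] for l in pool_a]
    rows_b = [idx[l] for l in pool_b]

    out = {"chromosome": geno.info["chromosome"].to_numpy(),
           "position_bp": geno.info["position_bp"].to_numpy()}
    for label, rows in (("a", rows_a), ("b", rows_b)):
        sub = geno.matrix[rows, :].astype(float)
        obs = sub != MISSING
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, sub, 0.0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
        depth = rng.poisson(mean_depth, geno.n_markers)
        donor = rng.binomial(depth, freq)
        out[f"donor_reads_{label}"] = donor
        out[f"recurrent_reads_{label}"] = depth - donor
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# the bundled default study


@dataclass
class CsslStudy:
    """A complete synthetic study with its ground truth."""

    chrom_map: tuple[ChromosomeMap, ...]
    genotypes: GenotypeData
    assignments: list[SegmentAssignment]
    truth: SimulationTruth
    observations: pd.DataFrame
    seed: int
    n_years: int = 2
    n_reps: int = 2
    extras: dict = field(default_factory=dict)


def default_study(
    seed: int = 0,
    n_lines: int = 319,
    markers_per_chrom: int = 400,
    n_years: int = 2,
    n_reps: int = 2,
    chrom_map: tuple[ChromosomeMap, ...] = DEFAULT_CHROMOSOMES,
    segment_spec: SegmentSpec | None = None,
    effect_frac: float = 0.06,
) -> CsslStudy:
    """Generate the default synthetic study (the package's test bench)."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_truth, s_pheno = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    geno, assignments = simulate_cssl_genotypes(
        chrom_map, n_lines, markers_per_chrom, segment_spec, seed=s_geno
    )
    truth = default_truth(geno, assignments, seed=s_truth, effect_frac=effect_frac)
    obs = simulate_phenotypes(
        assignments, truth, n_years=n_years, n_reps=n_reps, seed=s_pheno
    )
    return CsslStudy(
        chrom_map=tuple(chrom_map),
        genotypes=geno,
        assignments=assignments,
        truth=truth,
        observations=obs,
        seed=seed,
        n_years=n_years,
        n_reps=n_reps,
    )
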