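"""Bulked-segregant ΔSNP-index analysis with a CSSL-aware null.

Two extreme pools (drought-resistant / drought-sensitive, selected on the
composite MFVD score) are contrasted through the per-site SNP-index — the
donor-read fraction — and its difference Δ = index_resistant −
index_sensitive, smoothed in 1.5 Mb sliding windows.

Significance comes from a Monte-Carlo null tailored to CSSL panels: unlike
an F2 QTL-seq population, the donor-allele frequency at a locus is low and
locus-specific, so the null resamples the pooled allele frequency by
drawing 2 x pool_size chromosomes at the *observed* locus frequency and
then binomial read counts at the site depth. Within a window the pool
composition is shared across sites (the segments are line-level), so the
window-level null draws the pool frequencies once and only averages read
noise over the window's sites — ignoring this correlation would badly
understate the window band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import QtlRecord

__all__ = [
    "select_extreme_pools",
    "snp_index",
    "sliding_windows",
    "NullBandModel",
    "confidence_bands",
    "call_bsa_intervals",
    "DeltaIndexScan",
    "BsaResults",
]


def select_extreme_pools(
    mfvd: pd.Series, k: int = 30
) -> tuple[list[str], list[str]]:
    """Top-k / bottom-k lines by MFVD -> (resistant, sensitive) pools.

    Ties at the boundary break by line-id order, deterministically. Raises
    if the two tails would overlap.
    """
    scores = mfvd.dropna()
    if len(scores) < 2 * k:
        raise ValueError(f"need at least {2 * k} scored lines")
    order = scores.reset_index()
    order.columns = ["line_id", "score"]
    order = order.sort_values(["score", "line_id"], ascending=[False, True])
    resistant = order["line_id"].head(k).tolist()
    sensitive = order["line_id"].tail(k).tolist()
    if set(resistant) & set(sensitive):
        raise ValueError("extreme pools overlap; population too small")
    # a tie class reaching into both tails makes membership arbitrary
    shared = set(scores[resistant]) & set(scores[sensitive])
    if shared:
        raise ValueError(
            f"tied scores {sorted(shared)} span both pools; cannot bipartition"
        )
    return resistant, sensitive


def snp_index(
    depths: pd.DataFrame,
    min_depth: int = 10,
    parent_dosage_recurrent: np.ndarray | None = None,
    parent_dosage_donor: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-site SNP-index for both pools and their difference.

    ``depths`` columns: chromosome, position_bp, donor_reads_a,
    recurrent_reads_a, donor_reads_b, recurrent_reads_b (pool a =
    resistant). Sites below ``min_depth`` in either pool are dropped; if
    parent dosages are given, only parent-discordant homozygous sites
    (recurrent 0, donor 2) are retained. Positive delta means donor-allele
    enrichment in the resistant pool.
    """
    d = depths.copy()
    report = {"n_input": len(d)}
    if parent_dosage_recurrent is not None and parent_dosage_donor is not None:
        ok = (np.asarray(parent_dosage_recurrent) == 0) & (
            np.asarray(parent_dosage_donor) == 2
        )
        d = d.loc[ok].reset_index(drop=True)
        report["n_parent_discordant"] = len(d)
    tot_a = d["donor_reads_a"] + d["recurrent_reads_a"]
    tot_b = d["donor_reads_b"] + d["recurrent_reads_b"]
    keep = (tot_a >= min_depth) & (tot_b >= min_depth)
    report["n_low_depth_dropped"] = int((~keep).sum())
    d = d.loc[keep].reset_index(drop=True)
    tot_a, tot_b = tot_a[keep].reset_index(drop=True), tot_b[keep].reset_index(drop=True)
    d["index_resistant"] = d["donor_reads_a"] / tot_a
    d["index_sensitive"] = d["donor_reads_b"] / tot_b
    d["delta"] = d["index_resistant"] - d["index_sensitive"]
    d["depth_a"] = tot_a
    d["depth_b"] = tot_b
    # observed locus donor frequency pooling both bulks: the null's centre
    d["freq"] = (d["donor_reads_a"] + d["donor_reads_b"]) / (tot_a + tot_b)
    report["n_kept"] = len(d)
    return d, report


def sliding_windows(
    records: pd.DataFrame,
    window_bp: int = 1_500_000,
    step_bp: int = 100_000,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Mean delta in sliding windows [start, start + window) per chromosome.

    Windows tile each chromosome at ``step_bp``; windows with fewer than
    ``min_sites`` sites are flagged (``low_sites``), not silently valued.
    """
    rows = []
    for chrom, sub in records.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_bp")
        pos = sub["position_bp"].to_numpy()
        if len(pos) == 0:
            continue
        last = int(pos.max())
        starts = np.arange(1, last + 1, step_bp, dtype=np.int64)
        left = np.searchsorted(pos, starts, side="left")
        right = np.searchsorted(pos, starts + window_bp, side="left")
        delta = sub["delta"].to_numpy()
        freq = sub["freq"].to_numpy()
        depth = ((sub["depth_a"] + sub["depth_b"]) / 2.0).to_numpy()
        for s, a, b in zip(starts, left, right):
            n = int(b - a)
            rows.append(
                {
                    "chromosome": str(chrom),
                    "start_bp": int(s),
                    "end_bp": int(s + window_bp - 1),
                    "n_sites": n,
                    "mean_delta": float(delta[a:b].mean()) if n else np.nan,
                    "mean_freq": float(freq[a:b].mean()) if n else np.nan,
                    "mean_depth": float(depth[a:b].mean()) if n else np.nan,
                    "low_sites": n < min_sites,
                }
            )
    return pd.DataFrame(rows)


class NullBandModel:
    """Monte-Carlo confidence bands for the ΔSNP-index under the CSSL null.

    A null site at locus frequency p: each pool's allele frequency is a
    Binomial(n_units, p) draw / n_units, and its index a Binomial(depth,
    pool frequency) read fraction at Poisson(depth) reads. ``n_units``
    defaults to the *pool size in lines*, not 2 x pool_size chromosomes:
    CSSLs are near-fixed, so the two chromosomes of a line are copies of
    the same draw and the effective sampling unit is the line (an F2-style
    segregating pool would pass ``units_per_pool=2 * pool_size``).
    Per-site bands use one site; window bands share the pool-frequency
    draw across the window's sites and average only the read noise —
    within a window the same lines carry the same segment, so
    pool-composition noise does not average out.
    Bands are tabulated on a rounded (p, depth, n_sites) grid and cached.
    """

    def __init__(
        self,
        pool_size: int = 30,
        level: float = 0.99,
        n_sims: int = 10_000,
        seed: int = 0,
        p_grid: float = 0.02,
        depth_grid: float = 10.0,
        units_per_pool: int | None = None,
    ):
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        if n_sims < 1000:
            warnings.warn("n_sims < 1000: confidence bands will be noisy")
        self.pool_size = pool_size
        self.units = units_per_pool if units_per_pool is not None else pool_size
        self.level = level
        self.n_sims = n_sims
        self.seed = seed
        self.p_grid = p_grid
        self.depth_grid = depth_grid
        self._cache: dict[tuple, tuple[float, float]] = {}

    #: site-count ladder for tabulation (window bands vary slowly in n)
    _N_LADDER = np.array([1, 2, 3, 4, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50])

    def _key(self, p: float, depth: float, n_sites: int) -> tuple:
        pk = min(max(round(p / self.p_grid) * self.p_grid, self.p_grid / 2), 1.0)
        dk = max(round(depth / self.depth_grid) * self.depth_grid, 1.0)
        nk = int(self._N_LADDER[np.argmin(np.abs(self._N_LADDER - n_sites))])
        return (round(pk, 6), dk, nk)

    def _simulate(self, p: float, depth: float, n_sites: int) -> tuple[float, float]:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, int(p * 1e6), int(depth), n_sites])
        )
        units = self.units
        fa = rng.binomial(units, p, self.n_sims) / units
        fb = rng.binomial(units, p, self.n_sims) / units
        da = np.maximum(rng.poisson(depth, (self.n_sims, n_sites)), 1)
        db = np.maximum(rng.poisson(depth, (self.n_sims, n_sites)), 1)
        xa = rng.binomial(da, fa[:, None]) / da
        xb = rng.binomial(db, fb[:, None]) / db
        deltas = xa.mean(axis=1) - xb.mean(axis=1)
        alpha = (1.0 - self.level) / 2.0
        lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def site_band(self, p: float, depth: float) -> tuple[float, float]:
        return self.window_band(p, 1, depth)

    def window_band(self, p: float, n_sites: int, depth: float) -> tuple[float, float]:
        if not np.isfinite(p) or not np.isfinite(depth) or n_sites < 1:
            return (np.nan, np.nan)
        key = self._key(p, depth, n_sites)
        if key not in self._cache:
            self._cache[key] = self._simulate(*key)
        return self._cache[key]


def confidence_bands(
    pool_size: int = 30,
    level: float = 0.99,
    n_sims: int = 10_000,
    seed: int = 0,
) -> NullBandModel:
    """Build the null-band simulator (see :class:`NullBandModel`)."""
    return NullBandModel(pool_size=pool_size, level=level, n_sims=n_sims, seed=seed)


def annotate_bands(windows: pd.DataFrame, bands: NullBandModel, n_sites_cap: int = 50) -> pd.DataFrame:
    """Attach the window-level 99% band to each window record."""
    out = windows.copy()
    lo = np.full(len(out), np.nan)
    hi = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.n_sites >= 1 and np.isfinite(row.mean_freq):
            lo[i], hi[i] = bands.window_band(
                row.mean_freq, min(int(row.n_sites), n_sites_cap), row.mean_depth
            )
    out["ci_lower"] = lo
    out["ci_upper"] = hi
    return out


def call_bsa_intervals(
    windows: pd.DataFrame,
    trait: str = "MFVD",
    allow_gap: int = 1,
    method: str = "bsa",
) -> list[QtlRecord]:
    """Merge runs of windows whose |mean delta| exceeds the band into QTL.

    ``windows`` must carry ci_lower/ci_upper (see :func:`annotate_bands`).
    Runs may bridge up to ``allow_gap`` consecutive sub-threshold windows;
    low-site windows never exceed. The peak is the window with max |delta|.
    """
    out: list[QtlRecord] = []
    w = windows.copy()
    w["exceeds"] = (
        ~w["low_sites"]
        & np.isfinite(w["mean_delta"])
        & ((w["mean_delta"] > w["ci_upper"]) | (w["mean_delta"] < w["ci_lower"]))
    )
    for chrom, sub in w.groupby("chromosome", sort=True):
        sub = sub.sort_values("start_bp").reset_index(drop=True)
        exc = sub["exceeds"].to_numpy()
        hits = np.flatnonzero(exc)
        if len(hits) == 0:
            continue
        runs = []
        run_start = hits[0]
        prev = hits[0]
        for h in hits[1:]:
            if h - prev - 1 <= allow_gap:
                prev = h
            else:
                runs.append((run_start, prev))
                run_start = prev = h
        runs.append((run_start, prev))
        for a, b in runs:
            seg = sub.iloc[a : b + 1]
            seg_hits = seg[seg["exceeds"]]
            peak = seg_hits.loc[seg_hits["mean_delta"].abs().idxmax()]
            out.append(
                QtlRecord(
                    name="",
                    method=method,
                    trait=trait,
                    chromosome=str(chrom),
                    start_bp=int(seg["start_bp"].min()),
                    end_bp=int(seg["end_bp"].max()),
                    peak_bp=int((peak["start_bp"] + peak["end_bp"]) // 2),
                    statistic=float(abs(peak["mean_delta"])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# model-style wrapper


@dataclass
class BsaResults:
    """ΔSNP-index scan results."""

    sites: pd.DataFrame
    windows: pd.DataFrame  # with ci_lower / ci_upper
    intervals: list[QtlRecord]
    report: dict = field(default_factory=dict)

    def summary(self) -> str:
        n_exc = int(
            (
                (self.windows["mean_delta"] > self.windows["ci_upper"])
                | (self.windows["mean_delta"] < self.windows["ci_lower"])
            ).sum()
        )
        lines = [
            "Bulked-segregant ΔSNP-index scan",
            f"  sites kept: {self.report.get('n_kept', len(self.sites))}"
            f" of {self.report.get('n_input', '?')}",
            f"  windows: {len(self.windows)} ({n_exc} beyond the band)",
            f"  intervals called: {len(self.intervals)}",
        ]
        for r in self.intervals[:8]:
            lines.append(
                f"    {r.chromosome}:{r.start_bp}-{r.end_bp}  max|Δ|={r.statistic:.3f}"
            )
        return "\n".join(lines)


class DeltaIndexScan:
    """End-to-end BSA scan from pooled depths.

    Wraps site filtering, window smoothing, the CSSL-aware null band and
    interval calling in one fit.
    """

    def __init__(
        self,
        depths: pd.DataFrame,
        pool_size: int = 30,
        window_bp: int = 1_500_000,
        step_bp: int = 100_000,
        level: float = 0.99,
        min_depth: int = 10,
        min_sites: int = 10,
        n_sims: int = 10_000,
        trait: str = "MFVD",
    ):
        self.depths = depths
        self.pool_size = pool_size
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.level = level
        self.min_depth = min_depth
        self.min_sites = min_sites
        self.n_sims = n_sims
        self.trait = trait

    def fit(self, seed: int = 0, **snp_index_kw) -> BsaResults:
        sites, report = snp_index(self.depths, self.min_depth, **snp_index_kw)
        windows = sliding_windows(sites, self.window_bp, self.step_bp, self.min_sites)
        bands = NullBandModel(
            pool_size=self.pool_size, level=self.level, n_sims=self.n_sims, seed=seed
        )
        windows = annotate_bands(windows, bands)
        intervals = call_bsa_intervals(windows, trait=self.trait)
        return BsaResults(sites=sites, windows=windows, intervals=intervals, report=report)
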