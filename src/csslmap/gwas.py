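"""Mixed-linear-model association scanning for the CSSL panel.

The scan is the classic kinship mixed model: for phenotype y and marker
dosage x,

    y = mu + x * beta + u + e,     u ~ N(0, sg^2 K),  e ~ N(0, se^2 I).

K is spectrally decomposed once; the variance ratio delta = se^2/sg^2 is
profiled by REML on the null (intercept-only) model and then held fixed for
every marker (the population-parameters-previously-determined speed
approximation), with per-marker generalized least squares and a two-sided
Wald t test. Missing dosages are dropped pairwise per marker, handled
exactly through a low-rank Schur correction of the inverse covariance —
no imputation enters the scan itself.

Also here: the marker filters (MAF / missingness), the per-marker-count
association thresholds (1/M suggestive, 0.05/M significant), pairwise LD
r^2, greedy r^2 LD blocks, and flank-based candidate intervals around
highlighted SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeData, QtlRecord, recompute_marker_stats

__all__ = [
    "filter_markers",
    "association_thresholds",
    "compute_kinship",
    "MixedLMM",
    "MLMResults",
    "ld_r2",
    "LdBlock",
    "ld_blocks",
    "candidate_interval",
    "qtl_intervals_from_scan",
]


def filter_markers(
    geno: GenotypeData, maf_min: float = 0.05, missing_max: float = 0.5
) -> tuple[GenotypeData, dict]:
    """Drop markers with MAF <= ``maf_min`` or missing rate >= ``missing_max``.

    Statistics are recomputed from the matrix (not trusted from the info
    table). Returns the filtered data and a count report.
    """
    maf, miss = recompute_marker_stats(geno.matrix)
    keep = (maf > maf_min) & (miss < missing_max)
    if not keep.any():
        warnings.warn("no markers survive filtering")
    info = geno.info.loc[keep].reset_index(drop=True).copy()
    info["maf"] = maf[keep]
    info["missing_rate"] = miss[keep]
    out = GenotypeData(geno.matrix[:, keep], info, list(geno.line_ids))
    report = {
        "n_input": geno.n_markers,
        "n_kept": int(keep.sum()),
        "n_maf_removed": int((maf <= maf_min).sum()),
        "n_missing_removed": int((miss >= missing_max).sum()),
    }
    return out, report


def association_thresholds(n_markers: int) -> tuple[float, float]:
    """(suggestive, significant) genome-wide p thresholds: 1/M and 0.05/M."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return 1.0 / n_markers, 0.05 / n_markers


def compute_kinship(geno: GenotypeData) -> np.ndarray:
    """Centered cross-product (VanRaden-type) kinship.

    K = W W' / c with W the mean-centered dosage matrix and
    c = sum_j 2 p_j (1 - p_j); missing dosages are mean-imputed here only.
    """
    if geno.n_markers < 2:
        raise ValueError("need at least 2 markers for kinship")
    m = geno.matrix.astype(float)
    obs = m != MISSING
    if not obs.any(axis=1).all():
        raise ValueError("a line has no observed genotypes")
    col_mean = np.where(obs, m, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    w = np.where(obs, m, col_mean[None, :]) - col_mean[None, :]
    p = col_mean / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("monomorphic panel: kinship undefined")
    return (w @ w.T) / c


# ---------------------------------------------------------------------------
# mixed model scan


def _null_reml_neg_ll(log_delta: float, s: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """-2 x REML log-likelihood (up to a constant) for the intercept model."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xtwx = float(np.sum(w * xstar * xstar))
    mu = float(np.sum(w * xstar * ystar)) / xtwx
    r = ystar - xstar * mu
    rss = float(np.sum(w * r * r))
    n = len(s)
    return (n - 1) * np.log(rss) + float(np.sum(np.log(s + delta))) + np.log(xtwx)


@dataclass
class MLMResults:
    """Association scan results; one record per tested marker."""

    records: pd.DataFrame
    delta: float
    sigma2_g: float
    sigma2_e: float
    trait: str = ""
    n_lines: int = 0
    skipped: pd.DataFrame | None = None

    @property
    def thresholds(self) -> tuple[float, float]:
        return association_thresholds(len(self.records))

    def qtl(
        self, trait: str | None = None, p_max: float | None = None, merge_bp: int = 1_000_000
    ) -> list[QtlRecord]:
        p_max = p_max if p_max is not None else self.thresholds[0]
        return qtl_intervals_from_scan(
            self.records, trait or self.trait, p_max=p_max, merge_bp=merge_bp
        )

    def summary(self) -> str:
        sug, sig = self.thresholds
        top = self.records.nsmallest(5, "p")
        lines = [
            f"Mixed-model association scan: trait={self.trait or '?'}",
            f"  lines={self.n_lines}  markers={len(self.records)}",
            f"  profiled delta (se^2/sg^2) = {self.delta:.4g}"
            f"  (sg^2={self.sigma2_g:.4g}, se^2={self.sigma2_e:.4g})",
            f"  thresholds: suggestive p={sug:.3g}, significant p={sig:.3g}",
            "  top hits:",
        ]
        for _, r in top.iterrows():
            lines.append(
                f"    {r['marker_id']:>16}  -log10p={r['neg_log10_p']:6.2f}  beta={r['beta']:+.4g}"
            )
        return "\n".join(lines)


class MixedLMM:
    """Kinship mixed model for one phenotype over the genotyped lines.

    Parameters
    ----------
    phenotype : pd.Series indexed by line_id (NaN lines are dropped)
    geno : filtered genotype data
    kinship : optional precomputed K over ``geno.line_ids``
    """

    def __init__(
        self,
        phenotype: pd.Series,
        geno: GenotypeData,
        kinship: np.ndarray | None = None,
    ):
        y = phenotype.reindex(geno.line_ids)
        keep = y.notna().to_numpy()
        if keep.sum() < 30:
            raise ValueError("phenotype defined for fewer than 30 lines")
        self.line_ids = [l for l, k in zip(geno.line_ids, keep) if k]
        self.y = y.to_numpy(float)[keep]
        self.X = geno.matrix[keep, :]
        self.info = geno.info
        K = kinship if kinship is not None else compute_kinship(geno)
        self.K = K[np.ix_(keep, keep)]

    def fit(self, grid_points: int = 64, log_delta_bounds=(-10.0, 10.0), tol: float = 1e-6) -> MLMResults:
        n = len(self.y)
        s, U = np.linalg.eigh(self.K)
        s = np.clip(s, 0.0, None)
        ystar = U.T @ self.y
        onestar = U.T @ np.ones(n)

        # profile the variance ratio: grid scan then golden-section refinement
        grid = np.linspace(*log_delta_bounds, grid_points)
        vals = [_null_reml_neg_ll(g, s, ystar, onestar) for g in grid]
        i0 = int(np.argmin(vals))
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, grid_points - 1)]
        res = optimize.minimize_scalar(
            _null_reml_neg_ll,
            bounds=(lo, hi),
            args=(s, ystar, onestar),
            method="bounded",
            options={"xatol": tol},
        )
        log_delta = float(res.x)
        if _null_reml_neg_ll(grid[i0], s, ystar, onestar) < res.fun:
            log_delta = float(grid[i0])
        delta = float(np.exp(log_delta))

        # variance scale at the optimum (null model)
        w = 1.0 / (s + delta)
        mu = float(np.sum(w * onestar * ystar)) / float(np.sum(w * onestar * onestar))
        sg2 = float(np.sum(w * (ystar - onestar * mu) ** 2)) / (n - 1)
        se2 = sg2 * delta

        # inverse covariance (up to the sg^2 scale, which cancels in t tests)
        Q = (U * w[None, :]) @ U.T
        ones = np.ones(n)
        Q1 = Q @ ones
        Qy = Q @ self.y
        f11_full = float(ones @ Q1)
        f1y_full = float(ones @ Qy)
        fyy_full = float(self.y @ Qy)

        X0 = np.where(self.X == MISSING, 0, self.X).astype(float)
        G = Q @ X0  # main cost: one dense matmul
        miss_mask = self.X == MISSING

        rows = []
        skipped = []
        for j in range(X0.shape[1]):
            mj = np.flatnonzero(miss_mask[:, j])
            xj = X0[:, j]
            gj = G[:, j]
            if len(mj) == 0:
                f11, f1y, fyy = f11_full, f1y_full, fyy_full
                fx1 = float(gj @ ones)
                fxy = float(gj @ self.y)
                fxx = float(gj @ xj)
                n_s = n
                x_obs = xj
            else:
                # exact GLS on the observed subset via the Schur identity:
                # (V_SS)^-1 = Q_SS - Q_Sm Q_mm^-1 Q_mS
                ym = self.y[mj]
                Qmm = Q[np.ix_(mj, mj)]
                # padded quadratic forms a' Q b with zeros at m
                s1 = float(np.sum(gj) - np.sum(gj[mj]))
                sy = float(gj @ self.y - gj[mj] @ ym)
                sxx = float(gj @ xj)
                Q1m = Q1[mj] - Qmm.sum(axis=1)
                Qym = Qy[mj] - Qmm @ ym
                Qxm = gj[mj]
                f11_p = f11_full - 2.0 * float(Q1[mj].sum()) + float(Qmm.sum())
                f1y_p = (
                    f1y_full
                    - float(Qy[mj].sum())
                    - float(Q1[mj] @ ym)
                    + float(ym @ Qmm.sum(axis=1))
                )
                fyy_p = fyy_full - 2.0 * float(Qy[mj] @ ym) + float(ym @ Qmm @ ym)
                try:
                    Qmm_inv = np.linalg.inv(Qmm)
                except np.linalg.LinAlgError:
                    skipped.append({"marker_id": self.info.iloc[j]["marker_id"], "reason": "singular missing block"})
                    continue
                f11 = f11_p - float(Q1m @ Qmm_inv @ Q1m)
                f1y = f1y_p - float(Q1m @ Qmm_inv @ Qym)
                fyy = fyy_p - float(Qym @ Qmm_inv @ Qym)
                fx1 = s1 - float(Qxm @ Qmm_inv @ Q1m)
                fxy = sy - float(Qxm @ Qmm_inv @ Qym)
                fxx = sxx - float(Qxm @ Qmm_inv @ Qxm)
                n_s = n - len(mj)
                x_obs = np.delete(xj, mj)
            if n_s < 3 or np.ptp(x_obs) == 0:
                skipped.append(
                    {"marker_id": self.info.iloc[j]["marker_id"], "reason": "constant after missing-drop"}
                )
                continue
            A = np.array([[f11, fx1], [fx1, fxx]])
            c = np.array([f1y, fxy])
            det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
            if det <= 0 or not np.isfinite(det):
                skipped.append({"marker_id": self.info.iloc[j]["marker_id"], "reason": "singular design"})
                continue
            Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
            beta = Ainv @ c
            rss = fyy - c @ beta
            df = n_s - 2
            sigma2 = max(rss / df, 0.0)
            se_b = float(np.sqrt(max(sigma2 * Ainv[1, 1], 0.0)))
            if se_b == 0:
                p = 0.0
                tstat = np.inf
            else:
                tstat = beta[1] / se_b
                p = float(2.0 * stats.t.sf(abs(tstat), df))
            p = max(p, np.finfo(float).tiny)
            rows.append(
                {
                    "marker_id": self.info.iloc[j]["marker_id"],
                    "chromosome": self.info.iloc[j]["chromosome"],
                    "position_bp": int(self.info.iloc[j]["position_bp"]),
                    "n": n_s,
                    "beta": float(beta[1]),
                    "se": se_b,
                    "p": p,
                    "neg_log10_p": float(-np.log10(p)),
                }
            )
        return MLMResults(
            records=pd.DataFrame(rows),
            delta=delta,
            sigma2_g=sg2,
            sigma2_e=se2,
            n_lines=n,
            skipped=pd.DataFrame(skipped) if skipped else None,
        )


def qtl_intervals_from_scan(
    records: pd.DataFrame,
    trait: str,
    p_max: float,
    merge_bp: int = 1_000_000,
    method: str = "gwas",
) -> list[QtlRecord]:
    """Merge significant markers < ``merge_bp`` apart into QTL intervals.

    The marker with minimum p in each run is the highlighted SNP (peak);
    the statistic reported is its -log10 p. Names are assigned later by
    the integration step.
    """
    sig = records[records["p"] < p_max].sort_values(["chromosome", "position_bp"])
    out: list[QtlRecord] = []
    for chrom, sub in sig.groupby("chromosome", sort=True):
        pos = sub["position_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= merge_bp)
        start_idx = np.concatenate([[0], breaks + 1])
        end_idx = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(start_idx, end_idx):
            run = sub.iloc[a : b + 1]
            peak = run.loc[run["p"].idxmin()]
            out.append(
                QtlRecord(
                    name="",
                    method=method,
                    trait=trait,
                    chromosome=str(chrom),
                    start_bp=int(run["position_bp"].min()),
                    end_bp=int(run["position_bp"].max()),
                    peak_bp=int(peak["position_bp"]),
                    statistic=float(peak["neg_log10_p"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(geno: GenotypeData, marker_i: str | int, marker_j: str | int) -> float:
    """Squared Pearson correlation of dosages over jointly observed lines."""
    def col(m):
        if isinstance(m, str):
            j = int(np.flatnonzero(geno.info["marker_id"] == m)[0])
        else:
            j = m
        return geno.matrix[:, j].astype(float)

    a, b = col(marker_i), col(marker_j)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly observed lines")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdBlock:
    chromosome: str
    start_bp: int
    end_bp: int
    marker_ids: list[str] = field(default_factory=list)


def ld_blocks(geno: GenotypeData, r2_min: float = 0.8) -> list[LdBlock]:
    """Greedy r^2 blocks: grow while the next marker's r^2 with the block
    seed (its first marker) stays >= ``r2_min``; blocks are maximal and
    non-overlapping per chromosome."""
    blocks: list[LdBlock] = []
    for chrom, sub in geno.info.groupby("chromosome", sort=True):
        idx = sub.index.to_numpy()
        i = 0
        while i < len(idx):
            seed = idx[i]
            members = [seed]
            k = i + 1
            while k < len(idx):
                try:
                    r2 = ld_r2(geno, int(idx[k]), int(seed))
                except ValueError:
                    break
                if not np.isfinite(r2) or r2 < r2_min:
                    break
                members.append(idx[k])
                k += 1
            blocks.append(
                LdBlock(
                    chromosome=str(chrom),
                    start_bp=int(geno.info.loc[members[0], "position_bp"]),
                    end_bp=int(geno.info.loc[members[-1], "position_bp"]),
                    marker_ids=[geno.info.loc[m, "marker_id"] for m in members],
                )
            )
            i = k
    return blocks


def candidate_interval(
    chromosome: str,
    position_bp: int,
    chrom_length_bp: int | None = None,
    blocks: list[LdBlock] | None = None,
    flank_bp: int = 300_000,
) -> tuple[int, int, str]:
    """Candidate screening interval around a highlighted SNP.

    [pos - flank, pos + flank], clipped to the chromosome, then united with
    the LD block containing the SNP if one is supplied. Returns
    (start, end, provenance).
    """
    start = max(1, position_bp - flank_bp)
    end = position_bp + flank_bp
    if chrom_length_bp is not None:
        end = min(end, chrom_length_bp)
    provenance = "flank"
    for blk in blocks or []:
        if blk.chromosome == chromosome and blk.start_bp <= position_bp <= blk.end_bp:
            new_start, new_end = min(start, blk.start_bp), max(end, blk.end_bp)
            if (new_start, new_end) != (start, end):
                provenance = "union" if (blk.start_bp > start or blk.end_bp < end) else "block"
                if blk.start_bp <= start and blk.end_bp >= end:
                    provenance = "block"
                else:
                    provenance = "union"
            start, end = new_start, new_end
            break
    return start, end, provenance
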