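"""Marker filtering, kinship, mixed-model scan, LD and candidate intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csslmap as cm
from csslmap.datatypes import MISSING
from csslmap.gwas import (
    MixedLMM,
    association_thresholds,
    candidate_interval,
    compute_kinship,
    filter_markers,
    ld_blocks,
    ld_r2,
    LdBlock,
)
from conftest import make_geno


# ---------------------------------------------------------------------------
# filtering & thresholds


def test_filter_markers_recount_oracle():
    rng = np.random.default_rng(0)
    n_lines, n_markers = 60, 1000
    matrix = rng.choice([0, 2], size=(n_lines, n_markers), p=[0.8, 0.2]).astype(np.int8)
    matrix[:, 10] = 0  # monomorphic -> MAF 0
    matrix[:, 20] = 2
    matrix[: int(0.6 * n_lines), 30] = MISSING  # 60% missing
    low = rng.choice(n_lines, size=2, replace=False)
    matrix[:, 40] = 0
    matrix[low, 40] = 2  # MAF = 2/60 < 0.05
    geno = make_geno(matrix)
    out, report = filter_markers(geno)
    # brute-force recount
    keep = []
    for j in range(n_markers):
        col = matrix[:, j]
        obs = col[col != MISSING]
        f = obs.sum() / (2 * len(obs))
        maf = min(f, 1 - f)
        miss = 1 - len(obs) / n_lines
        keep.append(maf > 0.05 and miss < 0.5)
    assert out.n_markers == sum(keep) == report["n_kept"]
    kept_ids = set(out.info["marker_id"])
    for j, k in enumerate(keep):
        assert (geno.info.loc[j, "marker_id"] in kept_ids) == k
    for bad in (10, 20, 30, 40):
        assert geno.info.loc[bad, "marker_id"] not in kept_ids


@pytest.mark.parametrize(
    "n,expected",
    [
        (1_309_780, (7.63487e-7, 3.81743e-8)),  # the genome-wide SNP count
        (20, (0.05, 0.0025)),
    ],
)
def test_association_thresholds(n, expected):
    sug, sig = association_thresholds(n)
    assert float(f"{sug:.6g}") == pytest.approx(expected[0], rel=1e-6)
    assert float(f"{sig:.6g}") == pytest.approx(expected[1], rel=1e-6)


# ---------------------------------------------------------------------------
# kinship


def test_kinship_double_loop_oracle():
    rng = np.random.default_rng(1)
    matrix = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
    geno = make_geno(matrix)
    K = compute_kinship(geno)
    m = matrix.astype(float)
    p = m.mean(axis=0) / 2
    w = m - 2 * p
    c = np.sum(2 * p * (1 - p))
    brute = np.zeros((5, 5))
    for i in range(5):
        for k in range(5):
            brute[i, k] = np.sum(w[i] * w[k]) / c
    np.testing.assert_allclose(K, brute, atol=1e-12)
    np.testing.assert_allclose(K, K.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(K) > -1e-10)


def test_kinship_identical_lines_and_independence():
    rng = np.random.default_rng(2)
    row = rng.integers(0, 3, 500).astype(np.int8)
    matrix = np.vstack([row, row, rng.integers(0, 3, (3, 500))]).astype(np.int8)
    K = compute_kinship(make_geno(matrix))
    assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
    big = rng.integers(0, 3, size=(300, 10_000)).astype(np.int8)
    K2 = compute_kinship(make_geno(big))
    off = K2[~np.eye(300, dtype=bool)]
    # independent lines: off-diagonals ~0 (centering leaves a -diag/(n-1) bias)
    assert abs(off.mean()) < 0.01
    assert np.quantile(np.abs(off), 0.99) < 0.05


# ---------------------------------------------------------------------------
# mixed-model scan


def _panel(n_lines=60, n_markers=50, seed=3):
    rng = np.random.default_rng(seed)
    matrix = rng.choice([0, 2], size=(n_lines, n_markers), p=[0.7, 0.3]).astype(np.int8)
    return make_geno(matrix), rng


def test_mlm_degenerates_to_ols_with_identity_kinship():
    """With K = I the GLS weights are flat: per-marker p equals plain OLS
    to 1e-6 in -log10 p."""
    geno, rng = _panel()
    y = pd.Series(rng.normal(0, 1, geno.n_lines) + 0.3 * geno.matrix[:, 0],
                  index=geno.line_ids)
    res = MixedLMM(y, geno, kinship=np.eye(geno.n_lines)).fit()
    for _, rec in res.records.iterrows():
        j = geno.info.index[geno.info["marker_id"] == rec["marker_id"]][0]
        x = geno.matrix[:, j].astype(float)
        slope, _, _, p_ols, _ = stats.linregress(x, y.to_numpy())
        assert -np.log10(rec["p"]) == pytest.approx(-np.log10(p_ols), abs=1e-6)
        assert rec["beta"] == pytest.approx(slope, rel=1e-6)


def test_mlm_perfect_marker_underflows():
    geno, rng = _panel()
    y = pd.Series(geno.matrix[:, 5].astype(float), index=geno.line_ids)
    res = MixedLMM(y, geno, kinship=np.eye(geno.n_lines)).fit()
    rec = res.records.set_index("marker_id").loc[geno.info.loc[5, "marker_id"]]
    assert rec["neg_log10_p"] > 15


def test_mlm_allele_flip_invariance():
    geno, rng = _panel(seed=4)
    K = compute_kinship(geno)
    y = pd.Series(rng.normal(size=geno.n_lines) + 0.2 * geno.matrix[:, 3],
                  index=geno.line_ids)
    res1 = MixedLMM(y, geno, kinship=K).fit()
    flipped = make_geno(2 - geno.matrix)
    res2 = MixedLMM(pd.Series(y.to_numpy(), index=flipped.line_ids), flipped, kinship=K).fit()
    np.testing.assert_allclose(res1.records["p"], res2.records["p"], rtol=1e-10)
    np.testing.assert_allclose(res1.records["beta"], -res2.records["beta"], rtol=1e-10)


def test_mlm_pairwise_missing_drop_matches_subset_gls():
    """A marker with missing calls is tested by exact GLS on its observed
    subset of lines (oracle: direct solve on the subsetted covariance)."""
    geno, rng = _panel(n_lines=40, n_markers=12, seed=5)
    matrix = geno.matrix.copy()
    matrix[[3, 7, 11], 4] = MISSING
    geno2 = make_geno(matrix)
    K = compute_kinship(geno)  # complete-data kinship
    y = pd.Series(rng.normal(size=40) + 0.25 * geno.matrix[:, 4], index=geno2.line_ids)
    res = MixedLMM(y, geno2, kinship=K).fit()
    rec = res.records.set_index("marker_id").loc[geno2.info.loc[4, "marker_id"]]
    # oracle: GLS on observed lines with V restricted to them
    keep = np.ones(40, bool)
    keep[[3, 7, 11]] = False
    s, U = np.linalg.eigh(K)
    V = (U * (np.clip(s, 0, None) + res.delta)) @ U.T
    Vs = V[np.ix_(keep, keep)]
    Vi = np.linalg.inv(Vs)
    X = np.column_stack([np.ones(keep.sum()), matrix[keep, 4].astype(float)])
    yv = y.to_numpy()[keep]
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
    r = yv - X @ beta
    sigma2 = (r @ Vi @ r) / (keep.sum() - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Vi @ X)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), keep.sum() - 2)
    assert rec["beta"] == pytest.approx(beta[1], rel=1e-8)
    assert rec["p"] == pytest.approx(p, rel=1e-6)


def test_mlm_requires_enough_lines():
    geno, rng = _panel(n_lines=40)
    y = pd.Series(np.nan, index=geno.line_ids)
    y.iloc[:10] = 1.0
    with pytest.raises(ValueError):
        MixedLMM(y, geno)


# ---------------------------------------------------------------------------
# LD


def test_ld_r2_identity_and_complement():
    rng = np.random.default_rng(6)
    col = rng.choice([0, 2], 100, p=[0.6, 0.4]).astype(np.int8)
    matrix = np.column_stack([col, col, 2 - col]).astype(np.int8)
    geno = make_geno(matrix)
    assert ld_r2(geno, 0, 1) == pytest.approx(1.0)
    assert ld_r2(geno, 0, 2) == pytest.approx(1.0)  # coding flip invariant


def test_ld_r2_independent_markers_expectation():
    rng = np.random.default_rng(7)
    n = 500
    matrix = rng.choice([0, 2], size=(n, 200), p=[0.5, 0.5]).astype(np.int8)
    geno = make_geno(matrix)
    r2s = [ld_r2(geno, 2 * i, 2 * i + 1) for i in range(100)]
    # E[r^2] ~ 1/n for independent markers; 3 SE of the mean over 100 pairs
    assert np.mean(r2s) == pytest.approx(1 / n, abs=0.001)


def test_ld_blocks_perfect_and_singleton():
    rng = np.random.default_rng(8)
    col = rng.choice([0, 2], 80).astype(np.int8)
    perfect = np.tile(col[:, None], (1, 6))
    geno = make_geno(perfect)
    blocks = ld_blocks(geno)
    assert len(blocks) == 1 and len(blocks[0].marker_ids) == 6
    indep = rng.choice([0, 2], size=(80, 6)).astype(np.int8)
    blocks2 = ld_blocks(make_geno(indep))
    assert all(len(b.marker_ids) == 1 for b in blocks2)


def test_ld_blocks_planted_block_recovered():
    rng = np.random.default_rng(9)
    n = 100
    noise = rng.choice([0, 2], size=(n, 10)).astype(np.int8)
    core = rng.choice([0, 2], n).astype(np.int8)
    planted = np.tile(core[:, None], (1, 5))
    matrix = np.hstack([noise[:, :5], planted, noise[:, 5:]]).astype(np.int8)
    blocks = ld_blocks(make_geno(matrix))
    sizes = sorted(len(b.marker_ids) for b in blocks)
    assert sizes[-1] == 5
    big = [b for b in blocks if len(b.marker_ids) == 5][0]
    assert big.marker_ids == [f"A01_{(j + 1) * 1000}" for j in range(5, 10)]


# ---------------------------------------------------------------------------
# candidate intervals


def test_candidate_interval_printed_width():
    """300 kb flanks around the D09 highlighted SNP give the ~600 kb
    screening interval the coordinates imply."""
    start, end, prov = candidate_interval("D09", 40_715_689)
    assert (start, end) == (40_415_689, 41_015_689)
    assert end - start == 600_000
    assert prov == "flank"


def test_candidate_interval_clipping_and_block_union():
    start, end, _ = candidate_interval("A01", 100_000, chrom_length_bp=1_000_000)
    assert start == 1 and end == 400_000
    blk = LdBlock("A01", 50_000, 2_000_000, [])
    s2, e2, prov = candidate_interval("A01", 900_000, blocks=[blk])
    assert (s2, e2) == (50_000, 2_000_000)  # block wider than the flanks
    assert prov in ("block", "union")
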