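"""Phenomics: BLUP shrinkage, DRC/MFVD scoring, grading, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csslmap.phenotype import (
    BlupModel,
    PhysiologyMeasurement,
    blup_table,
    compute_drc,
    compute_mfvd,
    correlation_network,
    fit_blup,
    grade_lines,
    percent_change,
    physiology,
    summarize_condition,
)


def _obs(values_by_line, trait="PH", condition="control", years=(2018, 2019), reps=(1, 2)):
    rows = []
    for lid, vals in values_by_line.items():
        it = iter(vals)
        for y in years:
            for r in reps:
                rows.append(dict(line_id=lid, trait=trait, condition=condition,
                                 year=y, replicate=r, value=next(it)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BLUP


def test_blup_zero_residual_equals_line_means():
    obs = _obs({"a": [10] * 4, "b": [14] * 4, "c": [12] * 4})
    res = fit_blup(obs, "PH", "control")
    np.testing.assert_allclose(res.values[["a", "b", "c"]], [10, 14, 12], atol=1e-4)


def test_blup_zero_genetic_variance_shrinks_to_grand_mean():
    rng = np.random.default_rng(0)
    obs = _obs({f"l{i}": rng.normal(50, 2, 4) for i in range(20)})
    res = fit_blup(obs, "PH", "control")
    raw_means = obs.groupby("line_id")["value"].mean()
    # lines are exchangeable here: BLUPs hug the grand mean tighter
    assert res.values.std() < raw_means.std()
    assert res.values.mean() == pytest.approx(raw_means.mean(), abs=0.2)


def test_blup_matches_direct_gls_at_reml_optimum():
    """BLUP/fixed effects equal a hand-coded V-inverse GLS solve at the
    converged variance components, to 1e-8."""
    rng = np.random.default_rng(1)
    n_lines, nobs = 20, 4
    g = rng.normal(0, 3, n_lines)
    obs = _obs({f"l{i:02d}": 100 + g[i] + rng.normal(0, 1.5, nobs) for i in range(n_lines)})
    model = BlupModel(obs, "PH", "control")
    res = model.fit()
    X, Z, y = model._X, model._Z, model._y
    V = res.sigma2_line * Z @ Z.T + res.sigma2_residual * np.eye(len(y))
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = res.sigma2_line * Z.T @ Vi @ (y - X @ b)
    np.testing.assert_allclose(res.line_effects.to_numpy(), u, atol=1e-8)
    np.testing.assert_allclose(res.fixed_effects, b, atol=1e-8)


def test_blup_variance_components_match_statsmodels_reml():
    """Independent oracle: statsmodels MixedLM REML on the same design."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(2)
    n_lines = 25
    g = rng.normal(0, 2, n_lines)
    obs = _obs({f"l{i:02d}": 60 + g[i] + rng.normal(0, 1, 4) for i in range(n_lines)})
    res = fit_blup(obs, "PH", "control")
    df = obs.copy()
    # rep-within-year spans the year effect, so one nested factor suffices
    df["rep"] = df["year"].astype(str) + ":" + df["replicate"].astype(str)
    m = smf.mixedlm("value ~ C(rep)", df, groups=df["line_id"]).fit(reml=True)
    sm_su2 = float(m.cov_re.iloc[0, 0])
    sm_se2 = float(m.scale)
    assert res.sigma2_line == pytest.approx(sm_su2, rel=1e-3, abs=1e-6)
    assert res.sigma2_residual == pytest.approx(sm_se2, rel=1e-3, abs=1e-6)


def test_blup_missing_line_flagged_not_imputed():
    obs = pd.concat(
        [
            _obs({"a": [1, 2, 3, 4], "b": [2, 3, 4, 5]}),
            _obs({"a": [5, 6, 7, 8], "b": [6, 7, 8, 9], "c": [1, 2, 3, 4]},
                 condition="drought"),
        ]
    )
    table = blup_table(obs, traits=["PH"])
    assert np.isnan(table.loc["c", ("PH", "control")])
    assert np.isfinite(table.loc["c", ("PH", "drought")])


# ---------------------------------------------------------------------------
# summaries, DRC, MFVD


@pytest.mark.parametrize(
    "mc,md,expected,nd",
    [
        (131.665, 128.522, 2.387, 3),  # whole-growth-period reduction
        (5.293, 5.215, 1.47, 2),  # boll-weight reduction
        (10.0, 10.0, 0.0, 6),
    ],
)
def test_percent_change_printed_examples(mc, md, expected, nd):
    assert round(percent_change(mc, md), nd) == expected


def test_summarize_condition_and_cv():
    idx = pd.Index([f"l{i}" for i in range(6)], name="line_id")
    blups = pd.DataFrame(
        {("PH", "control"): [10, 12, 14, 16, 18, 20],
         ("PH", "drought"): [5, 6, 7, 8, 9, 10]},
        index=idx,
    )
    blups.columns = pd.MultiIndex.from_tuples(blups.columns, names=["trait", "condition"])
    s = summarize_condition(blups, "PH")
    assert s["percent_change"] == pytest.approx(50.0)
    assert s["cv_control"] == pytest.approx(np.std([10, 12, 14, 16, 18, 20], ddof=1) / 15)


def test_drc_elementwise_oracle_and_flags():
    idx = pd.Index([f"l{i}" for i in range(5)], name="line_id")
    ctrl = np.array([[10.0, 2.0], [8.0, 4.0], [5.0, 5.0], [4.0, 1.0], [0.0, 2.0]])
    drt = np.array([[9.0, 2.0], [8.0, 2.0], [0.0, 5.0], [6.0, 1.5], [3.0, 1.0]])
    cols = {}
    for t_i, t in enumerate(["BW", "FS"]):
        cols[(t, "control")] = ctrl[:, t_i]
        cols[(t, "drought")] = drt[:, t_i]
    blups = pd.DataFrame(cols, index=idx)
    blups.columns = pd.MultiIndex.from_tuples(blups.columns, names=["trait", "condition"])
    drc = compute_drc(blups)
    with np.errstate(divide="ignore"):
        expected = drt / ctrl  # independent elementwise division
    for t_i, t in enumerate(["BW", "FS"]):
        for i in range(5):
            if ctrl[i, t_i] > 0:
                assert drc[t].iloc[i] == pytest.approx(expected[i, t_i])
    assert np.isnan(drc["BW"].iloc[4])  # zero control flagged, not 0
    assert drc["BW"].iloc[2] == 0.0  # zero drought is a genuine 0


def test_mfvd_brute_force_oracle_and_bounds():
    rng = np.random.default_rng(3)
    drc = pd.DataFrame(
        rng.uniform(0.5, 1.5, (10, 3)),
        columns=["BW", "FS", "MV"],
        index=pd.Index([f"l{i}" for i in range(10)], name="line_id"),
    )
    out = compute_mfvd(drc, basis_traits=["BW", "FS", "MV"])
    brute = np.zeros((10, 3))
    for j, t in enumerate(["BW", "FS", "MV"]):
        x = drc[t].to_numpy()
        brute[:, j] = (x - x.min()) / (x.max() - x.min())
    np.testing.assert_allclose(out["mfvd"], brute.mean(axis=1), atol=1e-12)
    assert ((out["mfvd"] >= 0) & (out["mfvd"] <= 1)).all()
    # the population max on every trait scores exactly 1
    drc2 = drc.copy()
    drc2.loc["l0"] = drc.max() + 0.1
    out2 = compute_mfvd(drc2, basis_traits=["BW", "FS", "MV"])
    assert out2.loc["l0", "mfvd"] == pytest.approx(1.0)


def test_mfvd_two_lines_and_orientation_and_constant():
    drc = pd.DataFrame({"BW": [0.8, 1.2], "MV": [1.1, 0.9]},
                       index=pd.Index(["a", "b"], name="line_id"))
    out = compute_mfvd(drc, basis_traits=["BW", "MV"])
    assert sorted(out["membership_BW"]) == [0.0, 1.0]
    low = compute_mfvd(drc, basis_traits=["BW", "MV"], orientation={"MV": "lower"})
    assert low.loc["a", "membership_MV"] == 0.0  # higher MV now penalized
    const = pd.DataFrame({"BW": [1.0, 1.0, 1.0]},
                         index=pd.Index(list("abc"), name="line_id"))
    with pytest.warns(UserWarning):
        out_c = compute_mfvd(const, basis_traits=["BW"])
    assert (out_c["membership_BW"] == 0.5).all()


# ---------------------------------------------------------------------------
# grading


def test_grades_by_interval_membership():
    mfvd = pd.Series([0.05, 0.25, 0.5, 0.75, 0.95, 0.4],
                     index=pd.Index(list("abcdef"), name="line_id"))
    cutoffs = (0.2, 0.4, 0.6, 0.8)
    grades, counts = grade_lines(mfvd, cutoffs)
    assert grades.tolist() == ["I", "II", "III", "IV", "V", "III"]
    assert counts.sum() == 6
    # boundary is lower-inclusive on the upper side
    g2, _ = grade_lines(pd.Series([0.8, 0.2]), cutoffs)
    assert g2.tolist() == ["V", "II"]
    with pytest.raises(ValueError):
        grade_lines(mfvd, (0.4, 0.2, 0.6, 0.8))


def test_identical_scores_land_in_one_level():
    mfvd = pd.Series([0.5] * 8)
    grades, counts = grade_lines(mfvd, (0.1, 0.3, 0.6, 0.9))
    assert grades.nunique() == 1 and counts.sum() == 8


def test_default_cutoffs_match_normal_quantiles():
    """mean +/- 1.5 and 0.5 SD bands on a standard-normal sample give
    level proportions ~ (6.7, 24.2, 38.3, 24.2, 6.7)%."""
    rng = np.random.default_rng(8)
    mfvd = pd.Series(rng.normal(0, 1, 10_000))
    _, counts = grade_lines(mfvd)
    props = counts / counts.sum()
    expect = np.array([0.0668, 0.2417, 0.3829, 0.2417, 0.0668])
    np.testing.assert_allclose(props.to_numpy(), expect, atol=0.015)


def test_grading_monotone_in_score():
    rng = np.random.default_rng(9)
    mfvd = pd.Series(rng.uniform(0, 1, 200)).sort_values()
    grades, _ = grade_lines(mfvd, (0.2, 0.4, 0.6, 0.8))
    codes = grades.cat.codes.to_numpy()
    assert (np.diff(codes) >= 0).all()


# ---------------------------------------------------------------------------
# correlation network


def test_fourteen_traits_give_91_edges():
    rng = np.random.default_rng(10)
    drc = pd.DataFrame(rng.normal(1, 0.1, (50, 14)),
                       columns=[f"T{i}" for i in range(14)])
    edges = correlation_network(drc)
    assert len(edges) == 91  # C(14, 2)


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(11)
    drc = pd.DataFrame(rng.normal(0, 1, (50, 5)), columns=list("ABCDE"))
    edges = correlation_network(drc)
    for _, e in edges.iterrows():
        x, y = drc[e["trait_a"]], drc[e["trait_b"]]
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert e["r"] == pytest.approx(r, abs=1e-12)


def test_duplicated_and_constant_traits():
    rng = np.random.default_rng(12)
    drc = pd.DataFrame({"A": rng.normal(size=30)})
    drc["B"] = drc["A"]
    drc["C"] = 1.0
    edges = correlation_network(drc).set_index(["trait_a", "trait_b"])
    ab = edges.loc[("A", "B")]
    assert ab["r"] == pytest.approx(1.0) and ab["p"] < 1e-20 and ab["significant"]
    assert np.isnan(edges.loc[("A", "C"), "r"])
    assert not edges.loc[("A", "C"), "significant"]


def test_significance_rule():
    rng = np.random.default_rng(13)
    x = rng.normal(size=200)
    drc = pd.DataFrame({"A": x, "B": x + rng.normal(scale=3, size=200),
                        "C": rng.normal(size=200)})
    edges = correlation_network(drc)
    for _, e in edges.iterrows():
        assert e["significant"] == (e["p"] < 0.05 and abs(e["r"]) > 0.1)


# ---------------------------------------------------------------------------
# physiology


def test_physiology_formulas():
    m = PhysiologyMeasurement(C1=30.0, C2=30.0, A532=0.4, A600=0.4, fresh_weight=1.0,
                              ct_target_treated=20, ct_ref_treated=18,
                              ct_target_control=21, ct_ref_control=19)
    out = physiology(m)
    assert out["rec"] == pytest.approx(100.0)
    assert out["mda"] == pytest.approx(0.0)
    assert out["fold_expression"] == pytest.approx(1.0)
    out2 = physiology(PhysiologyMeasurement(A532=0.5, A600=0.4, fresh_weight=0.5))
    assert out2["mda"] == pytest.approx(5.16)  # 25.8 x 0.1 / 0.5
    with pytest.warns(UserWarning):
        assert np.isnan(physiology(PhysiologyMeasurement(C1=1.0, C2=0.0))["rec"])
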