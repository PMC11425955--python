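"""Phenomics scoring for drought trials.

Implements the per-line aggregation and drought-resistance statistics:

* best linear unbiased prediction (BLUP) of line values from the mixed model
  ``value = mu + year + rep(year) + line + error`` with the line effect
  random, fitted by EM restricted maximum likelihood;
* the drought-resistance coefficient DRC = drought value / control value;
* the membership-function composite score MFVD (mean of min-max rescaled
  DRC over a basis set of yield and fiber-quality traits) and its
  five-level drought-resistance grading;
* condition summaries (mean, SD, CV, percent change under drought);
* a Pearson correlation network over DRC traits;
* the physiology formulas REC = C1/C2 x 100,
  MDA = 25.8 x (A532 - A600) / fresh weight, and relative expression by
  2^-(ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CONDITIONS
from .simulate import BASIS_TRAITS

__all__ = [
    "BlupModel",
    "BlupResults",
    "fit_blup",
    "blup_table",
    "summarize_condition",
    "percent_change",
    "compute_drc",
    "compute_mfvd",
    "default_cutoffs",
    "grade_lines",
    "correlation_network",
    "PhysiologyMeasurement",
    "physiology",
    "DroughtTrial",
    "DroughtTrialResults",
]


# ---------------------------------------------------------------------------
# BLUP


class BlupModel:
    """Single-trait, single-condition mixed model with a random line effect.

    value = mu + year (fixed) + replicate-within-year (fixed)
            + line (random, iid N(0, sigma_g^2)) + residual

    Variance components are estimated by EM-REML (relative tolerance
    ``tol``, at most ``max_iter`` sweeps); the reported per-line value is
    the average fixed-effect prediction plus the line BLUP.
    """

    def __init__(self, observations: pd.DataFrame, trait: str, condition: str):
        sub = observations[
            (observations["trait"] == trait) & (observations["condition"] == condition)
        ]
        if sub.empty:
            raise ValueError(f"no observations for {trait}/{condition}")
        if sub["line_id"].nunique() < 2:
            raise ValueError("need at least 2 lines")
        self.trait = trait
        self.condition = condition
        self._y = sub["value"].to_numpy(float)
        self._lines = pd.Categorical(sub["line_id"])
        self.line_ids = list(self._lines.categories)
        # fixed design: intercept + year + rep-within-year (treatment coding)
        year = pd.Categorical(sub["year"])
        yr = pd.get_dummies(year, drop_first=True, dtype=float).to_numpy()
        rep_in_year = pd.Categorical(
            sub["year"].astype(str) + ":" + sub["replicate"].astype(str)
        )
        rp = pd.get_dummies(rep_in_year, drop_first=True, dtype=float).to_numpy()
        n = len(sub)
        X = np.column_stack([np.ones(n), yr, rp])
        # drop collinear rep columns (rep nested in year duplicates year dummies
        # when a year has a single replicate)
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        self._X = X[:, keep]
        self._Z = pd.get_dummies(self._lines, dtype=float).to_numpy()

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> "BlupResults":
        y, X, Z = self._y, self._X, self._Z
        n, p = X.shape
        q = Z.shape[1]
        vy = max(float(np.var(y)), 1e-12)
        su2, se2 = 0.5 * vy, 0.5 * vy
        floor = 1e-10 * vy
        XtX, XtZ, Xty = X.T @ X, X.T @ Z, X.T @ y
        ZtZ, Zty = Z.T @ Z, Z.T @ y
        yty = float(y @ y)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            lam = se2 / su2
            A = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * np.eye(q)]])
            rhs = np.concatenate([Xty, Zty])
            C = np.linalg.inv(A)
            sol = C @ rhs
            b, u = sol[:p], sol[p:]
            se2_new = (yty - b @ Xty - u @ Zty) / (n - p)
            se2_new = max(float(se2_new), floor)
            su2_new = (u @ u + se2_new * np.trace(C[p:, p:])) / q
            su2_new = max(float(su2_new), floor)
            delta = max(abs(su2_new - su2), abs(se2_new - se2)) / vy
            su2, se2 = su2_new, se2_new
            if delta < tol:
                break
        # final solve at the converged components
        lam = se2 / su2
        A = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * np.eye(q)]])
        sol = np.linalg.solve(A, np.concatenate([Xty, Zty]))
        b, u = sol[: p], sol[p:]
        grand = float(np.mean(X @ b))
        values = pd.Series(grand + u, index=pd.Index(self.line_ids, name="line_id"))
        return BlupResults(
            trait=self.trait,
            condition=self.condition,
            values=values,
            line_effects=pd.Series(u, index=values.index),
            grand_mean=grand,
            fixed_effects=b,
            sigma2_line=su2,
            sigma2_residual=se2,
            n_obs=n,
            n_iter=n_iter,
        )


@dataclass
class BlupResults:
    """Fitted per-line values and variance components for one trait/condition."""

    trait: str
    condition: str
    values: pd.Series  # grand mean + line BLUP
    line_effects: pd.Series
    grand_mean: float
    fixed_effects: np.ndarray
    sigma2_line: float
    sigma2_residual: float
    n_obs: int
    n_iter: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "trait": self.trait,
                "condition": self.condition,
                "n_obs": self.n_obs,
                "grand_mean": self.grand_mean,
                "sigma2_line": self.sigma2_line,
                "sigma2_residual": self.sigma2_residual,
                "n_iter": self.n_iter,
            }
        )


def fit_blup(observations: pd.DataFrame, trait: str, condition: str, **kw) -> BlupResults:
    """Convenience wrapper: build and fit :class:`BlupModel`."""
    return BlupModel(observations, trait, condition).fit(**kw)


def blup_table(observations: pd.DataFrame, traits=None, **kw) -> pd.DataFrame:
    """Per-line BLUP values for every trait x condition, wide on conditions.

    Lines absent from a trait/condition cell are NaN (flagged, not imputed).
    Returns a frame indexed by line_id with a (trait, condition) column
    MultiIndex.
    """
    traits = list(traits) if traits is not None else sorted(observations["trait"].unique())
    pieces = {}
    for t in traits:
        for c in CONDITIONS:
            pieces[(t, c)] = fit_blup(observations, t, c, **kw).values
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["trait", "condition"])
    return out


# ---------------------------------------------------------------------------
# condition summaries, DRC, MFVD


def percent_change(mean_control: float, mean_drought: float) -> float:
    """100 x (control - drought) / control; positive = reduction under drought."""
    if mean_control == 0:
        raise ZeroDivisionError("percent change undefined for zero control mean")
    return 100.0 * (mean_control - mean_drought) / mean_control


def summarize_condition(blups: pd.DataFrame, trait: str) -> dict:
    """Mean/SD/CV per condition plus the percent change under drought."""
    out: dict = {"trait": trait}
    for c in CONDITIONS:
        v = blups[(trait, c)].dropna()
        out[f"mean_{c}"] = float(v.mean())
        out[f"sd_{c}"] = float(v.std(ddof=1))
        out[f"cv_{c}"] = float(v.std(ddof=1) / v.mean()) if v.mean() != 0 else np.nan
    mc, md = out["mean_control"], out["mean_drought"]
    out["percent_change"] = percent_change(mc, md) if mc != 0 else np.nan
    return out


def compute_drc(blups: pd.DataFrame) -> pd.DataFrame:
    """Drought-resistance coefficient per line and trait.

    DRC = drought value / control value; cells with a nonpositive or
    missing control value are NaN (flagged), never silently zero.
    """
    traits = blups.columns.get_level_values("trait").unique()
    out = {}
    for t in traits:
        ctrl = blups[(t, "control")]
        drt = blups[(t, "drought")]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = drt / ctrl
        out[t] = ratio.where(ctrl > 0)
    return pd.DataFrame(out)


def compute_mfvd(
    drc: pd.DataFrame,
    basis_traits=BASIS_TRAITS,
    orientation: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Membership-function composite drought-resistance score.

    Membership of line x for a higher-better trait t is
    ``(x - min_t) / (max_t - min_t)`` over the population (lower-better
    traits use the mirrored form); MFVD is the arithmetic mean over the
    basis traits. Lines with undefined DRC on some basis traits are scored
    over the available ones, with the missing count recorded.
    """
    basis = list(basis_traits)
    missing = [t for t in basis if t not in drc.columns]
    if missing:
        raise KeyError(f"basis traits absent from DRC table: {missing}")
    orient = {t: "higher" for t in basis}
    orient.update(orientation or {})
    memb = {}
    for t in basis:
        x = drc[t]
        lo, hi = x.min(), x.max()
        if not np.isfinite(hi - lo) or hi == lo:
            warnings.warn(f"trait {t}: constant DRC, memberships set to 0.5")
            m = pd.Series(0.5, index=x.index).where(x.notna())
        elif orient[t] == "higher":
            m = (x - lo) / (hi - lo)
        else:
            m = (hi - x) / (hi - lo)
        memb[f"membership_{t}"] = m
    out = pd.DataFrame(memb)
    out["n_missing"] = out.isna().sum(axis=1)
    out["mfvd"] = out[[f"membership_{t}" for t in basis]].mean(axis=1)
    return out


def default_cutoffs(mfvd: pd.Series) -> tuple[float, float, float, float]:
    """Five-band cutoffs at mean -/+ 1.5 and 0.5 SD of the score distribution."""
    mu, sd = float(mfvd.mean()), float(mfvd.std(ddof=1))
    return (mu - 1.5 * sd, mu - 0.5 * sd, mu + 0.5 * sd, mu + 1.5 * sd)


GRADES = ("I", "II", "III", "IV", "V")


def grade_lines(
    mfvd: pd.Series, cutoffs: tuple[float, float, float, float] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Assign drought-resistance grades I (sensitive) .. V (tolerant).

    Intervals are half-open, lower-inclusive on the upper side: a line is
    grade V iff mfvd >= c4. Returns (per-line grades, level counts).
    """
    cuts = cutoffs if cutoffs is not None else default_cutoffs(mfvd.dropna())
    if not all(cuts[i] < cuts[i + 1] for i in range(3)):
        raise ValueError("cutoffs must be strictly ascending")
    idx = np.searchsorted(np.asarray(cuts), mfvd.to_numpy(float), side="right")
    grades = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(GRADES)), index=mfvd.index
    ).where(mfvd.notna())
    counts = grades.value_counts().reindex(GRADES, fill_value=0)
    return grades, counts


def correlation_network(drc: pd.DataFrame, p_max: float = 0.05, r_min: float = 0.1) -> pd.DataFrame:
    """Pearson correlation edge list over all unordered trait pairs.

    One edge per pair (n traits -> n(n-1)/2 edges); an edge is significant
    when p < ``p_max`` and |r| > ``r_min``. Constant traits give an
    undefined (NaN) r, flagged not significant.
    """
    traits = list(drc.columns)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            pair = drc[[a, b]].dropna()
            if len(pair) >= 3 and pair[a].std() > 0 and pair[b].std() > 0:
                r, p = stats.pearsonr(pair[a], pair[b])
            else:
                r, p = np.nan, np.nan
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "n": len(pair),
                    "r": r,
                    "p": p,
                    "significant": bool(np.isfinite(r) and p < p_max and abs(r) > r_min),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# physiology formulas


@dataclass
class PhysiologyMeasurement:
    """Raw leaf-assay readings for one sample."""

    C1: float = np.nan  # initial conductivity
    C2: float = np.nan  # conductivity after boiling
    A532: float = np.nan
    A600: float = np.nan
    fresh_weight: float = np.nan  # g
    ct_target_treated: float = np.nan
    ct_ref_treated: float = np.nan
    ct_target_control: float = np.nan
    ct_ref_control: float = np.nan


def physiology(m: PhysiologyMeasurement) -> dict[str, float]:
    """REC, MDA content and relative expression from raw readings.

    rec = C1/C2 x 100 (percent); mda = 25.8 x (A532 - A600)/fresh_weight
    (nmol per g fresh weight); fold_expression = 2^-(ddCt).
    Undefined quantities (zero C2, nonpositive fresh weight, missing Cts)
    come back NaN.
    """
    out = {"rec": np.nan, "mda": np.nan, "fold_expression": np.nan}
    if np.isfinite(m.C1) and np.isfinite(m.C2):
        if m.C2 == 0:
            warnings.warn("C2 = 0: REC undefined")
        else:
            if not (0 <= m.C1 <= m.C2):
                warnings.warn("expected 0 <= C1 <= C2; REC computed anyway")
            out["rec"] = m.C1 / m.C2 * 100.0
    if np.isfinite(m.A532) and np.isfinite(m.A600) and np.isfinite(m.fresh_weight):
        if m.fresh_weight <= 0:
            raise ValueError("fresh weight must be positive")
        out["mda"] = 25.8 * (m.A532 - m.A600) / m.fresh_weight
    cts = (m.ct_target_treated, m.ct_ref_treated, m.ct_target_control, m.ct_ref_control)
    if all(np.isfinite(c) for c in cts):
        ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
        out["fold_expression"] = 2.0 ** (-ddct)
    return out


# ---------------------------------------------------------------------------
# the model-level wrapper


class DroughtTrial:
    """End-to-end phenomics model for a drought trial.

    Built from the long observation table; ``fit()`` runs BLUP for every
    trait x condition and derives DRC, MFVD, grades, condition summaries
    and the correlation network in one Results object.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        basis_traits=BASIS_TRAITS,
        orientation: dict[str, str] | None = None,
        cutoffs: tuple[float, float, float, float] | None = None,
    ):
        need = {"line_id", "trait", "condition", "year", "replicate", "value"}
        if not need.issubset(observations.columns):
            raise ValueError(f"observation table must have columns {sorted(need)}")
        self.observations = observations
        self.basis_traits = tuple(basis_traits)
        self.orientation = orientation
        self.cutoffs = cutoffs

    def fit(self) -> "DroughtTrialResults":
        blups = blup_table(self.observations)
        traits = blups.columns.get_level_values("trait").unique()
        summaries = pd.DataFrame([summarize_condition(blups, t) for t in traits])
        drc = compute_drc(blups)
        mfvd = compute_mfvd(drc, self.basis_traits, self.orientation)
        grades, counts = grade_lines(mfvd["mfvd"], self.cutoffs)
        edges = correlation_network(drc)
        return DroughtTrialResults(
            blups=blups,
            summaries=summaries,
            drc=drc,
            mfvd=mfvd,
            grades=grades,
            grade_counts=counts,
            edges=edges,
        )


@dataclass
class DroughtTrialResults:
    """Phenomics results bundle; see :class:`DroughtTrial`."""

    blups: pd.DataFrame
    summaries: pd.DataFrame
    drc: pd.DataFrame
    mfvd: pd.DataFrame
    grades: pd.Series
    grade_counts: pd.Series
    edges: pd.DataFrame

    def summary(self) -> str:
        n_sig = int(self.edges["significant"].sum())
        lines = [
            "Drought trial phenomics",
            f"  lines graded: {int(self.grades.notna().sum())}",
            "  grade counts: "
            + ", ".join(f"{g}={int(self.grade_counts[g])}" for g in GRADES),
            f"  correlation edges: {len(self.edges)} ({n_sig} significant)",
            "  percent change under drought (by trait):",
        ]
        for _, row in self.summaries.iterrows():
            lines.append(
                f"    {row['trait']:>6}: {row['percent_change']:+7.3f}%"
                f"  (control {row['mean_control']:.3f} -> drought {row['mean_drought']:.3f})"
            )
        return "\n".join(lines)
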