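"""Aggregation and statistics for the fatigue protocol.

Block averaging of per-contraction metrics (four-set blocks or five 20 %
intervals of 32 contractions, as % of each subject's protocol maximum),
per-subject percent changes, standardized-coefficient OLS and forward
stepwise regression, one-way repeated-measures ANOVA with Tukey HSD post
hoc on the within-subject error term, mono-exponential VO2 kinetics, and
blood-lactate accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    CollinearityError,
    FitFailureError,
    InvalidInputError,
    UnbalancedDesignError,
)

__all__ = [
    "RegressionResult",
    "ExpFitResult",
    "block_average",
    "percent_change",
    "mean_percent_change",
    "ols_standardized",
    "forward_stepwise",
    "rm_anova",
    "tukey_posthoc",
    "fit_monoexp",
    "lactate_accumulation",
]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def block_average(values: pd.DataFrame, grouping: str = "four_sets",
                  value_col: str = "value") -> pd.DataFrame:
    """Block means ± SD of a per-contraction metric, as % of subject maximum.

    ``values`` needs columns ``subject``, ``set``, ``rep`` and ``value_col``.
    Each subject's values are first expressed as a percentage of that
    subject's protocol maximum; per-subject block means are then averaged
    across subjects.  ``grouping`` is ``"four_sets"`` (blocks of 4
    consecutive sets) or ``"five_intervals"`` (five equal intervals by
    contraction count, 32 contractions each for the 20×8 protocol).
    """
    if grouping not in ("four_sets", "five_intervals"):
        raise InvalidInputError(f"unknown grouping {grouping!r}")
    df = values.copy()
    df["pct"] = df.groupby("subject")[value_col].transform(
        lambda v: 100.0 * v / v.max())
    if grouping == "four_sets":
        df["block"] = (df["set"] - 1) // 4
        labels = {b: f"sets {4 * b + 1}-{4 * b + 4}" for b in sorted(df["block"].unique())}
    else:
        df = df.sort_values(["subject", "set", "rep"])
        df["idx"] = df.groupby("subject").cumcount()
        n = df.groupby("subject")["idx"].transform("size")
        df["block"] = (5 * df["idx"] // n).clip(upper=4)
        labels = {b: f"interval {b + 1}" for b in range(5)}
    per_subject = df.groupby(["subject", "block"])["pct"].mean().reset_index()
    out = per_subject.groupby("block")["pct"].agg(["mean", "std"]).reset_index()
    out["label"] = out["block"].map(labels)
    return out[["block", "label", "mean", "std"]]


def percent_change(pre: float, post: float) -> float:
    """Relative change ``(post − pre) / pre × 100`` in percent."""
    if pre == 0:
        raise InvalidInputError("pre value must be nonzero")
    return (post - pre) / pre * 100.0


def mean_percent_change(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Group mean ± SD of per-subject percent changes (mean of ratios).

    The subject-level change is computed first and then averaged, matching
    how group changes are conventionally reported; this differs from the
    percent change of the group means when baselines vary across subjects.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise InvalidInputError("pre and post must be equal-length, non-empty")
    changes = (post - pre) / pre * 100.0
    return float(changes.mean()), float(changes.std(ddof=1)) if changes.size > 1 else 0.0


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    r2: float
    betas: dict[str, float]         # standardized coefficients
    p_values: dict[str, float]
    included: list[str] = field(default_factory=list)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise CollinearityError("constant column cannot be z-scored")
    return (a - a.mean()) / sd


def ols_standardized(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """OLS on z-scored response and predictors; betas are standardized
    coefficients with their t-test p-values, plus the model R²."""
    import statsmodels.api as sm

    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidInputError(f"need n > p + 1 (n={n}, p={p})")
    Xz = np.column_stack([_zscore(X[c].to_numpy(dtype=float)) for c in X.columns])
    if np.linalg.matrix_rank(Xz) < p:
        raise CollinearityError("predictor matrix is rank deficient")
    yz = _zscore(y)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    names = list(X.columns)
    return RegressionResult(
        r2=float(model.rsquared),
        betas={c: float(b) for c, b in zip(names, model.params[1:])},
        p_values={c: float(pv) for c, pv in zip(names, model.pvalues[1:])},
        included=names)


def forward_stepwise(y: np.ndarray, X: pd.DataFrame, alpha_in: float = 0.05,
                     collinearity_r: float = 0.9) -> RegressionResult:
    """Forward stepwise OLS with standardized coefficients.

    Predictors enter in order of R² gain while the entering predictor's
    partial F-test has p < ``alpha_in`` and it is not correlated (|r| >
    ``collinearity_r``) with an already-included predictor.  With a single
    surviving predictor this reduces to simple regression; if nothing
    enters, the result has an empty model (R² = 0, no betas).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    included: list[str] = []
    remaining = list(X.columns)
    current_r2 = 0.0
    while remaining:
        best = None
        for cand in remaining:
            cols = included + [cand]
            try:
                res = ols_standardized(y, X[cols])
            except CollinearityError:
                continue
            if best is None or res.r2 > best[1]:
                best = (cand, res.r2)
        if best is None:
            break
        cand, r2_new = best
        # partial F test for the entering predictor
        p_new = len(included) + 1
        df_resid = n - p_new - 1
        if df_resid <= 0:
            break
        if r2_new >= 1.0 - 1e-15:
            p_val = 0.0
        else:
            f_stat = (r2_new - current_r2) / ((1.0 - r2_new) / df_resid)
            p_val = float(stats.f.sf(f_stat, 1, df_resid))
        if p_val >= alpha_in:
            break
        if included:
            r_with_included = np.abs([
                np.corrcoef(X[cand].to_numpy(dtype=float),
                            X[c].to_numpy(dtype=float))[0, 1]
                for c in included])
            if np.any(r_with_included > collinearity_r):
                remaining.remove(cand)
                continue
        included.append(cand)
        remaining.remove(cand)
        current_r2 = r2_new
    if not included:
        return RegressionResult(r2=0.0, betas={}, p_values={}, included=[])
    out = ols_standardized(y, X[included])
    out.included = included
    return out


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA and Tukey post hoc
# ---------------------------------------------------------------------------

def rm_anova(values: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on a subjects × conditions table.

    F = MS_condition / MS_(condition × subject) with df = (k−1, (k−1)(n−1));
    no sphericity correction is applied (pass the table through
    ``pingouin``/Greenhouse–Geisser externally if one is wanted).
    Returns ``(F, (df1, df2), p)``.
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise UnbalancedDesignError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(a)):
        raise UnbalancedDesignError("table has missing cells")
    n, k = a.shape
    grand = a.mean()
    ss_cond = n * np.sum((a.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((a.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((a - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), (df1, df2), p


def tukey_posthoc(values: np.ndarray) -> pd.DataFrame:
    """Tukey HSD on the condition means of a repeated-measures table.

    Uses the studentized range distribution with the RM ANOVA interaction
    error term (MS_error, df = (k−1)(n−1)), i.e. the error the omnibus test
    used — not the between-group MS of an independent-groups Tukey test.
    Returns a DataFrame of pairwise mean differences and p-values.
    """
    a = np.asarray(values, dtype=float)
    f, (df1, df2), _ = rm_anova(a)  # validates the table shape
    n, k = a.shape
    grand = a.mean()
    ss_total = np.sum((a - grand) ** 2)
    ss_cond = n * np.sum((a.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((a.mean(axis=1) - grand) ** 2)
    ms_err = (ss_total - ss_cond - ss_subj) / df2
    means = a.mean(axis=0)
    rows = []
    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df2))
            rows.append({"a": i, "b": j, "diff": float(diff), "p": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VO2 kinetics and lactate
# ---------------------------------------------------------------------------

@dataclass
class ExpFitResult:
    asymptote: float       # mL·min⁻¹·kg⁻¹
    tau: float             # s
    baseline: float        # mL·min⁻¹·kg⁻¹
    sse: float
    tau_identifiable: bool = True


def fit_monoexp(t: np.ndarray, y: np.ndarray) -> ExpFitResult:
    """Least-squares fit of ``y(t) = y0 + (A − y0)(1 − e^{−t/τ})``.

    τ is initialized by a grid search (for each trial τ the linear
    parameters have a closed-form solution) and the best candidate refined
    with ``scipy.optimize.curve_fit``.  A constant series returns its mean
    as the asymptote with ``tau_identifiable=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 5:
        raise InvalidInputError("need >= 5 (t, y) points")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        return ExpFitResult(asymptote=float(y.mean()), tau=float("nan"),
                            baseline=float(y.mean()), sse=0.0,
                            tau_identifiable=False)

    span = t.max() - t.min()
    best = None
    for tau in np.geomspace(span / 100.0, span * 3.0, 40):
        basis = 1.0 - np.exp(-t / tau)
        design = np.column_stack([np.ones_like(t), basis])
        coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((design @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tau, coef)
    _, tau0, coef0 = best
    y0_0, delta0 = coef0

    def model(tt, y0, a, tau):
        return y0 + (a - y0) * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = optimize.curve_fit(model, t, y,
                                     p0=[y0_0, y0_0 + delta0, tau0],
                                     maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitFailureError(f"mono-exponential fit did not converge: {exc}") from exc
    y0, a, tau = map(float, popt)
    if tau <= 0:
        raise FitFailureError(f"fit returned non-positive time constant τ={tau:.4g}")
    sse = float(np.sum((model(t, *popt) - y) ** 2))
    return ExpFitResult(asymptote=a, tau=tau, baseline=y0, sse=sse)


def lactate_accumulation(pre: float, post: float) -> float:
    """Blood lactate accumulation: post − pre (mmol·L⁻¹)."""
    return post - pre
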