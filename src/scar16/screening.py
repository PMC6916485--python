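"""Univariate distribution tests and bivariate association screening.

Implements the battery applied to the cohort: Shapiro-Wilk / likelihood-
ratio chi-square for variable distributions, pooled t tests, one-way ANOVA
with Tukey-Kramer post hocs, OLS regression, two-tailed Fisher's exact
tests on 2xk contingency tables, and Benjamini-Hochberg FDR adjustment
within each screening family (default cutoff: Q < 0.10).

Fisher's exact p is the point-probability ("Fisher-Irwin") two-tailed
definition: the sum of the probabilities, under fixed margins, of every
table no more probable than the observed one.  2x2 tables use the same
enumeration path as 2x3 tables; the doubled one-tail alternative is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "test_distribution",
    "fisher_exact",
    "two_group_t",
    "anova_tukey",
    "simple_regression",
    "bh_adjust",
    "screen",
    "results_table",
]


class DegenerateDataError(ValueError):
    """Raised when a test's input has no variation to analyze."""


@dataclass
class TestResult:
    """One association or distribution test with its multiplicity-adjusted Q."""

    test_name: str
    y_var: str
    x_var: str | None
    statistic: float
    p: float
    n_used: int
    q: float | None = None
    group_summaries: dict = field(default_factory=dict)
    posthoc: list | None = None
    extra: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    flagged: bool | None = None


# ------------------------------------------------------------ distribution

def test_distribution(values, var_type: str, var_name: str = "") -> TestResult:
    """Distribution test for one variable.

    Continuous: Shapiro-Wilk W against normality.  Categorical:
    likelihood-ratio chi-square against an equal-frequency null over the
    observed levels (df = levels - 1).
    """
    if var_type == "continuous":
        x = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(float)
        if x.size < 3:
            raise ValueError(f"{var_name or 'variable'}: need >= 3 non-missing values")
        if np.ptp(x) == 0:
            raise DegenerateDataError(f"{var_name or 'variable'}: all values identical")
        w, p = stats.shapiro(x)
        summ = {
            "n": int(x.size),
            "median": float(np.median(x)),
            "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
        }
        return TestResult("shapiro_wilk", var_name, None, float(w), float(p),
                          int(x.size), group_summaries=summ)
    if var_type != "categorical":
        raise ValueError(f"unknown var_type {var_type!r}")
    s = pd.Series(values).dropna().astype(str)
    if s.size < 3:
        raise ValueError(f"{var_name or 'variable'}: need >= 3 non-missing values")
    counts = s.value_counts().sort_index()
    if len(counts) < 2:
        raise DegenerateDataError(f"{var_name or 'variable'}: single observed level")
    obs = counts.to_numpy(float)
    expected = obs.sum() / len(obs)
    g = 2.0 * float(np.sum(obs * np.log(obs / expected)))
    g = max(g, 0.0)
    p = float(stats.chi2.sf(g, df=len(obs) - 1))
    summ = {lvl: {"n": int(n), "pct": 100.0 * n / obs.sum()} for lvl, n in counts.items()}
    return TestResult("lr_chi2", var_name, None, g, p, int(obs.sum()),
                      group_summaries=summ)


# ------------------------------------------------------------ fisher exact

def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _fisher_point_prob_two_tailed(table: np.ndarray) -> tuple[float, float]:
    """(two-tailed p, observed point probability) by exhaustive enumeration.

    Sums the conditional (fixed-margin) probability of every 2xk table
    whose point probability does not exceed the observed one (relative
    tolerance 1e-7 for floating-point ties).
    """
    cols = table.sum(axis=0).astype(int)
    r = int(table[0].sum())
    n = int(table.sum())
    denom = _log_comb(n, r)
    lobs = sum(_log_comb(int(cols[j]), int(table[0, j])) for j in range(len(cols))) - denom
    k = len(cols)
    total = 0.0

    def rec(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = acc + _log_comb(int(cols[j]), remaining) - denom
                if lp <= lobs + 1e-7:
                    total += math.exp(lp)
            return
        hi = min(int(cols[j]), remaining)
        lo = max(0, remaining - int(cols[j + 1:].sum()))
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, acc + _log_comb(int(cols[j]), x))

    rec(0, r, 0.0)
    if total > 1.0 - 1e-9:  # snap accumulated rounding when every table counts
        total = 1.0
    return min(total, 1.0), math.exp(lobs)


def fisher_exact(
    table, alternative: str = "two-tailed-point-prob"
) -> TestResult:
    """Fisher's exact test on a 2xk (k in {2, 3}) contingency table.

    ``table`` may be an array of counts or a pandas crosstab.  A zero row
    or column margin yields p = 1 with a warning flag rather than an
    error.  ``alternative="two-tailed-doubled"`` doubles the smaller
    one-tail instead (2x2 only).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must hold nonnegative integer counts")
    arr = np.round(arr).astype(int)
    n = int(arr.sum())
    warnings: list[str] = []
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.append("zero margin: test is vacuous, p set to 1")
        stat = np.nan
        p, point = 1.0, 1.0
    elif alternative == "two-tailed-doubled":
        if arr.shape[1] != 2:
            raise ValueError("doubled one-tail alternative defined for 2x2 only")
        a, b, c, d = arr.ravel()
        less = stats.hypergeom.cdf(a, n, a + b, a + c)
        greater = stats.hypergeom.sf(a - 1, n, a + b, a + c)
        p = float(min(1.0, 2.0 * min(less, greater)))
        point = float(stats.hypergeom.pmf(a, n, a + b, a + c))
        stat = _odds_ratio(arr)
    elif alternative == "two-tailed-point-prob":
        p, point = _fisher_point_prob_two_tailed(arr)
        stat = _odds_ratio(arr) if arr.shape[1] == 2 else np.nan
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        "fisher_exact", "", None, float(stat), float(p), n,
        extra={"point_prob": float(point), "table": arr.tolist()},
        warnings=warnings,
    )


def _odds_ratio(arr: np.ndarray) -> float:
    a, b, c, d = arr.ravel().astype(float)
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


# ------------------------------------------------------- group comparisons

def _level_summary(y: np.ndarray) -> dict:
    n = y.size
    mean = float(y.mean())
    if n > 1 and y.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, n - 1) * y.std(ddof=1) / math.sqrt(n)
    else:
        half = 0.0
    return {"n": int(n), "mean": mean, "median": float(np.median(y)),
            "ci95": (mean - half, mean + half)}


def two_group_t(y, group, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test (pooled variance by default).

    Reports per-group means with 95% CIs and the difference (level1 -
    level2, levels in sorted order) with its CI.
    """
    frame = pd.DataFrame({"y": pd.to_numeric(pd.Series(y), errors="coerce"),
                          "g": pd.Series(group).astype(str)}).dropna()
    levels = sorted(frame["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    y1 = frame.loc[frame["g"] == levels[0], "y"].to_numpy(float)
    y2 = frame.loc[frame["g"] == levels[1], "y"].to_numpy(float)
    if y1.size < 2 or y2.size < 2:
        raise ValueError("both groups need >= 2 values")
    t, p = stats.ttest_ind(y1, y2, equal_var=not welch)
    diff = float(y1.mean() - y2.mean())
    n1, n2 = y1.size, y2.size
    if welch:
        se = math.sqrt(y1.var(ddof=1) / n1 + y2.var(ddof=1) / n2)
        df = (y1.var(ddof=1) / n1 + y2.var(ddof=1) / n2) ** 2 / (
            (y1.var(ddof=1) / n1) ** 2 / (n1 - 1) + (y2.var(ddof=1) / n2) ** 2 / (n2 - 1)
        ) if se > 0 else n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * y1.var(ddof=1) + (n2 - 1) * y2.var(ddof=1)) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    half = stats.t.ppf(0.975, df) * se if se > 0 else 0.0
    if np.isnan(t):  # identical constant groups
        t, p = 0.0, 1.0
    return TestResult(
        "t_test" if not welch else "welch_t", "", None, float(t), float(p),
        int(n1 + n2),
        group_summaries={levels[0]: _level_summary(y1), levels[1]: _level_summary(y2)},
        extra={"mean_diff": diff, "diff_ci95": (diff - half, diff + half),
               "levels": levels},
    )


def anova_tukey(y, group) -> TestResult:
    """One-way ANOVA with Tukey-Kramer post hoc pairwise comparisons.

    Levels with fewer than 2 observations are excluded and reported in
    ``warnings``; Tukey-Kramer handles unbalanced group sizes.
    """
    frame = pd.DataFrame({"y": pd.to_numeric(pd.Series(y), errors="coerce"),
                          "g": pd.Series(group).astype(str)}).dropna()
    sizes = frame["g"].value_counts()
    dropped = sorted(sizes[sizes < 2].index)
    warnings = [f"singleton level(s) excluded: {dropped}"] if dropped else []
    frame = frame[~frame["g"].isin(dropped)]
    levels = sorted(frame["g"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    groups = [frame.loc[frame["g"] == lvl, "y"].to_numpy(float) for lvl in levels]
    with np.errstate(all="ignore"):
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # zero between- and within-group variance
        f, p = 0.0, 1.0
    posthoc = None
    if frame["y"].nunique() > 1:
        tk = pairwise_tukeyhsd(frame["y"].to_numpy(float), frame["g"].to_numpy(), alpha=0.05)
        pairs = list(zip(*np.triu_indices(len(tk.groupsunique), 1)))
        posthoc = [
            {
                "level_a": str(tk.groupsunique[i]),
                "level_b": str(tk.groupsunique[j]),
                "mean_diff": float(md),
                "p_adj": float(pv),
                "ci95": (float(lo), float(hi)),
            }
            for (i, j), md, pv, (lo, hi) in zip(pairs, tk.meandiffs, tk.pvalues, tk.confint)
        ]
    return TestResult(
        "anova", "", None, float(f), float(p), int(len(frame)),
        group_summaries={lvl: _level_summary(g) for lvl, g in zip(levels, groups)},
        posthoc=posthoc, warnings=warnings,
    )


def simple_regression(y, x) -> TestResult:
    """OLS of y on x: slope, R^2, F-test p and 95% confidence-band parameters."""
    frame = pd.DataFrame({"y": pd.to_numeric(pd.Series(y), errors="coerce"),
                          "x": pd.to_numeric(pd.Series(x), errors="coerce")}).dropna()
    if len(frame) < 3:
        raise ValueError("need >= 3 complete pairs")
    xv = frame["x"].to_numpy(float)
    yv = frame["y"].to_numpy(float)
    if np.ptp(xv) == 0:
        raise DegenerateDataError("x has zero variance")
    res = stats.linregress(xv, yv)
    n = xv.size
    resid = yv - (res.intercept + res.slope * xv)
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    p = float(res.pvalue)
    if np.ptp(yv) == 0 or math.isnan(p):  # exact fit or constant y
        p = 0.0 if np.ptp(yv) != 0 else 1.0
    return TestResult(
        "regression", "", None, float(res.slope), p, int(n),
        extra={
            "intercept": float(res.intercept),
            "r2": float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
            "resid_var": s2,
            "mean_x": float(xv.mean()),
            "ssx": float(((xv - xv.mean()) ** 2).sum()),
        },
    )


# ---------------------------------------------------------------- BH / FDR

def bh_adjust(pvalues, family_label: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up Q values, in the input order, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"p-values outside [0, 1] in family {family_label!r}")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ screen

def _infer_type(series: pd.Series) -> str:
    if series.dtype.kind in "biufc" and series.dtype.kind != "b":
        return "continuous"
    return "categorical"


def screen(
    data: pd.DataFrame,
    y_var: str,
    x_vars: Sequence[str],
    var_types: Mapping[str, str] | None = None,
    fdr: float = 0.10,
    welch: bool = False,
) -> list[TestResult]:
    """Association screen of one response against several candidate variables.

    Dispatch per type pair: continuous x continuous -> regression;
    continuous x categorical -> t test (2 levels) or ANOVA (>2);
    categorical x categorical -> Fisher's exact (2xk).  Each test uses the
    complete cases for its variable pair; Q values are BH-adjusted within
    this screen as one family and flagged at Q < ``fdr``.
    """
    var_types = dict(var_types or {})
    results: list[TestResult] = []
    y_type = var_types.get(y_var) or _infer_type(data[y_var])
    for x_var in x_vars:
        if x_var == y_var:
            continue
        sub = data[[y_var, x_var]].dropna()
        x_type = var_types.get(x_var) or _infer_type(data[x_var])
        try:
            res = _dispatch(sub, y_var, y_type, x_var, x_type, welch=welch)
        except (ValueError, DegenerateDataError):
            # untestable after complete-case filtering (e.g. a factor left
            # with a single usable level); excluded from the family
            continue
        res.y_var, res.x_var = y_var, x_var
        results.append(res)
    qs = bh_adjust([r.p for r in results], family_label=f"screen:{y_var}")
    for r, q in zip(results, qs):
        r.q = float(q)
        r.flagged = bool(q < fdr)
    return results


def _dispatch(sub, y_var, y_type, x_var, x_type, welch=False) -> TestResult:
    if y_type == "continuous" and x_type == "continuous":
        return simple_regression(sub[y_var], sub[x_var])
    if y_type == "continuous" and x_type == "categorical":
        vals, grp = sub[y_var], sub[x_var]
    elif y_type == "categorical" and x_type == "continuous":
        vals, grp = sub[x_var], sub[y_var]
    else:
        ct = pd.crosstab(sub[y_var].astype(str), sub[x_var].astype(str))
        if ct.shape[0] != 2 and ct.shape[1] == 2:
            ct = ct.T
        if ct.shape[0] == 2 and ct.shape[1] in (2, 3):
            return fisher_exact(ct.to_numpy())
        res_g, res_p, _, _ = stats.chi2_contingency(ct, lambda_="log-likelihood")
        return TestResult("lr_chi2_independence", y_var, x_var, float(res_g),
                          float(res_p), int(ct.to_numpy().sum()),
                          warnings=["table larger than 2x3: LR chi-square used"])
    grp = grp.astype(str)
    effective = (grp.value_counts() >= 2).sum()
    if effective == 2 and grp.nunique() == 2:
        return two_group_t(vals, grp, welch=welch)
    return anova_tukey(vals, grp)


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tidy one-row-per-test export (test, y, x, n, statistic, p, q, flagged)."""
    return pd.DataFrame(
        [
            {
                "test_name": r.test_name,
                "y": r.y_var,
                "x": r.x_var,
                "n": r.n_used,
                "statistic": r.statistic,
                "p": r.p,
                "q": r.q,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
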