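"""Group-comparison statistics with explicit contracts.

Thin, contract-checked wrappers around scipy and statsmodels for the
tests used throughout the xenograft analysis: Student's t (pooled by
default, Welch by flag), one-way ANOVA with Tukey HSD contrasts,
two/three-way factorial ANOVA (Type II sums of squares by default,
order-invariant for main effects in unbalanced designs), Pearson
chi-square on 2×2 tables (no continuity correction unless requested)
and Pearson correlation.  Every result carries its statistic, p-value,
degrees of freedom, tail convention and any adjustment applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult", "DegenerateTableError", "t_test", "anova_tukey",
    "factorial_anova", "chi_square_2x2", "pearson",
]


class DegenerateTableError(ValueError):
    """A contingency table with a zero marginal cannot be tested."""


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome.

    ``df`` is a float for t-type tests, a (num, den) pair for F-type
    tests.  ``adjusted`` marks multiplicity-adjusted p-values (Tukey).
    ``contrast`` labels which comparison or model term the result
    belongs to; ``direction`` records the alternative for one-tailed
    tests.
    """

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    tails: str = "two"
    df: object = None
    adjusted: bool = False
    contrast: str = ""
    direction: str | None = None
    flags: tuple = ()

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _clean(values, name):
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def t_test(group_a, group_b, tails: str = "two", direction: str = "greater",
           equal_var: bool = True) -> TestResult:
    """Two-sample t-test.

    Pooled-variance (classic Student) by default; set
    ``equal_var=False`` for Welch.  With ``tails="one"`` the alternative
    is that ``group_a``'s mean is ``direction`` ("greater"/"less") than
    ``group_b``'s: the one-tailed p is half the two-tailed p when the
    observed difference matches the alternative, else one minus that
    half.  Groups that are both constant and equal have no evidence
    either way: p = 1 with a ``degenerate`` flag.
    """
    a = _clean(group_a, "group_a")
    b = _clean(group_b, "group_b")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    df = (a.size + b.size - 2) if equal_var else None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, tails=tails, df=df,
                          direction=direction if tails == "one" else None,
                          flags=("degenerate",))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    stat, p_two = float(res.statistic), float(res.pvalue)
    if not equal_var:
        df = float(res.df)
    if tails == "two":
        return TestResult(stat, p_two, tails="two", df=df)
    observed_matches = (stat > 0) if direction == "greater" else (stat < 0)
    p_one = p_two / 2.0 if observed_matches else 1.0 - p_two / 2.0
    if stat == 0.0:
        p_one = 0.5
    return TestResult(stat, p_one, tails="one", df=df, direction=direction)


def anova_tukey(values, groups):
    """One-way ANOVA followed by Tukey HSD pairwise contrasts.

    Levels with fewer than two observations are excluded with a
    warning.  Returns ``(omnibus, contrasts)`` where the contrasts carry
    family-wise adjusted p-values.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.shape != groups.shape:
        raise ValueError("values and groups must be paired")
    keep_levels = []
    for level in pd.unique(groups):
        n = int((groups == level).sum())
        if n < 2:
            warnings.warn(f"level {str(level)!r} excluded (n = {n} < 2)",
                          stacklevel=2)
        else:
            keep_levels.append(level)
    if len(keep_levels) < 2:
        raise ValueError("need at least 2 levels with n >= 2")
    mask = np.isin(groups, keep_levels)
    values, groups = values[mask], groups[mask]
    arrays = [values[groups == lv] for lv in keep_levels]
    f_stat, p = sps.f_oneway(*arrays)
    k, n = len(arrays), values.size
    omnibus = TestResult(float(f_stat), float(p), df=(k - 1, n - k),
                         contrast="omnibus")
    tk = pairwise_tukeyhsd(values, groups)
    contrasts = []
    for row in tk.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
        contrasts.append(TestResult(float(meandiff), float(p_adj),
                                    adjusted=True,
                                    contrast=f"{g1} vs {g2}"))
    return omnibus, contrasts


def factorial_anova(data: pd.DataFrame, value: str, factors,
                    typ: int = 2) -> list[TestResult]:
    """Two- or three-way factorial ANOVA with all interactions.

    ``factors`` names 2 or 3 categorical columns of ``data`` (a single
    factor belongs in :func:`anova_tukey`).  Every cell of the full
    factorial design must be populated; an empty cell is an error
    naming the cell.  Sums of squares are Type II by default
    (order-invariant for main effects when the design is unbalanced).
    Returns one :class:`TestResult` per model term, interactions
    included, with the SS type in ``flags``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = list(factors)
    if not 2 <= len(factors) <= 3:
        raise ValueError("factorial_anova takes 2 or 3 factors "
                         "(use anova_tukey for a single factor)")
    df = data[[value] + factors].copy()
    for f in factors:
        df[f] = df[f].astype(str)
    counts = df.groupby(factors, sort=False).size()
    full = pd.MultiIndex.from_product(
        [sorted(df[f].unique()) for f in factors], names=factors)
    missing = full.difference(counts.index)
    if len(missing):
        cell = missing[0]
        cell = cell if isinstance(cell, tuple) else (cell,)
        desc = " x ".join(f"{f}={v}" for f, v in zip(factors, cell))
        raise ValueError(f"empty design cell: {desc}")
    # Patsy chokes on arbitrary column names; remap to safe identifiers.
    safe = {value: "y", **{f: f"f{i}" for i, f in enumerate(factors)}}
    df = df.rename(columns=safe)
    formula = "y ~ " + " * ".join(f"C({safe[f]})" for f in factors)
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    inverse = {f"C({v})": k for k, v in safe.items()}
    resid_df = float(table.loc["Residual", "df"])
    results = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = ":".join(inverse.get(part, part) for part in term.split(":"))
        results.append(TestResult(float(row["F"]), float(row["PR(>F)"]),
                                  df=(float(row["df"]), resid_df),
                                  contrast=name,
                                  flags=(f"type_{'I' * typ}_ss",)))
    return results


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2×2 count table [[a, b], [c, d]].

    No continuity correction by default.  Invariant under simultaneous
    row and column swaps.
    """
    counts = [a, b, c, d]
    if any((not float(x).is_integer()) or x < 0 for x in counts):
        raise ValueError("counts must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        raise DegenerateTableError("degenerate table: grand total is 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("degenerate table: zero marginal")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(float(res.statistic), float(res.pvalue), df=1.0,
                      contrast="2x2 association",
                      flags=("yates",) if correction else ())


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided p.

    Needs at least three finite pairs; a zero-variance input leaves r
    undefined (NaN statistic, ``undefined_zero_variance`` flag) rather
    than raising, so screens over many gene pairs keep running.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, contrast="pearson",
                          flags=("undefined_zero_variance",))
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), df=float(x.size - 2),
                      contrast="pearson")
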