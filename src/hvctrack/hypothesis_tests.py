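"""Statistical comparison layer: one-way ANOVA, Tukey post hoc q,
two-sample t tests (raw and summary-input) and balanced/unbalanced
two-way ANOVA.

Statistics are computed from classical sums of squares; p-values come
from the corresponding scipy reference distributions (F, t, studentized
range).  The Tukey q keeps its sign — positive q means group A exceeds
group B — because the direction of a mismatch between measured and
model distances carries meaning (apparent shrinkage vs expansion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "TukeyResult",
    "one_way_anova",
    "tukey_hsd",
    "t_two_sample",
    "t_from_summary",
    "two_way_anova",
]

Direction = Literal["two_sided", "greater", "less"]


class InsufficientDataError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    """All variability zero: the test statistic is 0/0."""


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    direction: Direction = "two_sided"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class TukeyResult:
    pair: tuple[str, str]
    q: float
    se: float
    p_value: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "q": self.q, "se": self.se, "p_value": self.p_value}


def _as_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for i, g in enumerate(out):
        if g.size < 2:
            raise InsufficientDataError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return out


def _anova_decomposition(groups: list[np.ndarray]):
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    df_between = k - 1
    df_within = n_total - k
    return means, ns, ss_between, ss_within, df_between, df_within


def one_way_anova(groups: Sequence[np.ndarray], name: str = "one_way_anova") -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with df (k-1, N-k).
    """
    gs = _as_groups(groups)
    _, _, ssb, ssw, dfb, dfw = _anova_decomposition(gs)
    if ssw == 0.0:
        if ssb == 0.0:
            raise UndefinedStatisticError("zero variance between and within groups")
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f_stat, dfb, dfw))
    return TestResult(name=name, statistic=float(f_stat), df=(dfb, dfw), p_value=p)


def tukey_hsd(
    groups: dict[str, np.ndarray],
    se_convention: Literal["tukey_kramer", "sum_of_means"] = "tukey_kramer",
) -> list[TukeyResult]:
    """Signed Tukey post hoc comparisons for every group pair.

    q = (mean_a - mean_b) / SE.  With the default Tukey–Kramer convention
    SE = sqrt(MS_within * (1/n_a + 1/n_b) / 2) and the p-value comes from
    the studentized range distribution with (k, N-k) parameters.  The
    alternative ``sum_of_means`` convention uses the standard error of
    the sum (difference) of the two group means,
    sqrt(s_a²/n_a + s_b²/n_b); it is reported with the same reference
    distribution but is not exactly studentized-range distributed.
    """
    labels = list(groups)
    gs = _as_groups([groups[lab] for lab in labels])
    means, ns, _, ssw, _, dfw = _anova_decomposition(gs)
    ms_within = ssw / dfw
    k = len(gs)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if se_convention == "tukey_kramer":
                se = float(np.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0))
            elif se_convention == "sum_of_means":
                se = float(
                    np.sqrt(gs[i].var(ddof=1) / ns[i] + gs[j].var(ddof=1) / ns[j])
                )
            else:
                raise ValueError(f"unknown se_convention {se_convention!r}")
            if se == 0.0:
                raise UndefinedStatisticError("zero standard error in Tukey comparison")
            q = float((means[i] - means[j]) / se)
            p = float(stats.studentized_range.sf(abs(q), k, dfw))
            out.append(TukeyResult(pair=(labels[i], labels[j]), q=q, se=se, p_value=p))
    return out


def _t_result(
    name: str, t_stat: float, df: float, direction: Direction
) -> TestResult:
    if direction == "two_sided":
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    elif direction == "greater":
        p = float(stats.t.sf(t_stat, df))
    elif direction == "less":
        p = float(stats.t.cdf(t_stat, df))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return TestResult(name=name, statistic=float(t_stat), df=float(df),
                      p_value=min(p, 1.0), direction=direction)


def t_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    direction: Direction = "two_sided",
    equal_var: bool = True,
    name: str = "t_two_sample",
) -> TestResult:
    """Two-sample t test on raw values (pooled variance by default).

    ``direction='greater'`` tests mean(x) > mean(y).  Welch's correction
    is available with ``equal_var=False``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("both samples need at least 2 values")
    return t_from_summary(
        x.mean(), x.std(ddof=1), x.size,
        y.mean(), y.std(ddof=1), y.size,
        direction=direction, equal_var=equal_var, name=name,
    )


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    direction: Direction = "two_sided",
    equal_var: bool = True,
    name: str = "t_from_summary",
) -> TestResult:
    """Two-sample t test from group summaries (mean, SD, n).

    Pooled variance with df = n_a + n_b - 2 by default, matching designs
    where only printed summary statistics are available.
    """
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if equal_var:
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1)) if se > 0 else 1.0
    if se == 0.0:
        if mean_a == mean_b:
            raise UndefinedStatisticError("zero variance and equal means: t undefined")
        t_stat = np.inf if mean_a > mean_b else -np.inf
    else:
        t_stat = (mean_a - mean_b) / se
    return _t_result(name, t_stat, df, direction)


def two_way_anova(
    values: np.ndarray,
    factor_a: Sequence,
    factor_b: Sequence,
    name_a: str = "factor_a",
    name_b: str = "factor_b",
) -> list[TestResult]:
    """Two-way ANOVA main effects (no interaction term).

    Unbalanced designs use sequential (type I) sums of squares with
    ``factor_a`` entered first; the fit is an ordinary least-squares
    regression on factor dummies via statsmodels.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    values = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a, dtype=object)
    fb = np.asarray(factor_b, dtype=object)
    if not (values.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")
    if len(set(fa)) < 2 or len(set(fb)) < 2:
        raise InsufficientDataError("each factor needs at least 2 levels")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells == 0).any().any():
        empty = [
            (str(r), str(c))
            for r in cells.index for c in cells.columns if cells.loc[r, c] == 0
        ]
        raise ValueError(f"empty design cells: {empty}")

    df = pd.DataFrame({"value": values, "a": fa.astype(str), "b": fb.astype(str)})
    fit = smf.ols("value ~ C(a) + C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    df_resid = float(table.loc["Residual", "df"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    out = []
    for term, label in (("C(a)", name_a), ("C(b)", name_b)):
        row = table.loc[term]
        ss_term = float(row["sum_sq"])
        if ss_resid <= 1e-12 * max(ss_term, 1.0):
            # degenerate: an exact fit — F is 0 for a null effect, infinite otherwise
            f_stat = 0.0 if np.isclose(ss_term, 0.0) else float("inf")
            p = 1.0 if f_stat == 0.0 else 0.0
        else:
            f_stat, p = float(row["F"]), float(row["PR(>F)"])
        out.append(
            TestResult(name=label, statistic=f_stat, df=(float(row["df"]), df_resid), p_value=p)
        )
    return out
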