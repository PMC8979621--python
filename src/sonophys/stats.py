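"""Statistical procedures for the subthreshold and spiking analyses.

Three tests cover the study design:

* ordinary least-squares regression with R^2 and the slope F-test p-value
  (dose-response relations such as depolarization vs. I_spta);
* the Kruskal–Wallis rank test with tie correction (non-parametric
  comparison of waveform-feature distributions across stimulus groups);
* two-way factorial ANOVA over the duty-cycle x pressure design, using
  Type II sums of squares since trace counts differ across cells of the
  factorial grid.

No multiple-testing correction is applied anywhere: raw p-values are
reported, and pairwise group comparisons are plain pairwise Kruskal–Wallis
tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .errors import DegenerateDesignError, DomainError, UnbalancedDesignError

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "TwoWayAnovaResult",
    "linear_regression",
    "kruskal_wallis",
    "pairwise_kruskal",
    "two_way_anova",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    dof: int
    group_sizes: tuple[int, ...]
    test_name: str = "kruskal-wallis"


@dataclass(frozen=True)
class TwoWayAnovaResult:
    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_interaction: float
    p_interaction: float
    residual_dof: int


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x.

    R^2 = 1 - SS_res / SS_tot; the p-value is the slope F-test (equivalently
    the two-sided t-test), reported as NaN for n < 3 where it is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d sequences of equal length")
    if x.size < 2:
        raise DomainError("regression needs at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant x: slope is not identifiable")
    if np.ptp(y) == 0:
        # no variance to explain: slope 0, R^2 0 by convention
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue) if x.size >= 3 else math.nan
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=int(x.size),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal–Wallis H test across k groups, with tie correction.

    The p-value uses the chi-square approximation with k - 1 degrees of
    freedom.  If every pooled value is identical the test is degenerate and
    returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise DomainError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("all groups must be non-empty")
    sizes = tuple(int(a.size) for a in arrays)
    dof = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return GroupTestResult(0.0, 1.0, dof, sizes)
    h, p = sps.kruskal(*arrays)
    return GroupTestResult(float(h), float(p), dof, sizes)


def pairwise_kruskal(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
) -> pd.DataFrame:
    """All pairwise Kruskal–Wallis comparisons (uncorrected p-values)."""
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    rows = []
    for (na, ga), (nb, gb) in itertools.combinations(items, 2):
        res = kruskal_wallis([ga, gb])
        rows.append(
            {"group_a": na, "group_b": nb, "H": res.statistic, "p_value": res.p_value}
        )
    return pd.DataFrame(rows)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> TwoWayAnovaResult:
    """Two-way factorial ANOVA with Type II sums of squares.

    Every (a, b) cell must contain at least one observation; the interaction
    term additionally requires at least two observations in some cell with
    replication across the design (cells with a single observation leave no
    within-cell variance, in which case the interaction F is reported as
    NaN from the additive model).
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise DegenerateDesignError("each factor needs at least two levels")
    counts = df.groupby(["a", "b"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty) > 0:
        a0, b0 = empty.index[0]
        raise UnbalancedDesignError(
            f"empty design cell: factor_a={a0!r}, factor_b={b0!r}"
        )
    with_interaction = (counts >= 2).any() and len(df) > df["a"].nunique() * df[
        "b"
    ].nunique()
    formula = "y ~ C(a) * C(b)" if with_interaction else "y ~ C(a) + C(b)"
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def _term(name: str) -> tuple[float, float]:
        if name not in table.index:
            return math.nan, math.nan
        row = table.loc[name]
        return float(row["F"]), float(row["PR(>F)"])

    f_a, p_a = _term("C(a)")
    f_b, p_b = _term("C(b)")
    f_ab, p_ab = _term("C(a):C(b)")
    return TwoWayAnovaResult(
        f_a=f_a,
        p_a=p_a,
        f_b=f_b,
        p_b=p_b,
        f_interaction=f_ab,
        p_interaction=p_ab,
        residual_dof=int(table.loc["Residual", "df"]),
    )
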