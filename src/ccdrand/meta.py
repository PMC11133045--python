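"""Effect-size summaries over simulation-result grids.

Eta-squared (SS_effect / SS_total, against benchmarks .01-.05 small,
.06-.14 medium, .15-1.00 large) quantifies how strongly each simulation
factor drives the rejection-rate estimates; the paired-t r-squared,
``r2 = t**2 / (t**2 + df)``, does the same for paired comparisons such as
with-versus-without reversal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def eta_squared_oneway(grid: pd.DataFrame, factor: str, response: str = "rate") -> float:
    """One-way eta-squared: between-group over total sum of squares.

    A constant response (zero total sum of squares) gives 0 by convention.
    """
    y = grid[response].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        return 0.0
    group_means = grid.groupby(factor, observed=True)[response].transform("mean").to_numpy()
    ss_between = float(np.sum((group_means - y.mean()) ** 2))
    return ss_between / ss_total


def eta_squared_interaction(
    grid: pd.DataFrame, factor_a: str, factor_b: str, response: str = "rate"
) -> float:
    """Eta-squared of the A x B interaction in a two-way ANOVA with main effects.

    The decomposition uses sequential (type I) sums of squares; the grids
    produced here are balanced, where all SS types coincide — unbalanced
    input triggers a warning.  An empty factor combination is an error.
    """
    counts = pd.crosstab(grid[factor_a], grid[factor_b])
    if (counts == 0).any().any():
        a, b = np.argwhere(counts.to_numpy() == 0)[0]
        raise ValueError(
            f"no observations for {factor_a}={counts.index[a]!r}, "
            f"{factor_b}={counts.columns[b]!r}"
        )
    if counts.to_numpy().std() != 0:
        warnings.warn(
            "unbalanced design: type I sums of squares depend on factor order",
            UserWarning,
            stacklevel=2,
        )
    df = grid[[factor_a, factor_b, response]].rename(
        columns={factor_a: "A", factor_b: "B", response: "y"}
    )
    df["A"] = df["A"].astype(str)
    df["B"] = df["B"].astype(str)
    model = smf.ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    with warnings.catch_warnings():
        # saturated designs (one observation per cell) have zero residual df
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=1)
    ss_total = float(table["sum_sq"].sum())
    if ss_total == 0.0:
        return 0.0
    return float(table.loc["C(A):C(B)", "sum_sq"]) / ss_total


def paired_t_r2(x, y) -> tuple[float, float]:
    """Paired-samples t on ``x - y`` and the r-squared ``t**2 / (t**2 + df)``.

    Degenerate cases: zero-variance differences give ``t = 0, r2 = 0`` when
    the mean difference is zero, and ``r2 = 1`` (infinite t, reported as
    ``inf``) when it is not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("at least two pairs are required")
    d = x - y
    if d.std(ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, 0.0
        return float(np.sign(d.mean()) * np.inf), 1.0
    t = float(stats.ttest_rel(x, y).statistic)
    nu = n - 1
    return t, t * t / (t * t + nu)
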