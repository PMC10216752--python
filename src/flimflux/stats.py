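"""Statistics layer for per-pixel / per-cell lifetime tables.

Aggregation to group summaries, Welch's unequal-variance t-test (raw-sample
and summary-statistic forms), two-way ANOVA with Sidak-adjusted pairwise
comparisons, sample-size-normalized KDE curves, and condition-vs-reference
effect tables. Hypothesis tests default to cell-level values because pixels
within a cell are not independent.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_by",
    "welch_ttest",
    "welch_from_summary",
    "two_way_anova",
    "sidak_adjust",
    "kde_normalized",
    "compare_conditions",
]


def aggregate_by(
    table: pd.DataFrame,
    keys: list[str],
    level: str = "cell",
    value: str = "tm_ps",
    cell_key: str = "cell_id",
) -> pd.DataFrame:
    """Group summaries (n, mean, median, sd, sem) of ``value``.

    ``level='cell'`` first averages pixels within each cell so n counts cells;
    ``level='pixel'`` summarizes raw pixels. Empty groups are simply absent.
    """
    if level not in ("pixel", "cell"):
        raise ValueError("level must be 'pixel' or 'cell'")
    missing = [k for k in keys if k not in table.columns]
    if missing:
        raise ValueError(f"unknown group keys: {missing}")
    data = table
    if level == "cell":
        data = (
            table.groupby(keys + [cell_key], observed=True)[value].mean().reset_index()
        )
    g = data.groupby(keys, observed=True)[value]
    out = g.agg(n="count", mean="mean", median="median", sd=lambda v: v.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def welch_ttest(sample_a, sample_b) -> tuple[float, float, float, float]:
    """Welch's two-sample unequal-variance t-test (two-sided).

    Returns (t, df, p, mean_diff) with mean_diff = mean(a) - mean(b) and
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    mean_diff = float(a.mean() - b.mean())
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        # zero variance in both samples
        if mean_diff == 0:
            return 0.0, float(a.size + b.size - 2), 1.0, 0.0
        return float(np.inf) * np.sign(mean_diff), float(a.size + b.size - 2), 0.0, mean_diff
    t = mean_diff / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p), mean_diff


def welch_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's test from group summaries (mean, SEM, n); t = (m2-m1)/sqrt(sem1^2+sem2^2)."""
    if n1 <= 1 or n2 <= 1:
        raise ValueError("n must exceed 1 in both groups")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    s1, s2 = sem1**2, sem2**2
    t = (m2 - m1) / np.sqrt(s1 + s2)
    df = (s1 + s2) ** 2 / (s1**2 / (n1 - 1) + s2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak family-wise adjustment p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str = "tm_ps",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-effects two-way ANOVA (Type II SS) with interaction, plus
    Sidak-adjusted pairwise Welch comparisons.

    Pairwise comparisons run between levels of ``factor_a`` within each level
    of ``factor_b``; the Sidak family is the full set of such comparisons.
    If the design has empty cells the interaction term is dropped with a
    diagnostic.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = table[[factor_a, factor_b, value]].dropna().copy()
    data.columns = ["A", "B", "y"]
    for col in ("A", "B"):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 levels")
    cells = data.groupby(["A", "B"], observed=True).size()
    full_grid = data["A"].nunique() * data["B"].nunique()
    formula = "y ~ C(A) * C(B)"
    dropped = None
    if len(cells) < full_grid:
        formula = "y ~ C(A) + C(B)"
        dropped = "interaction dropped: empty cells make it inestimable"
        warnings.warn(dropped, stacklevel=2)
    model = smf.ols(formula, data=data).fit()
    anova = anova_lm(model, typ=2)
    anova = anova.rename(
        index={"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    )

    pairs = []
    levels_a = sorted(data["A"].unique())
    for b_level, sub in data.groupby("B", observed=True):
        for la, lb in itertools.combinations(levels_a, 2):
            va = sub.loc[sub["A"] == la, "y"].to_numpy()
            vb = sub.loc[sub["A"] == lb, "y"].to_numpy()
            if va.size < 2 or vb.size < 2:
                continue
            t, df, p, diff = welch_ttest(va, vb)
            pairs.append(
                {factor_b: b_level, "level_1": la, "level_2": lb,
                 "mean_diff": diff, "t": t, "df": df, "p": p}
            )
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        pairwise["p_sidak"] = sidak_adjust(pairwise["p"].to_numpy(), len(pairwise))
    anova.attrs["note"] = dropped
    return anova, pairwise


def kde_normalized(
    values,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density that integrates to 1 regardless of sample size.

    Bandwidth defaults to Silverman's rule; an absolute ``bandwidth`` (data
    units) is converted to a kernel factor. Zero-variance input yields a
    flagged narrow spike at the common value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: returning a delta-like spike", stacklevel=2)
        h = max(abs(v[0]), 1.0) * 1e-3
        x = grid if grid is not None else np.linspace(v[0] - 6 * h, v[0] + 6 * h, n_grid)
        dens = np.exp(-0.5 * ((x - v[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
        return x, dens
    bw_method = "silverman" if bandwidth is None else bandwidth / sd
    kde = sps.gaussian_kde(v, bw_method=bw_method)
    h = kde.factor * sd
    if grid is None:
        grid = np.linspace(v.min() - 4 * h, v.max() + 4 * h, n_grid)
    return grid, kde(grid)


def compare_conditions(
    table: pd.DataFrame,
    reference_group,
    group_key: str = "group",
    value: str = "tm_ps",
) -> pd.DataFrame:
    """Per-group mean-lifetime effect vs a reference group.

    ``table`` holds one row per analysis unit (cell-level means by default
    upstream). Output columns: group, n, mean, delta_mean (group - reference),
    t, df, p (Welch), direction — 'higher_tm' means lower relative ATP.
    """
    groups = table[group_key].unique()
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = table.loc[table[group_key] == reference_group, value].to_numpy()
    rows = []
    for g in groups:
        vals = table.loc[table[group_key] == g, value].to_numpy()
        delta = float(vals.mean() - ref.mean())
        if g == reference_group:
            t, df, p = 0.0, float(2 * (ref.size - 1)), 1.0
        else:
            t, df, p, _ = welch_ttest(vals, ref)
        if delta > 0:
            direction = "higher_tm (lower relative ATP)"
        elif delta < 0:
            direction = "lower_tm (higher relative ATP)"
        else:
            direction = "no_change"
        rows.append(
            {group_key: g, "n": vals.size, "mean": float(vals.mean()),
             "delta_mean": delta, "t": t, "df": df, "p": p, "direction": direction}
        )
    return pd.DataFrame(rows)
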