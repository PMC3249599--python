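"""Statistical battery for the variability study.

Two-way ANOVA (type-II sums of squares, additive model) over the AUROC
table, Tukey post-hoc pairs, Kruskal-Wallis for the transfer scenarios,
Pearson correlation between ROI polar position and performance, and the
one-way ANOVA of Cartesian ROI coordinates against performance tertiles.
The primary significance threshold is alpha = 0.01 with a secondary 0.05
reading reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

_EPS = 1e-12


def two_way_anova(
    table: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> dict:
    """Additive two-way ANOVA with type-II sums of squares.

    Returns ``{factor: {"F": ..., "df": ..., "p": ...}}`` for both factors.
    A constant response yields F = 0, p = 1.  Raises if any factor-level
    combination is empty (type-II SS would silently misattribute variance).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[response, factor_a, factor_b]].copy()
    cross = pd.crosstab(df[factor_a], df[factor_b])
    empty = [
        (a, b)
        for a in cross.index
        for b in cross.columns
        if cross.loc[a, b] == 0
    ]
    if empty:
        raise ValueError(f"empty factor cells: {empty}")

    if float(np.var(df[response].to_numpy())) < _EPS:
        out = {}
        for fac, levels in ((factor_a, cross.shape[0]), (factor_b, cross.shape[1])):
            out[fac] = {"F": 0.0, "df": float(levels - 1), "p": 1.0}
        return out

    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) + C(Q('{factor_b}'))", data=df
    ).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out = {}
    for fac in (factor_a, factor_b):
        row = aov.loc[f"C(Q('{fac}'))"]
        f_val = float(row["F"])
        p_val = float(row["PR(>F)"])
        if not np.isfinite(f_val):  # zero residual variance
            f_val, p_val = 0.0, 1.0
        out[fac] = {"F": f_val, "df": float(row["df"]), "p": p_val}
    return out


def tukey_hsd(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized range).

    Returns a frame with columns ``group1, group2, meandiff, p_adj``.
    If all observations are identical every adjusted p is 1.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if float(values.var()) < _EPS:
        rows = [
            {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0}
            for i, a in enumerate(uniq)
            for b in uniq[i + 1 :]
        ]
        return pd.DataFrame(rows)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, groups)
    pairs = [
        (res.groupsunique[i], res.groupsunique[j])
        for i in range(len(res.groupsunique))
        for j in range(i + 1, len(res.groupsunique))
    ]
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    All-identical observations give ``(0.0, 1.0)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate([np.asarray(g, dtype=np.float64) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson_corr_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-test p-value; zero-variance input is an
    error."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if x.var() < _EPS or y.var() < _EPS:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def position_effect_report(
    table: pd.DataFrame,
    alpha: float = 0.01,
    alpha_secondary: float = 0.05,
    exclude_expert: int | None = 5,
) -> dict:
    """ROI-position analysis over per-(expert, iteration) means.

    ``table`` must carry columns ``expert, iteration, auroc, mean_rho,
    mean_theta, mean_ox, mean_oy`` with one row per (expert, iteration).
    Reports Pearson correlations of mean rho / mean theta with AUROC and
    one-way ANOVAs of mean Ox / mean Oy across AUROC tertiles (the fixed
    automatic expert is excluded from the Cartesian analysis because its
    position never varies).  Both significance levels are stated.
    """
    out: dict = {"alpha_levels": [alpha, alpha_secondary]}

    for coord in ("mean_rho", "mean_theta"):
        r, p = pearson_corr_test(table[coord].to_numpy(), table["auroc"].to_numpy())
        out[f"pearson_{coord.removeprefix('mean_')}"] = {
            "r": r,
            "p": p,
            f"significant_at_{alpha}": bool(p < alpha),
            f"significant_at_{alpha_secondary}": bool(p < alpha_secondary),
        }

    cart = table
    if exclude_expert is not None:
        cart = table[table["expert"] != exclude_expert]
    tertile = pd.qcut(cart["auroc"], 3, labels=["low", "mid", "high"], duplicates="drop")
    for coord in ("mean_ox", "mean_oy"):
        groups = [
            cart.loc[tertile == t, coord].to_numpy()
            for t in tertile.cat.categories
            if (tertile == t).sum() > 0
        ]
        if len(groups) < 2:
            f_val, p_val = 0.0, 1.0
        else:
            f_val, p_val = sps.f_oneway(*groups)
            if not np.isfinite(f_val):
                f_val, p_val = 0.0, 1.0
        out[f"anova_{coord.removeprefix('mean_')}"] = {
            "F": float(f_val),
            "p": float(p_val),
            f"significant_at_{alpha}": bool(p_val < alpha),
            f"significant_at_{alpha_secondary}": bool(p_val < alpha_secondary),
        }
    return out
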