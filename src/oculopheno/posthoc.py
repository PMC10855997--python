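"""Nonparametric group comparisons for phenotype post-hocs.

Kruskal-Wallis omnibus tests with eta-squared effect sizes, Dunn's multiple
comparisons on pooled ranks, two-sample rank-sum tests with rank-biserial
effect sizes, pairwise-complete Spearman correlation matrices and profile
prevalence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    statistic: float
    p_value: float
    effect_size: float
    df: int | None = None
    group_sizes: tuple[int, ...] = ()
    note: str = ""


def kruskal_eta_squared(h: float, k: int, n: int) -> float:
    """Eta-squared for a Kruskal-Wallis H: ``(H - k + 1) / (n - k)``,
    clipped at 0."""
    return float(max(0.0, (h - k + 1) / (n - k)))


def kruskal_wallis_eta(*groups) -> StatResult:
    """Tie-corrected Kruskal-Wallis test with eta-squared effect size."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[~np.isnan(g)] for g in clean]
    if any(len(g) == 0 for g in clean):
        raise ValueError("every group must be non-empty")
    k = len(clean)
    n = sum(len(g) for g in clean)
    pooled = np.concatenate(clean)
    if np.all(pooled == pooled[0]):
        return StatResult(0.0, 1.0, 0.0, df=k - 1,
                          group_sizes=tuple(len(g) for g in clean))
    h, p = stats.kruskal(*clean)
    return StatResult(float(h), float(p), kruskal_eta_squared(h, k, n),
                      df=k - 1, group_sizes=tuple(len(g) for g in clean))


def dunn_posthoc(groups: dict | list, adjustment: str = "holm",
                 ) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    Returns one row per pair with the z statistic, raw and adjusted
    p-values.  ``adjustment`` is any method statsmodels supports
    (``holm`` default, ``bonferroni``, or ``none``).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        names = [f"g{j}" for j in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    data = [d[~np.isnan(d)] for d in data]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([len(d) for d in data])
    pooled = np.concatenate(data)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    at = 0
    for m in sizes:
        mean_ranks.append(ranks[at:at + m].mean())
        at += m
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie

    rows = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            rows.append({"group_1": names[i], "group_2": names[j],
                         "z": float(z),
                         "p_raw": float(2 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    if adjustment.lower() in ("none", ""):
        out["p_adj"] = out["p_raw"]
    else:
        out["p_adj"] = multipletests(out["p_raw"], method=adjustment)[1]
    out["p_adj"] = np.maximum(out["p_adj"], out["p_raw"])
    return out


def ranksum_effect(x, y) -> StatResult:
    """Two-sample Wilcoxon rank-sum test with a rank-biserial effect size.

    ``statistic`` is the rank sum W of the first sample; the Mann-Whitney
    U parameterisation is reported in ``note``.  The effect size is the
    rank-biserial correlation ``1 - 2 U / (n1 n2)`` (reported in place of
    a conventional d; it is not Cohen's d).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n1, n2 = len(x), len(y)
    w = u + n1 * (n1 + 1) / 2.0
    effect = 1.0 - 2.0 * u / (n1 * n2)
    return StatResult(statistic=float(w), p_value=float(res.pvalue),
                      effect_size=float(effect), group_sizes=(n1, n2),
                      note=f"U={u}")


def spearman_matrix(data: pd.DataFrame, min_pairs: int = 3,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete tie-corrected Spearman correlations.

    Returns ``(rho, p)`` DataFrames; cells with fewer than ``min_pairs``
    complete pairs are reported absent (NaN).
    """
    cols = data.columns
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = data[[a, b]].dropna()
            if len(pair) < min_pairs:
                continue
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def phenotype_prevalence(assignments) -> pd.Series:
    """Percentage of the sample in each profile, to one decimal place."""
    s = pd.Series(assignments)
    if len(s) == 0:
        raise ValueError("no assignments supplied")
    pct = 100.0 * s.value_counts(sort=False) / len(s)
    return pct.round(1)


def phenotype_comparisons(metrics: pd.DataFrame, assignments,
                          variables: list[str],
                          adjustment: str = "holm") -> pd.DataFrame:
    """Kruskal-Wallis + Dunn post-hocs of clinical variables across
    phenotypes, mirroring the profile-difference analysis layout."""
    assign = pd.Series(assignments, index=metrics.index)
    rows = []
    for var in variables:
        if var not in metrics:
            continue
        groups = {str(g): metrics.loc[assign == g, var].dropna()
                  for g in sorted(assign.unique())}
        groups = {g: v for g, v in groups.items() if len(v) > 0}
        if len(groups) < 2:
            continue
        res = kruskal_wallis_eta(*groups.values())
        rows.append({"variable": var, "H": res.statistic, "df": res.df,
                     "p_value": res.p_value, "eta_squared": res.effect_size})
    return pd.DataFrame(rows)
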