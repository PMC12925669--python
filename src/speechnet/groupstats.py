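"""Descriptive group-comparison statistics.

One-way ANOVA with eta-squared for variables meeting parametric
assumptions, Kruskal-Wallis otherwise (gate: Shapiro-Wilk per group or
Levene across groups failing at alpha = .05), Bonferroni-corrected
pairwise post hoc tests, and Cramer's V for categorical tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpeechNetError

__all__ = ["oneway_anova", "kruskal_wallis", "cramers_v", "choose_test",
           "compare_groups", "GroupStatsResult"]


def _clean_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    out = [g[~np.isnan(g)] for g in out]
    if len(out) < 2:
        raise SpeechNetError("need at least 2 groups")
    return out


def oneway_anova(groups) -> dict:
    """Classical one-way ANOVA with the eta-squared effect size.

    eta^2 = SS_between / SS_total, the proportion of variance explained
    by group membership.
    """
    gs = _clean_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise SpeechNetError("every group needs n >= 2")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    ss_total = ss_between + ss_within
    df_between = len(gs) - 1
    df_within = len(all_vals) - len(gs)
    if ss_within == 0:
        raise SpeechNetError("zero within-group variance; ANOVA undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return {
        "F": float(F),
        "df_between": df_between,
        "df_within": df_within,
        "p": p,
        "eta_squared": float(ss_between / ss_total) if ss_total > 0 else 0.0,
    }


def kruskal_wallis(groups) -> dict:
    """Rank-based Kruskal-Wallis H test with tie correction."""
    gs = _clean_groups(groups)
    n_total = sum(len(g) for g in gs)
    if n_total < 5:
        warnings.warn("total n < 5: chi-squared approximation is poor",
                      stacklevel=2)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; H = 0", stacklevel=2)
        return {"H": 0.0, "df": len(gs) - 1, "p": 1.0}
    H, p = stats.kruskal(*gs)
    return {"H": float(H), "df": len(gs) - 1, "p": float(p)}


def cramers_v(table) -> float:
    """Cramer's V = sqrt(chi2 / (n (min(r, c) - 1))) for an r x c table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0) or tab.sum() == 0:
        raise SpeechNetError("table must be a nonnegative 2-D array with total > 0")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise SpeechNetError("table has an all-zero row or column")
    r, c = tab.shape
    if min(r, c) < 2:
        raise SpeechNetError("table needs at least 2 rows and 2 columns")
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def choose_test(groups, alpha: float = 0.05) -> str:
    """Parametric-assumption gate: Shapiro-Wilk per group OR Levene
    significant at ``alpha`` selects the Kruskal-Wallis path."""
    gs = _clean_groups(groups)
    for g in gs:
        if len(g) >= 3 and len(np.unique(g)) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if stats.shapiro(g).pvalue < alpha:
                    return "kruskal"
    if all(len(g) >= 2 for g in gs):
        if stats.levene(*gs).pvalue < alpha:
            return "kruskal"
    return "anova"


def _posthoc(gs: list[np.ndarray], labels: list[str], parametric: bool) -> dict:
    """Pairwise Bonferroni-adjusted post hoc p-values."""
    pairs = list(itertools.combinations(range(len(gs)), 2))
    raw = []
    for i, j in pairs:
        if parametric:
            p = stats.ttest_ind(gs[i], gs[j], equal_var=True).pvalue
        else:
            p = stats.mannwhitneyu(gs[i], gs[j], alternative="two-sided").pvalue
        raw.append(float(p))
    adj = np.minimum(1.0, np.array(raw) * len(pairs))
    return {f"{labels[i]}:{labels[j]}": float(a)
            for (i, j), a in zip(pairs, adj)}


@dataclass
class GroupStatsResult:
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_groups(
    df: pd.DataFrame,
    variables: list[str],
    group_col: str,
    alpha: float = 0.05,
    force_test: dict[str, str] | None = None,
) -> GroupStatsResult:
    """Tables-style group comparison over a set of numeric variables.

    Per variable: group means (SD), the chosen test (ANOVA or
    Kruskal-Wallis via :func:`choose_test`, overridable per variable with
    ``force_test``), its statistic, p-value, effect size, and
    Bonferroni-adjusted post hoc contrasts significant at ``alpha``.
    """
    force_test = force_test or {}
    labels = sorted(df[group_col].dropna().unique())
    rows = []
    for var in variables:
        gs = [df.loc[df[group_col] == lab, var].dropna().to_numpy(dtype=float)
              for lab in labels]
        test = force_test.get(var) or choose_test(gs, alpha=alpha)
        if test == "anova":
            res = oneway_anova(gs)
            stat_name, stat = "F", res["F"]
            p, effect = res["p"], res["eta_squared"]
        else:
            res = kruskal_wallis(gs)
            stat_name, stat = "H", res["H"]
            p, effect = res["p"], np.nan
        post = _posthoc(gs, labels, parametric=(test == "anova"))
        sig = [k for k, v in post.items() if v < alpha]
        row = {"variable": var, "test": test, "statistic_name": stat_name,
               "statistic": stat, "p": p, "eta_squared": effect,
               "significant_posthoc": ";".join(sig)}
        for lab, g in zip(labels, gs):
            row[f"mean_{lab}"] = float(np.mean(g)) if len(g) else np.nan
            row[f"sd_{lab}"] = float(np.std(g, ddof=1)) if len(g) > 1 else np.nan
        rows.append(row)
    return GroupStatsResult(pd.DataFrame(rows))
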