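"""Comparison outputs: accuracy-vs-size tables, confusion matrices, the
method-effect ANOVA and the pairwise-FST vs mismatch-delta analysis."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .assign import accuracy_summary, self_assign
from .matrix import GenotypeMatrix
from .panels import Panel, SplitSpec


def accuracy_curve(panels: list[Panel], m: GenotypeMatrix,
                   split: SplitSpec) -> pd.DataFrame:
    """One row per panel: method, parameter, size, overall holdout accuracy
    (%) and per-population accuracy columns; sorted by method then size."""
    rows = []
    for panel in panels:
        res = self_assign(m, panel, split)
        overall, per_pop = accuracy_summary(res, holdout_only=True)
        row = {"method": panel.method, "parameter": panel.parameter,
               "size": panel.size, "overall": overall}
        row.update({f"acc_{p}": v for p, v in per_pop.items()})
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["method", "size"], kind="stable").reset_index(drop=True)


def confusion_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """True population (rows) x assigned population (columns), as the percent
    of each true population's holdout individuals; rows sum to 100."""
    r = results[results["holdout"]]
    if not len(r):
        raise ValueError("no holdout individuals")
    pops = sorted(set(r["true_pop"]) | set(r["assigned_pop"]))
    counts = pd.crosstab(r["true_pop"], r["assigned_pop"]).reindex(
        index=pops, columns=pops, fill_value=0
    )
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = counts.div(totals, axis=0) * 100.0
    return pct


def method_effect_test(table: pd.DataFrame):
    """Nested-model F-test for a selection-method effect on accuracy.

    Fits overall accuracy on (size, size²) with and without method
    indicators via ordinary least squares and compares the nested models.
    Returns ``(F, df_num, df_den, p_value)``.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    if table["method"].nunique() < 2:
        raise ValueError("need at least 2 methods")
    if (table.groupby("method")["size"].count() < 3).any():
        raise ValueError("need at least 3 panel sizes per method")
    df = table[["method", "size", "overall"]].copy()
    df["size2"] = df["size"].astype(float) ** 2
    reduced = ols("overall ~ size + size2", data=df).fit()
    full = ols("overall ~ size + size2 + C(method)", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    cmp = anova_lm(reduced, full)
    F = float(cmp["F"].iloc[1])
    df_num = int(cmp["df_diff"].iloc[1])
    df_den = int(full.df_resid)
    p = float(cmp["Pr(>F)"].iloc[1])
    if not np.isfinite(F) or F < 0:  # identical fits up to float noise
        F, p = 0.0, 1.0
    return F, df_num, df_den, p


def _pair_mismatch(results: pd.DataFrame, a: str, b: str) -> float:
    """Proportion of holdout individuals cross-assigned between pops a and b."""
    r = results[results["holdout"]]
    in_pair = r[r["true_pop"].isin([a, b])]
    if not len(in_pair):
        return np.nan
    cross = ((in_pair["true_pop"] == a) & (in_pair["assigned_pop"] == b)) | (
        (in_pair["true_pop"] == b) & (in_pair["assigned_pop"] == a)
    )
    return float(cross.sum() / len(in_pair))


def mismatch_delta(results_a: pd.DataFrame, results_b: pd.DataFrame,
                   pairwise: pd.DataFrame) -> pd.DataFrame:
    """Per population pair: pairwise θ and the difference in cross-assignment
    proportion, method B minus method A (both on the same split)."""
    if set(results_a["individual"]) != set(results_b["individual"]):
        raise ValueError("the two result sets cover different individuals")
    pops = list(pairwise.index)
    rows = []
    for a, b in itertools.combinations(pops, 2):
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "pairwise_theta": float(pairwise.loc[a, b]),
                "delta": _pair_mismatch(results_b, a, b)
                - _pair_mismatch(results_a, a, b),
            }
        )
    return pd.DataFrame(rows)


def min_panel_for_threshold(table: pd.DataFrame, threshold: float):
    """Smallest panel size reaching the accuracy threshold.

    Returns ``(per_method, best)``: a dict method -> size (or None if the
    method never reaches it) and the overall ``(method, size)`` winner (or
    None).
    """
    if not len(table):
        raise ValueError("empty evaluation table")
    per_method = {}
    best = None
    for method, grp in table.groupby("method"):
        ok = grp[grp["overall"] >= threshold]
        per_method[method] = None if ok.empty else int(ok["size"].min())
        if not ok.empty:
            cand = (method, int(ok["size"].min()))
            if best is None or cand[1] < best[1]:
                best = cand
    return per_method, best
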