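"""Cluster-wise comparisons of scores, expression, and subtype composition.

Pairwise cluster differences in enrichment scores or per-gene expression use
Welch's unequal-variance t test with Benjamini-Hochberg adjustment across
the analysis table; subtype composition across clusters is assessed with a
chi-squared test against the background frequency, flagging tables whose
expected counts violate the usual > 5 rule of thumb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .subpopulations import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "welch_test",
    "bh_adjust",
    "enrichment_chi2",
    "compare_all",
]


@dataclass
class GroupComparison:
    """One Welch comparison between two groups of values."""

    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_adj: float | None = None


def welch_test(
    a: np.ndarray,
    b: np.ndarray,
    names: tuple[str, str] = ("a", "b"),
    ci_level: float = 0.95,
) -> GroupComparison:
    """Welch's unequal-variance t test with a CI for the mean difference.

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate comparison: both groups have zero variance")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    diff = float(a.mean() - b.mean())
    half = crit * np.sqrt(se2)
    return GroupComparison(
        group_a=names[0], group_b=names[1], t=float(t), df=float(df), p=float(p),
        mean_diff=diff, ci_low=diff - half, ci_high=diff + half,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_chi2(
    cluster_labels: Sequence, category_labels: Sequence
) -> dict:
    """Chi-squared test of category composition across clusters.

    The null model gives every cluster the background category frequencies:
    expected(c, s) = n_c * n_s / N.  No continuity correction is applied.
    Empty clusters are excluded with a warning; ``low_counts`` flags any
    expected cell below 5 (where the chi-squared approximation is doubtful).
    """
    table = pd.crosstab(pd.Series(cluster_labels, name="cluster"),
                        pd.Series(category_labels, name="category"))
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        logger.warning("excluding empty clusters: %s", list(empty))
        table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("need >= 2 non-empty clusters")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return {
        "chi2": float(chi2),
        "dof": int(dof),
        "p": float(p),
        "observed": table,
        "expected": expected,
        "low_counts": bool((expected.to_numpy() < 5).any()),
    }


def compare_all(
    values: pd.DataFrame,
    assignment: ClusterAssignment | Sequence,
    pairs: Iterable[tuple[str, str]] | None = None,
    use_semantic: bool = True,
) -> pd.DataFrame:
    """Welch-compare every variable between cluster pairs, BH-adjusted.

    ``values`` is samples x variables (scores or normalized expression),
    aligned with the assignment.  ``pairs`` defaults to all unordered label
    pairs.  BH adjustment is applied across the whole emitted table (one
    analysis = one correction family).  Failed comparisons (e.g. degenerate
    variance) are recorded as NaN rows, not fatal.
    """
    if isinstance(assignment, ClusterAssignment):
        labels = (
            assignment.semantic_labels()
            if use_semantic and assignment.semantic is not None
            else assignment.labels.astype(str)
        )
    else:
        labels = np.asarray(assignment).astype(str)
    if len(labels) != len(values):
        raise ValueError("assignment does not cover the samples")
    uniq = sorted(pd.unique(labels))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    rows = []
    for var in values.columns:
        col = values[var].to_numpy(dtype=float)
        for g1, g2 in pairs:
            try:
                cmp_ = welch_test(col[labels == g1], col[labels == g2], names=(g1, g2))
                rows.append(
                    {
                        "variable": var, "group1": g1, "group2": g2,
                        "t": cmp_.t, "df": cmp_.df, "p": cmp_.p,
                        "ci_low": cmp_.ci_low, "ci_high": cmp_.ci_high,
                    }
                )
            except ValueError as err:
                logger.warning("comparison %s %s vs %s failed: %s", var, g1, g2, err)
                rows.append(
                    {
                        "variable": var, "group1": g1, "group2": g2,
                        "t": np.nan, "df": np.nan, "p": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan,
                    }
                )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
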