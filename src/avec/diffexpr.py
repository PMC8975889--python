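"""Differential expression and supporting statistics.

Two-sample Wilcoxon rank-sum testing on normalized expression with the
study's filters (minimum expressing fraction, linear fold-change,
Benjamini–Hochberg adjusted P), pattern-gene categorization along the
arterial developmental axis, Fisher's combined probability, and the
moving-average smoother used for trajectory heatmaps.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset, ValidationError

__all__ = [
    "rank_test_table",
    "wilcoxon_deg",
    "bh_adjust",
    "pattern_genes",
    "fisher_combine",
    "smooth_over_cells",
]

_EPS = 1e-9

DEG_COLUMNS = [
    "gene",
    "log_fc",
    "fold_change",
    "p",
    "p_adj",
    "pct_1",
    "pct_2",
    "direction",
]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1, returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def rank_test_table(
    dataset: ExpressionDataset,
    group1: Sequence[str],
    group2: Sequence[str],
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon rank-sum statistics for every gene passing the expression filter.

    A gene is tested when the fraction of cells with nonzero normalized
    expression reaches ``min_pct`` in either group.  P-values use the normal
    approximation with tie correction (two-sided); fold change is the ratio
    of group means on the linear (expm1 of normalized) scale with a small
    pseudo-count, and ``log_fc`` the difference of mean normalized values.
    """
    g1 = list(group1)
    g2 = list(group2)
    if not g1 or not g2:
        raise ValidationError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValidationError("groups overlap")
    norm = dataset.require_norm()
    x = norm[:, dataset.cell_index(g1)]
    y = norm[:, dataset.cell_index(g2)]
    pct1 = (x > 0).mean(axis=1)
    pct2 = (y > 0).mean(axis=1)
    tested = np.flatnonzero((pct1 >= min_pct) | (pct2 >= min_pct))
    if tested.size == 0:
        return pd.DataFrame(columns=DEG_COLUMNS[:-1] + ["direction"]).astype(
            {"p": float}
        )
    res = stats.mannwhitneyu(
        x[tested], y[tested], axis=1, alternative="two-sided", method="asymptotic"
    )
    mean1 = np.expm1(x[tested]).mean(axis=1)
    mean2 = np.expm1(y[tested]).mean(axis=1)
    fc = (mean1 + _EPS) / (mean2 + _EPS)
    log_fc = x[tested].mean(axis=1) - y[tested].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": [dataset.genes[i] for i in tested],
            "log_fc": log_fc,
            "fold_change": fc,
            "p": res.pvalue,
            "pct_1": pct1[tested],
            "pct_2": pct2[tested],
            "direction": np.where(fc >= 1.0, "up", "down"),
        }
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table[DEG_COLUMNS]


def wilcoxon_deg(
    dataset: ExpressionDataset,
    group1: Sequence[str],
    group2: Sequence[str],
    min_pct: float = 0.25,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed genes between two cell groups.

    Returns the rows of :func:`rank_test_table` whose linear fold change (in
    either direction) reaches ``fc_min`` and whose BH-adjusted p-value is at
    most ``alpha``, one record per retained gene.
    """
    table = rank_test_table(dataset, group1, group2, min_pct=min_pct)
    if table.empty:
        return table
    effect = np.maximum(table["fold_change"], 1.0 / table["fold_change"])
    keep = (effect >= fc_min) & (table["p_adj"] <= alpha)
    return table.loc[keep].reset_index(drop=True)


def pattern_genes(
    dataset: ExpressionDataset,
    ep1_cells: Sequence[str],
    ep2_cells: Sequence[str],
    ep3_cells: Sequence[str],
    fc_min: float = 1.5,
    ep6_cells: Sequence[str] | None = None,
    ep7_cells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Categorize genes along the major-artery developmental axis.

    Genes up-regulated in the early-artery stage (EP2) versus the early
    plexus (EP1) are arterial *segregation* genes; genes up-regulated in the
    maturing artery (EP3) versus EP2 are arterial *strengthening* genes.  A
    gene passing both contrasts is assigned to segregation (the earlier
    event) and flagged.  When EP6/EP7 cell sets are supplied, the raw
    Wilcoxon p-value of that venous-vs-arterial-plexus contrast is attached
    for downstream ordering.
    """
    for name, cells in (("EP1", ep1_cells), ("EP2", ep2_cells), ("EP3", ep3_cells)):
        if not len(cells):
            raise ValidationError(f"no cells supplied for {name}")
    seg = wilcoxon_deg(dataset, ep2_cells, ep1_cells, fc_min=fc_min)
    seg_up = set(seg.loc[seg["direction"] == "up", "gene"])
    stren = wilcoxon_deg(dataset, ep3_cells, ep2_cells, fc_min=fc_min)
    stren_up = set(stren.loc[stren["direction"] == "up", "gene"])

    genes = sorted(seg_up | stren_up)
    category = [
        "arterial_segregation" if g in seg_up else "arterial_strengthening"
        for g in genes
    ]
    both = [g in seg_up and g in stren_up for g in genes]

    p67 = pd.Series(np.nan, index=genes)
    if ep6_cells is not None and ep7_cells is not None and genes:
        contrast = rank_test_table(dataset, list(ep6_cells), list(ep7_cells), min_pct=0.0)
        p67.update(contrast.set_index("gene")["p"])

    return pd.DataFrame(
        {
            "gene": genes,
            "category": category,
            "in_both": both,
            "p_ep6_vs_ep7": p67.to_numpy(),
        }
    )


def fisher_combine(pvals: Sequence[float]) -> float:
    """Fisher's combined probability of independent p-values.

    ``X = -2 * sum(ln p_i)`` is referred to a chi-square with ``2k`` degrees
    of freedom.  Zero p-values are clamped to the smallest positive float
    with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_combine needs at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p=0 clamped to the smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def smooth_over_cells(
    values: Sequence[float], order: Sequence[int], window: int = 20
) -> np.ndarray:
    """Centered moving average along a cell ordering, truncated at the ends.

    ``order`` is a permutation of cell indices (e.g. an argsort of
    pseudo-order positions); the returned array is aligned to the original
    indexing.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(len(values))):
        raise ValidationError("order must be a permutation of cell indices")
    ordered = pd.Series(values[order])
    smoothed = ordered.rolling(window, center=True, min_periods=1).mean().to_numpy()
    out = np.empty_like(smoothed)
    out[order] = smoothed
    return out
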