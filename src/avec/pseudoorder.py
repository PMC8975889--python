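"""Principal-curve pseudo-ordering in a modified PCA space.

Cells on a developmental continuum are ordered by (i) computing modified
principal-component scores in which each of the top two components is
restricted to its ``n_top`` largest-|loading| genes — suppressing the long
tail of small technical loadings — and (ii) fitting a principal curve to the
resulting 2-D cloud.  A principal curve is a smooth 1-D curve through the
middle of the points, fitted by alternating projection (each point is
assigned the arc-length position ``lambda`` of its nearest point on the
curve) and smoothing (each coordinate is re-fit against ``lambda`` with a
cubic smoothing spline whose penalty is chosen by generalized
cross-validation).  The pseudo-order of the cells is the ranking of their
``lambda`` values; its direction is fixed by an explicit anchor group (for
example the earliest sampling stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .dataset import ExpressionDataset, ValidationError
from .diffexpr import smooth_over_cells

__all__ = [
    "PseudoOrderResult",
    "modified_pc_scores",
    "fit_principal_curve",
    "orient_pseudoorder",
    "pattern_dynamics",
]

_CATEGORY_ORDER = ["arterial_segregation", "arterial_strengthening", "other"]


@dataclass
class PseudoOrderResult:
    """Arc-length positions, projections and the fitted polyline."""

    lambda_: np.ndarray
    projection: np.ndarray
    curve: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    orientation_anchor: str | None = None

    def order(self) -> np.ndarray:
        """Permutation of cell indices sorted by ``lambda``."""
        return np.argsort(self.lambda_, kind="stable")


def modified_pc_scores(
    dataset: ExpressionDataset,
    cells: list[str] | None = None,
    n_top: int = 60,
    weighted: bool = True,
) -> pd.DataFrame:
    """Top-two PCA scores recomputed from the ``n_top`` largest-|loading| genes.

    Standard PCA is run on centered normalized expression; per component,
    loadings outside the ``n_top`` largest in absolute value are zeroed and
    the score recomputed, so with ``n_top >= n_genes`` the result equals the
    standard PC scores.  With ``weighted=False`` the retained loadings are
    replaced by their signs (an unweighted signed sum of gene values).
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    cells = cells if cells is not None else list(dataset.cells)
    if len(cells) < 3:
        raise ValidationError("need at least 3 cells")
    if dataset.n_genes < 2:
        raise ValidationError("need at least 2 genes")
    norm = dataset.require_norm()
    x = norm[:, dataset.cell_index(cells)].T  # cells × genes
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    scores = {}
    for comp in range(2):
        loading = vt[comp].copy()
        # deterministic sign: largest-|loading| gene is positive
        if loading[np.argmax(np.abs(loading))] < 0:
            loading = -loading
        keep = np.argsort(np.abs(loading), kind="stable")[::-1][:n_top]
        masked = np.zeros_like(loading)
        masked[keep] = loading[keep] if weighted else np.sign(loading[keep])
        scores[f"pc{comp + 1}_mod"] = xc @ masked
    return pd.DataFrame(scores, index=pd.Index(cells, name="cell"))


def _project_to_polyline(
    points: np.ndarray, curve: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project points to a polyline; return arc-length positions, projections
    and the mean squared projection distance."""
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len2 = np.maximum((seg_vec**2).sum(axis=1), 1e-300)
    cum = np.concatenate([[0.0], np.sqrt((seg_vec**2).sum(axis=1)).cumsum()])
    diff = points[:, None, :] - seg_start[None, :, :]  # n × m × 2
    t = np.clip((diff * seg_vec[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = seg_start[None, :, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    lam = cum[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return lam, proj[rows, best], float(d2[rows, best].mean())


def _smooth_coordinates(lam: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Fit each coordinate against lambda (duplicates averaged) and return
    the smoothed polyline evaluated at the sorted unique lambdas."""
    frame = pd.DataFrame({"lam": lam, "x": points[:, 0], "y": points[:, 1]})
    grouped = frame.groupby("lam", sort=True).mean()
    grid = grouped.index.to_numpy()
    if grid.size < 5:
        # too few distinct positions for a spline: least-squares line
        coeff_x = np.polyfit(lam, points[:, 0], 1)
        coeff_y = np.polyfit(lam, points[:, 1], 1)
        return np.column_stack([np.polyval(coeff_x, grid), np.polyval(coeff_y, grid)])
    sx = make_smoothing_spline(grid, grouped["x"].to_numpy())
    sy = make_smoothing_spline(grid, grouped["y"].to_numpy())
    return np.column_stack([sx(grid), sy(grid)])


def fit_principal_curve(
    points: np.ndarray, max_iter: int = 50, tol: float = 1e-4
) -> PseudoOrderResult:
    """Fit a principal curve to 2-D points and return arc-length positions.

    Initialized on the first principal axis, the fit alternates projection
    onto the current polyline with GCV-spline smoothing of each coordinate
    against arc length, and stops when the mean squared projection distance
    changes by less than ``tol`` (or would increase, in which case the
    previous state is kept), so the recorded objective is non-increasing.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    if len(points) < 5:
        raise ValidationError("need at least 5 points")
    if np.allclose(points, points[0]):
        raise ValidationError("all points identical; no curve is defined")

    center = points.mean(axis=0)
    xc = points - center
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    axis = vt[0]
    lam0 = xc @ axis
    order = np.argsort(lam0, kind="stable")
    curve = center + np.outer(lam0[order], axis)
    lam, proj, obj = _project_to_polyline(points, curve)
    history = [obj]

    best = (lam, proj, curve)
    for _ in range(max_iter):
        new_curve = _smooth_coordinates(lam, points)
        new_lam, new_proj, new_obj = _project_to_polyline(points, new_curve)
        if new_obj > history[-1]:
            break
        improved = history[-1] - new_obj
        history.append(new_obj)
        best = (new_lam, new_proj, new_curve)
        lam = new_lam
        if improved < tol:
            break
    lam, proj, curve = best
    return PseudoOrderResult(
        lambda_=lam, projection=proj, curve=curve, objective_history=history
    )


def orient_pseudoorder(
    result: PseudoOrderResult,
    anchor_mask: np.ndarray,
    anchor_name: str | None = None,
) -> PseudoOrderResult:
    """Fix the direction of a pseudo-order so an anchor group sits at low lambda.

    ``anchor_mask`` is a boolean array over cells (e.g. the earliest sampling
    stage); lambda is negated when the anchor's mean lambda exceeds that of
    the remaining cells.  Idempotent.
    """
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    if anchor_mask.shape != result.lambda_.shape:
        raise ValidationError("anchor mask length differs from cell count")
    if not anchor_mask.any():
        raise ValidationError("anchor covers no cell")
    lam = result.lambda_
    others = ~anchor_mask
    flip = others.any() and lam[anchor_mask].mean() > lam[others].mean()
    return PseudoOrderResult(
        lambda_=-lam if flip else lam.copy(),
        projection=result.projection.copy(),
        curve=result.curve[::-1].copy() if flip else result.curve.copy(),
        objective_history=list(result.objective_history),
        orientation_anchor=anchor_name,
    )


def pattern_dynamics(
    dataset: ExpressionDataset,
    lambda_: pd.Series,
    pattern_table: pd.DataFrame,
    window: int = 20,
) -> pd.DataFrame:
    """Smoothed expression of pattern genes, ordered for heatmap display.

    Rows are pattern genes sorted by category (segregation before
    strengthening) then ascending EP6-vs-EP7 p-value; columns are cells
    sorted by ``lambda_``; values are normalized expression smoothed over
    ``window`` adjacent cells along the pseudo-order.  Genes absent from the
    dataset are dropped with a warning.
    """
    present = pattern_table["gene"].isin(set(dataset.genes))
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} pattern gene(s) absent from dataset; dropped",
            stacklevel=2,
        )
    table = pattern_table.loc[present].copy()
    table["category"] = pd.Categorical(
        table["category"], categories=_CATEGORY_ORDER, ordered=True
    )
    table = table.sort_values(
        ["category", "p_ep6_vs_ep7"], kind="stable", na_position="last"
    )
    cells = list(lambda_.index)
    cell_order = np.argsort(lambda_.to_numpy(), kind="stable")
    norm = dataset.require_norm()
    cols = dataset.cell_index(cells)
    # smooth along pseudo-order, then emit columns in pseudo-order
    ordered_cells = [cells[i] for i in cell_order]
    data = np.empty((len(table), len(cells)))
    for i, gene in enumerate(table["gene"]):
        values = norm[dataset.gene_index([gene])[0], cols]
        smoothed = smooth_over_cells(values, cell_order, window)
        data[i] = smoothed[cell_order]
    return pd.DataFrame(data, index=pd.Index(table["gene"], name="gene"), columns=ordered_cells)
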