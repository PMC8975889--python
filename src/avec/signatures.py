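"""Gene-signature scoring: arteriovenous feature scores and cell-cycle phases.

The arteriovenous (AV) score summarizes a cell's arterial and venous marker
programs on a common 0–10 scale.  Per gene, normalized expression is min–max
scaled to 0–10 across all cells; per cell, scaled values are averaged within
the arterial and the venous signature; the two averages are each rescaled to
0–10 across cells.  A cell is called arterial (venous) when its arterial
(venous) score strictly exceeds a threshold tau (default 5) while the other
score does not.  Because every step is a per-gene monotone rescaling followed
by averaging and a global rescaling, identity calls are invariant to
strictly increasing per-gene affine transforms of the expression values —
in particular to the base of the logarithm used in normalization.

Cell-cycle phase scores follow the binned-control module-score construction:
the mean expression of a phase gene set minus the mean of an
expression-matched control pool, with phases assigned as G1 when both scores
are non-positive and otherwise by the larger score.

Default signatures ship with the package: 13 arterial and 3 venous
endothelial markers, and the core 43 G1/S + 54 G2/M cell-cycle sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset, ValidationError

__all__ = [
    "SignatureSet",
    "ClusterEllipse",
    "default_signatures",
    "load_signature",
    "scale_gene_0_10",
    "av_scores",
    "classify_av",
    "cluster_summary",
    "cluster_ellipse",
    "cell_cycle_scores",
]

DEFAULT_TAU = 5.0


def load_signature(name: str) -> list[str]:
    """Load a bundled signature file (``arterial``, ``venous``, ``g1s``, ``g2m``)."""
    text = resources.files("avec.data").joinpath(f"{name}.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class SignatureSet:
    """Named marker-gene lists used by the scoring functions."""

    arterial: list[str]
    venous: list[str]
    g1s: list[str] = field(default_factory=list)
    g2m: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.arterial) & set(self.venous):
            raise ValidationError("arterial and venous signatures overlap")


def default_signatures() -> SignatureSet:
    return SignatureSet(
        arterial=load_signature("arterial"),
        venous=load_signature("venous"),
        g1s=load_signature("g1s"),
        g2m=load_signature("g2m"),
    )


def scale_gene_0_10(values: np.ndarray) -> np.ndarray:
    """Min–max scale a per-cell vector to [0, 10]; a constant vector maps to 0."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite values in scale_gene_0_10")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo) * 10.0


def _present_genes(dataset: ExpressionDataset, symbols: list[str], side: str) -> list[str]:
    present = [s for s in symbols if s in set(dataset.genes)]
    missing = len(symbols) - len(present)
    if not present:
        raise ValidationError(f"no {side} signature gene found in dataset")
    if missing:
        warnings.warn(
            f"{missing} {side} signature gene(s) absent from dataset; "
            f"scoring uses {len(present)}",
            stacklevel=3,
        )
    return present


def av_scores(dataset: ExpressionDataset, signatures: SignatureSet | None = None) -> pd.DataFrame:
    """Per-cell arterial (``S_a``) and venous (``S_v``) scores on the 0–10 scale.

    Missing signature symbols are dropped with a warning; a side with no
    genes present raises.  Requires at least two cells (min–max scaling is
    undefined on one).
    """
    signatures = signatures or default_signatures()
    if dataset.n_cells < 2:
        raise ValidationError("av_scores needs at least 2 cells")
    norm = dataset.require_norm()

    def side_score(symbols: list[str], side: str) -> np.ndarray:
        genes = _present_genes(dataset, symbols, side)
        rows = dataset.gene_index(genes)
        scaled = np.stack([scale_gene_0_10(norm[r]) for r in rows])
        return scale_gene_0_10(scaled.mean(axis=0))

    return pd.DataFrame(
        {
            "S_a": side_score(signatures.arterial, "arterial"),
            "S_v": side_score(signatures.venous, "venous"),
        },
        index=pd.Index(dataset.cells, name="cell"),
    )


def classify_av(table: pd.DataFrame, tau: float = DEFAULT_TAU) -> pd.Series:
    """Call per-cell identity from AV scores with a strict threshold.

    arterial iff S_a > tau and S_v <= tau; venous iff S_v > tau and S_a <= tau;
    double iff both exceed tau; otherwise neither.  Ties at tau are neither.
    """
    sa = table["S_a"].to_numpy()
    sv = table["S_v"].to_numpy()
    identity = np.full(len(table), "neither", dtype=object)
    identity[(sa > tau) & (sv <= tau)] = "arterial"
    identity[(sv > tau) & (sa <= tau)] = "venous"
    identity[(sa > tau) & (sv > tau)] = "double"
    return pd.Series(identity, index=table.index, name="identity")


def cluster_summary(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean arterial and venous scores."""
    labels = labels.reindex(table.index)
    return table.groupby(labels).mean().rename(columns={"S_a": "mean_S_a", "S_v": "mean_S_v"})


@dataclass
class ClusterEllipse:
    """Coverage ellipse of a cluster's (S_a, S_v) cloud.

    The ellipse is ``{x : (x-center)' Sigma^-1 (x-center) <= q}`` with ``q``
    the chi-square(2 df) quantile at the coverage level; radii are the
    semi-axes ``sqrt(eigval * q)`` and ``angle`` the orientation of the major
    axis in radians.
    """

    cluster: str
    center: np.ndarray
    cov: np.ndarray
    coverage: float
    q: float
    radii: np.ndarray | None
    angle: float | None
    degenerate: bool

    def contains(self, points: np.ndarray) -> np.ndarray:
        if self.degenerate:
            raise ValidationError(f"degenerate ellipse for cluster {self.cluster!r}")
        diff = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.cov)
        return np.einsum("ij,jk,ik->i", diff, inv, diff) <= self.q


def cluster_ellipse(
    table: pd.DataFrame, labels: pd.Series, coverage: float = 0.5
) -> dict[str, ClusterEllipse]:
    """Per-cluster mean, covariance and coverage ellipse of the AV scores.

    Clusters with fewer than 3 cells or a singular covariance are flagged
    degenerate rather than raising.
    """
    if not 0 < coverage < 1:
        raise ValidationError("coverage must be in (0, 1)")
    q = stats.chi2.ppf(coverage, df=2)
    labels = labels.reindex(table.index)
    out: dict[str, ClusterEllipse] = {}
    for cluster, sub in table.groupby(labels):
        pts = sub[["S_a", "S_v"]].to_numpy()
        center = pts.mean(axis=0)
        if len(pts) < 3:
            out[str(cluster)] = ClusterEllipse(
                str(cluster), center, np.full((2, 2), np.nan), coverage, q, None, None, True
            )
            continue
        cov = np.cov(pts, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        degenerate = bool(eigval.min() <= 1e-12 * max(eigval.max(), 1.0))
        if degenerate:
            radii, angle = None, None
        else:
            order = np.argsort(eigval)[::-1]
            eigval, eigvec = eigval[order], eigvec[:, order]
            radii = np.sqrt(eigval * q)
            angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
        out[str(cluster)] = ClusterEllipse(
            str(cluster), center, cov, coverage, q, radii, angle, degenerate
        )
    return out


def cell_cycle_scores(
    dataset: ExpressionDataset,
    signatures: SignatureSet | None = None,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-cycle phase scores and assignments.

    Per phase set, the score is the mean normalized expression of the set
    minus the mean of an expression-matched control pool: genes are ranked by
    mean expression and cut into ``n_bins`` equal-size bins, and ``ctrl_size``
    control genes are sampled (seeded) from the bin of each signature gene.
    Phase is G1 when both scores are <= 0, otherwise the phase of the larger
    score (S for the G1/S set, G2M for the G2/M set).
    """
    signatures = signatures or default_signatures()
    norm = dataset.require_norm()
    gene_means = norm.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(dataset.n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(dataset.n_genes) * n_bins) // max(dataset.n_genes, 1), n_bins - 1
    )
    bins: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)
    }
    rng = np.random.default_rng(seed)

    def module_score(symbols: list[str], side: str) -> np.ndarray:
        genes = _present_genes(dataset, symbols, side)
        rows = dataset.gene_index(genes)
        row_set = set(rows.tolist())
        ctrl_rows: list[np.ndarray] = []
        for r in rows:
            # expression-matched controls from the gene's bin, excluding the
            # signature itself (degenerate otherwise in small gene spaces)
            pool = np.array([i for i in bins[bin_of[r]] if i not in row_set])
            if pool.size == 0:
                pool = np.array(
                    [i for i in range(dataset.n_genes) if i not in row_set]
                )
            take = min(ctrl_size, pool.size)
            ctrl_rows.append(rng.choice(pool, size=take, replace=False))
        ctrl = np.unique(np.concatenate(ctrl_rows))
        return norm[rows].mean(axis=0) - norm[ctrl].mean(axis=0)

    g1s = module_score(signatures.g1s, "G1/S")
    g2m = module_score(signatures.g2m, "G2/M")
    phase = np.where(
        (g1s <= 0) & (g2m <= 0), "G1", np.where(g1s > g2m, "S", "G2M")
    )
    return pd.DataFrame(
        {"g1s_score": g1s, "g2m_score": g2m, "phase": phase},
        index=pd.Index(dataset.cells, name="cell"),
    )
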