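"""Expression container, IO, UMI normalization and quality-control filters.

The central object is :class:`ExpressionDataset`, a gene × cell UMI count
matrix with an optional normalized layer and per-cell / per-gene metadata
tables.  Counts are unique-molecular-identifier (UMI) transcript counts;
the normalized layer is ``ln(TPM/s + 1)`` where TPM is the per-cell
transcripts-per-million rescaling and ``s`` a platform-dependent divisor
(10 for well-based plates sequenced to ~1e5 UMIs/cell, 100 for droplet
data at ~1e4 UMIs/cell) that keeps the pseudo-count honest at the actual
sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionDataset",
    "QCThresholds",
    "QC_PRESETS",
    "ParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "normalize",
    "qc_filter",
]

#: per-platform TPM divisor used by :func:`normalize`
PLATFORM_SCALE = {"well": 10.0, "droplet": 100.0}


class ParseError(ValueError):
    """A file could not be interpreted as a valid count matrix."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


@dataclass
class QCThresholds:
    """Strict lower bounds on detected genes and total transcripts per cell."""

    min_genes: int
    min_transcripts: int

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_transcripts < 0:
            raise ValidationError("QC thresholds must be non-negative")


#: named presets for the well-based datasets of different sequencing depth
QC_PRESETS = {
    "well_default": QCThresholds(2000, 100_000),
    "well_shallow": QCThresholds(2000, 50_000),
    "well_minimal": QCThresholds(1000, 10_000),
}


@dataclass
class ExpressionDataset:
    """Gene × cell UMI counts plus an optional normalized layer and metadata.

    Parameters
    ----------
    counts
        Dense ``(n_genes, n_cells)`` array of non-negative integer UMI counts.
    genes, cells
        Ordered unique identifiers for rows and columns.
    norm
        Optional normalized layer of the same shape (see :func:`normalize`).
    cell_meta, gene_meta
        Metadata tables indexed by cell / gene identifier.  Any subset of
        columns (stage, location, cluster, batch, ...) is allowed.
    platform
        ``"well"`` or ``"droplet"``; controls the normalization divisor.
    """

    counts: np.ndarray
    genes: list[str]
    cells: list[str]
    norm: np.ndarray | None = None
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    platform: str = "well"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D gene × cell matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes or len(self.cells) != n_cells:
            raise ValidationError(
                f"label/matrix mismatch: {len(self.genes)} genes × "
                f"{len(self.cells)} cells vs matrix {self.counts.shape}"
            )
        if len(set(self.genes)) != n_genes:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cells)) != n_cells:
            raise ValidationError("duplicate cell identifiers")
        if self.counts.size:
            if np.any(self.counts < 0):
                raise ValidationError("negative counts")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("non-integer counts")
        self.counts = self.counts.astype(np.int64, copy=False)
        if self.norm is not None:
            self.norm = np.asarray(self.norm, dtype=float)
            if self.norm.shape != self.counts.shape:
                raise ValidationError("norm layer shape differs from counts")
        if self.platform not in PLATFORM_SCALE:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cells, name="cell"))
        else:
            self.cell_meta = self.cell_meta.reindex(self.cells)
        if self.gene_meta.empty:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.genes, name="gene"))
        else:
            self.gene_meta = self.gene_meta.reindex(self.genes)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[s] for s in symbols], dtype=int)

    def cell_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        return np.array([lookup[c] for c in ids], dtype=int)

    def require_norm(self) -> np.ndarray:
        if self.norm is None:
            raise ValidationError(
                "dataset has no normalized layer; call avec.normalize first"
            )
        return self.norm

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionDataset":
        idx = self.cell_index(cells)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            norm=None if self.norm is None else self.norm[:, idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
            platform=self.platform,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return ExpressionDataset(
            counts=self.counts[idx, :],
            genes=[self.genes[i] for i in idx],
            cells=list(self.cells),
            norm=None if self.norm is None else self.norm[idx, :],
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].copy(),
            platform=self.platform,
        )


# -- reading and writing -------------------------------------------------------


def _read_labels(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise ParseError(f"missing {what} file: {path}")
    labels = [line.strip().split("\t")[0] for line in path.read_text().splitlines()]
    return [l for l in labels if l]


def _read_meta(path: Path) -> pd.DataFrame:
    if path.exists():
        return pd.read_csv(path, sep="\t", index_col=0)
    return pd.DataFrame()


def read_dataset(path: str | Path, format: str = "mtx") -> ExpressionDataset:
    """Read a dataset directory in matrix-market (``mtx``) or dense ``tsv`` form.

    ``mtx`` layout: ``matrix.mtx`` (genes as rows), ``genes.tsv``,
    ``barcodes.tsv`` and optional ``cell_meta.tsv`` / ``gene_meta.tsv``.
    ``tsv`` layout: ``counts.tsv`` with gene rows, cell columns, plus the
    same optional metadata files.
    """
    path = Path(path)
    if format == "mtx":
        mtx_path = path / "matrix.mtx"
        if not mtx_path.exists():
            raise ParseError(f"missing matrix file: {mtx_path}")
        mat = spio.mmread(mtx_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        genes = _read_labels(path / "genes.tsv", "gene label")
        cells = _read_labels(path / "barcodes.tsv", "cell barcode")
    elif format == "tsv":
        tsv_path = path / "counts.tsv"
        if not tsv_path.exists():
            raise ParseError(f"missing counts file: {tsv_path}")
        table = pd.read_csv(tsv_path, sep="\t", index_col=0)
        mat = table.to_numpy()
        genes = [str(g) for g in table.index]
        cells = [str(c) for c in table.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    if np.any(mat < 0):
        g, c = np.argwhere(mat < 0)[0]
        raise ParseError(
            f"negative count at gene {genes[g]!r}, cell {cells[c]!r}"
        )
    if not np.allclose(mat, np.round(mat)):
        g, c = np.argwhere(~np.isclose(mat, np.round(mat)))[0]
        raise ParseError(
            f"non-integer count at gene {genes[g]!r}, cell {cells[c]!r}"
        )
    try:
        return ExpressionDataset(
            counts=mat.astype(np.int64),
            genes=genes,
            cells=cells,
            cell_meta=_read_meta(path / "cell_meta.tsv"),
            gene_meta=_read_meta(path / "gene_meta.tsv"),
        )
    except ValidationError as exc:  # dimension/duplicate problems become parse errors
        raise ParseError(str(exc)) from exc


def write_dataset(dataset: ExpressionDataset, path: str | Path, format: str = "mtx") -> None:
    """Write ``dataset`` to a directory in ``mtx`` or ``tsv`` form (see reader)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        spio.mmwrite(
            str(path / "matrix.mtx"),
            sparse.coo_matrix(dataset.counts),
            field="integer",
        )
        (path / "genes.tsv").write_text("\n".join(dataset.genes) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(dataset.cells) + "\n")
    elif format == "tsv":
        table = pd.DataFrame(dataset.counts, index=dataset.genes, columns=dataset.cells)
        table.index.name = "gene"
        table.to_csv(path / "counts.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(dataset.cell_meta.columns):
        dataset.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    if len(dataset.gene_meta.columns):
        dataset.gene_meta.to_csv(path / "gene_meta.tsv", sep="\t")


# -- normalization and QC ------------------------------------------------------


def normalize(dataset: ExpressionDataset, platform: str | None = None) -> ExpressionDataset:
    """Fill the normalized layer with ``ln(TPM/s + 1)``.

    TPM is ``counts / cell_total × 1e6`` per cell; ``s`` is 10 for well-based
    and 100 for droplet data.  Cells with zero total UMIs cannot be rescaled
    and raise an error listing their identifiers.
    """
    platform = platform or dataset.platform
    if platform not in PLATFORM_SCALE:
        raise ValidationError(f"unknown platform {platform!r}")
    totals = dataset.counts.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        bad = [dataset.cells[i] for i in np.flatnonzero(zero)]
        raise ValidationError(f"cells with zero total UMIs: {bad}")
    tpm = dataset.counts / totals[None, :] * 1e6
    norm = np.log1p(tpm / PLATFORM_SCALE[platform])
    return ExpressionDataset(
        counts=dataset.counts,
        genes=list(dataset.genes),
        cells=list(dataset.cells),
        norm=norm,
        cell_meta=dataset.cell_meta.copy(),
        gene_meta=dataset.gene_meta.copy(),
        platform=platform,
    )


def qc_filter(
    dataset: ExpressionDataset, thresholds: QCThresholds
) -> tuple[ExpressionDataset, list[str]]:
    """Retain cells with strictly more detected genes and transcripts than the bounds.

    Both inequalities are strict: a cell at exactly the threshold is rejected.
    Returns the filtered dataset (cell order preserved) and the rejected ids.
    """
    genes_detected = (dataset.counts > 0).sum(axis=0)
    totals = dataset.counts.sum(axis=0)
    keep = (genes_detected > thresholds.min_genes) & (totals > thresholds.min_transcripts)
    rejected = [dataset.cells[i] for i in np.flatnonzero(~keep)]
    if not np.any(keep):
        warnings.warn("qc_filter rejected every cell", stacklevel=2)
        kept = []
    else:
        kept = [dataset.cells[i] for i in np.flatnonzero(keep)]
    return dataset.subset_cells(kept), rejected
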