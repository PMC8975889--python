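"""Heterologous ligand–receptor interaction calling between cell compartments.

A ligand–receptor pair is called between a mural-cell (MC) population and a
vascular-endothelial (VEC) population when the ligand is expressed above an
expression threshold in strictly more than half the cells of the sender
compartment AND the receptor is above the threshold in strictly more than
half the cells of the receiver compartment.  Both directions (MC ligand →
VEC receptor and VEC ligand → MC receptor) are evaluated.  The threshold is
the upper quartile of per-gene mean normalized expression over the analyzed
data; the value 1.34 derived from the original study's datasets is shipped
as :data:`REFERENCE_THRESHOLD` for reproducing that setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError

__all__ = [
    "REFERENCE_THRESHOLD",
    "InteractionCall",
    "load_lr_pairs",
    "expression_threshold",
    "detect_interactions",
    "shared_distinct",
    "interaction_network",
]

#: upper-quartile expression threshold reported for the original datasets
REFERENCE_THRESHOLD = 1.34

MC_TO_VEC = "MC→VEC"
VEC_TO_MC = "VEC→MC"


@dataclass(frozen=True)
class InteractionCall:
    """A directional ligand–receptor hit between two populations."""

    ligand: str
    receptor: str
    direction: str
    ligand_frac: float
    receptor_frac: float
    threshold_used: float
    dataset_pair_id: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


def load_lr_pairs(path) -> pd.DataFrame:
    """Read a two-column ``ligand<TAB>receptor`` table, dropping duplicates."""
    table = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(table.columns):
        raise ValidationError("LR table needs 'ligand' and 'receptor' columns")
    return table[["ligand", "receptor"]].drop_duplicates().reset_index(drop=True)


def _gene_means(dataset: ExpressionDataset) -> np.ndarray:
    return dataset.require_norm().mean(axis=1)


def expression_threshold(
    datasets: Iterable[ExpressionDataset], method: str = "gene_mean"
) -> float:
    """Upper quartile (75th percentile) of expression pooled over datasets.

    ``method="gene_mean"`` (default) pools per-gene mean normalized
    expression — robust to the zero-dominated entries of sparse matrices;
    ``"entry"`` pools every matrix entry and ``"nonzero_entry"`` only the
    nonzero ones.  Linear interpolation between order statistics is used.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValidationError("expression_threshold needs at least one dataset")
    if method == "gene_mean":
        pooled = np.concatenate([_gene_means(d) for d in datasets])
    elif method == "entry":
        pooled = np.concatenate([d.require_norm().ravel() for d in datasets])
    elif method == "nonzero_entry":
        pooled = np.concatenate(
            [d.require_norm()[d.require_norm() > 0] for d in datasets]
        )
        if pooled.size == 0:
            return 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.percentile(pooled, 75, method="linear"))


def _expressing_fraction(
    dataset: ExpressionDataset, gene: str, threshold: float
) -> float:
    """Fraction of cells with normalized expression strictly above threshold;
    genes absent from the dataset count as never expressed."""
    if gene not in set(dataset.genes):
        return 0.0
    row = dataset.require_norm()[dataset.gene_index([gene])[0]]
    return float((row > threshold).mean())


def detect_interactions(
    vec_data: ExpressionDataset,
    mc_data: ExpressionDataset,
    pairs: pd.DataFrame,
    threshold: float = REFERENCE_THRESHOLD,
    min_frac: float = 0.5,
    dataset_pair_id: str = "",
) -> list[InteractionCall]:
    """Call directional ligand–receptor interactions between two populations.

    For each pair and each direction, a call is emitted iff the expressing
    fraction strictly exceeds ``min_frac`` for the ligand in the sender
    population and for the receptor in the receiver population.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    calls: list[InteractionCall] = []
    for ligand, receptor in pairs[["ligand", "receptor"]].itertuples(index=False):
        for direction, sender, receiver in (
            (MC_TO_VEC, mc_data, vec_data),
            (VEC_TO_MC, vec_data, mc_data),
        ):
            lf = _expressing_fraction(sender, ligand, threshold)
            rf = _expressing_fraction(receiver, receptor, threshold)
            if lf > min_frac and rf > min_frac:
                calls.append(
                    InteractionCall(
                        ligand=ligand,
                        receptor=receptor,
                        direction=direction,
                        ligand_frac=lf,
                        receptor_frac=rf,
                        threshold_used=threshold,
                        dataset_pair_id=dataset_pair_id,
                    )
                )
    return calls


def shared_distinct(
    call_sets: Mapping[str, Iterable[tuple[str, str]]]
) -> dict[frozenset, set[tuple[str, str]]]:
    """Venn partition of named pair sets.

    Each pair of the union is assigned to exactly one region, keyed by the
    frozenset of set names that contain it; region sizes sum to the size of
    the union.
    """
    named = {k: set(v) for k, v in call_sets.items()}
    if len(named) < 2:
        raise ValidationError("shared_distinct needs at least 2 named sets")
    regions: dict[frozenset, set[tuple[str, str]]] = {}
    universe = set().union(*named.values())
    for pair in universe:
        members = frozenset(k for k, s in named.items() if pair in s)
        regions.setdefault(members, set()).add(pair)
    return regions


def interaction_network(calls: Iterable[InteractionCall]) -> dict[str, pd.DataFrame]:
    """Directional bipartite edge lists with node degrees.

    Returns one edge list per direction with columns ``ligand``,
    ``receptor``, ``ligand_degree`` and ``receptor_degree`` (degrees within
    that direction's deduplicated edge set).
    """
    calls = list(calls)
    out: dict[str, pd.DataFrame] = {}
    for direction in (MC_TO_VEC, VEC_TO_MC):
        edges = sorted(
            {(c.ligand, c.receptor) for c in calls if c.direction == direction}
        )
        table = pd.DataFrame(edges, columns=["ligand", "receptor"])
        if len(table):
            table["ligand_degree"] = table.groupby("ligand")["receptor"].transform("size")
            table["receptor_degree"] = table.groupby("receptor")["ligand"].transform("size")
        else:
            table["ligand_degree"] = pd.Series(dtype=int)
            table["receptor_degree"] = pd.Series(dtype=int)
        out[direction] = table
    return out
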