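"""Cross-species conservation screens and kNN label transfer.

Conserved cluster markers are genes called differentially expressed, in the
same direction, in the matched cluster contrast of both species (linked
through a homolog map); conserved arterial genes are additionally required
to be up-regulated in *all four* arterial-vs-venous comparisons (two
arterial populations, AEC1 and AEC2, each against the venous population
VeEC, in both species).  Candidates are ranked by Fisher's combined
probability of the per-comparison raw p-values.

Label transfer classifies query cells onto reference clusters by k-nearest
neighbors in a shared embedding (any integrated space; the embedding is an
input, not computed here).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ValidationError
from .diffexpr import fisher_combine

__all__ = [
    "load_homolog_map",
    "map_homologs",
    "conserved_cluster_markers",
    "conserved_arterial_genes",
    "knn_transfer",
]


def load_homolog_map(path) -> pd.DataFrame:
    """Read a two-column homolog table; fully duplicated rows are dropped."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValidationError("homolog map needs two columns")
    table = table.iloc[:, :2]
    table.columns = ["species_a", "species_b"]
    return table.drop_duplicates().reset_index(drop=True)


def map_homologs(
    genes: Sequence[str], homolog_map: pd.DataFrame, policy: str = "keep_all"
) -> pd.DataFrame:
    """Map gene symbols through a (possibly one-to-many) homolog table.

    Returns a table of ``(source, target, ambiguous)`` rows.  One-to-many
    sources are resolved per ``policy``: ``"keep_all"`` (default) keeps every
    target with the ambiguity flag set; ``"first"`` keeps the first target
    only (still flagged).  Unmapped genes are dropped and their count logged
    via a warning.
    """
    if homolog_map.empty:
        raise ValidationError("empty homolog map")
    if policy not in ("keep_all", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    a_col, b_col = homolog_map.columns[:2]
    grouped = homolog_map.groupby(a_col)[b_col].apply(list)
    rows = []
    unmapped = 0
    for g in genes:
        targets = grouped.get(g)
        if targets is None:
            unmapped += 1
            continue
        ambiguous = len(targets) > 1
        kept = targets if policy == "keep_all" else targets[:1]
        rows.extend({"source": g, "target": t, "ambiguous": ambiguous} for t in kept)
    if unmapped:
        warnings.warn(f"{unmapped} gene(s) without homolog dropped", stacklevel=2)
    return pd.DataFrame(rows, columns=["source", "target", "ambiguous"])


def _deg_lookup(deg: pd.DataFrame) -> pd.DataFrame:
    return deg.set_index("gene")[["p", "direction", "fold_change"]]


def conserved_cluster_markers(
    deg_species_a: pd.DataFrame,
    deg_species_b: pd.DataFrame,
    homolog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Shared cluster markers between two species, ranked by combined p.

    A species-A DEG is conserved when at least one of its homologs is a DEG
    with the same direction in the matched species-B contrast.  The record
    keeps both raw p-values, both fold changes and the Fisher combined
    p-value; rows are sorted ascending by the combined value.
    """
    a = _deg_lookup(deg_species_a)
    b = _deg_lookup(deg_species_b)
    mapping = map_homologs(list(a.index), homolog_map, policy="keep_all")
    rows = []
    for gene, sub in mapping.groupby("source", sort=False):
        hits = [t for t in sub["target"] if t in b.index
                and b.loc[t, "direction"] == a.loc[gene, "direction"]]
        if not hits:
            continue
        # with several homolog hits keep the most significant partner
        partner = min(hits, key=lambda t: b.loc[t, "p"])
        rows.append(
            {
                "gene": gene,
                "homolog": partner,
                "direction": a.loc[gene, "direction"],
                "p_a": a.loc[gene, "p"],
                "p_b": b.loc[partner, "p"],
                "fold_change_a": a.loc[gene, "fold_change"],
                "fold_change_b": b.loc[partner, "fold_change"],
                "ambiguous": bool(sub["ambiguous"].iloc[0]),
                "combined_p": fisher_combine([a.loc[gene, "p"], b.loc[partner, "p"]]),
                "n_comparisons": 2,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "homolog", "direction", "p_a", "p_b",
            "fold_change_a", "fold_change_b", "ambiguous",
            "combined_p", "n_comparisons",
        ],
    )
    return table.sort_values("combined_p", kind="stable").reset_index(drop=True)


def conserved_arterial_genes(
    deg_sets: Sequence[pd.DataFrame], homolog_map: pd.DataFrame
) -> pd.DataFrame:
    """Genes up-regulated in all four arterial-vs-venous comparisons.

    ``deg_sets`` are the four DEG tables in the order (species-A AEC1 vs
    VeEC, species-A AEC2 vs VeEC, species-B AEC1 vs VeEC, species-B AEC2 vs
    VeEC); the species-B tables are reached through the homolog map.  The
    result is ranked by Fisher's combination of the four raw p-values
    (chi-square with 8 df) and is, by construction, a subset of every
    up-regulated input list.
    """
    if len(deg_sets) != 4:
        raise ValidationError("conserved_arterial_genes needs exactly 4 DEG lists")
    ups = []
    for deg in deg_sets:
        table = _deg_lookup(deg)
        ups.append(table[table["direction"] == "up"])
    a1, a2, b1, b2 = ups
    candidates = sorted(set(a1.index) & set(a2.index))
    if not candidates:
        return pd.DataFrame(
            columns=["gene", "homolog", "p_values", "combined_p", "n_comparisons"]
        )
    mapping = map_homologs(candidates, homolog_map, policy="keep_all")
    rows = []
    for gene, sub in mapping.groupby("source", sort=False):
        partners = [t for t in sub["target"] if t in b1.index and t in b2.index]
        if not partners:
            continue
        partner = min(partners, key=lambda t: b1.loc[t, "p"] * b2.loc[t, "p"])
        ps = [a1.loc[gene, "p"], a2.loc[gene, "p"], b1.loc[partner, "p"], b2.loc[partner, "p"]]
        rows.append(
            {
                "gene": gene,
                "homolog": partner,
                "p_values": ps,
                "combined_p": fisher_combine(ps),
                "n_comparisons": 4,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "homolog", "p_values", "combined_p", "n_comparisons"]
    )
    return table.sort_values("combined_p", kind="stable").reset_index(drop=True)


def knn_transfer(
    reference_embedding: np.ndarray,
    reference_labels: Sequence[str],
    query_embedding: np.ndarray,
    k: int = 15,
) -> pd.DataFrame:
    """Classify query cells by majority vote of their k nearest reference cells.

    Distances are Euclidean in the shared embedding.  Ties in the vote are
    broken in favor of the tied label with the smallest summed distance; the
    vote fraction of the winning label is reported.
    """
    ref = np.asarray(reference_embedding, dtype=float)
    query = np.atleast_2d(np.asarray(query_embedding, dtype=float))
    labels = np.asarray(reference_labels)
    if ref.ndim != 2 or query.shape[1] != ref.shape[1]:
        raise ValidationError("embeddings must share dimensionality")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(ref):
        raise ValidationError(f"k={k} exceeds reference size {len(ref)}")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(query)
    predicted = []
    fractions = []
    for d_row, i_row in zip(dist, idx):
        neigh = labels[i_row]
        counts = pd.Series(neigh).value_counts()
        top = counts.max()
        tied = counts.index[counts == top]
        if len(tied) == 1:
            winner = tied[0]
        else:
            sums = {lab: d_row[neigh == lab].sum() for lab in tied}
            winner = min(sorted(sums), key=lambda lab: sums[lab])
        predicted.append(winner)
        fractions.append(top / k)
    return pd.DataFrame({"label": predicted, "vote_fraction": fractions})
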